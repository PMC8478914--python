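"""Domestication-signal analyses.

Grouped allele frequencies along the wild -> landrace -> cultivar axis
detect directional selection (stepwise accumulation of the favoured
allele).  Nucleotide diversity pi is the average pairwise per-site
difference among haplotypes, computed with the unbiased per-site form
2 p (1-p) n/(n-1); windowed scans use a 100 kb sliding window with a
20 kb step by default.  Selective sweeps around a cloned gene show up as
a valley of the ratio pi(favoured-allele accessions) /
pi(unfavoured-allele accessions) across the gene's flanking region, and
the selection pressure on a gene is the average cultivar/landrace pi
ratio over its windows.

Unphased diploid genotypes are expanded to haplotypes under site
independence (a heterozygote contributes one copy of each allele); every
statistic here depends on allele frequencies only, not phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GradmapError, GroupedGenotypes

log = logging.getLogger("gradmap.popgen")


@dataclass
class GroupedHaplotypes:
    """Biallelic 0/1 haplotypes with a group label per haplotype."""

    haps: np.ndarray      # n_haplotypes x n_sites, int8, -1 = missing
    groups: np.ndarray    # n_haplotypes labels
    pos: np.ndarray       # site positions, 1-based bp, sorted
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.haps.ndim != 2 or self.haps.shape[0] != len(self.groups):
            raise GradmapError("haplotype matrix and group labels disagree")
        if not np.all(np.diff(self.pos) >= 0):
            raise GradmapError("site positions must be sorted")

    def subset(self, mask: np.ndarray) -> "GroupedHaplotypes":
        return GroupedHaplotypes(self.haps[mask], self.groups[mask], self.pos, self.chrom)

    def group(self, label: str) -> np.ndarray:
        m = self.groups == label
        if not m.any():
            raise GradmapError(f"group {label!r} is empty")
        return self.haps[m]


def haplotypes_from_genotypes(geno: GroupedGenotypes) -> GroupedHaplotypes:
    """Expand unphased diploid dosages into 2n haplotypes (site-independent).

    Dosage 1 contributes one reference and one alternate haplotype allele;
    missing dosages propagate as missing on both haplotypes.
    """
    d = geno.dosage
    h1 = np.where(d == -1, -1, (d == 2).astype(np.int8))
    h2 = np.where(d == -1, -1, (d >= 1).astype(np.int8))
    haps = np.empty((2 * d.shape[0], d.shape[1]), dtype=np.int8)
    haps[0::2], haps[1::2] = h1, h2
    groups = np.repeat(np.asarray(geno.groups, dtype=object), 2)
    order = np.argsort(geno.pos, kind="stable")
    chrom = str(geno.chrom[0]) if len(set(geno.chrom)) == 1 else "multi"
    return GroupedHaplotypes(haps[:, order], groups, geno.pos[order], chrom)


# ---------------------------------------------------------------------------
# Allele frequencies and directional selection
# ---------------------------------------------------------------------------

def allele_freq_by_group(
    hap: GroupedHaplotypes, site: int, allele: int = 1
) -> pd.DataFrame:
    """Frequency of ``allele`` at one site per group (missing excluded)."""
    rows = []
    for grp in pd.unique(hap.groups):
        col = hap.haps[hap.groups == grp, site]
        ok = col >= 0
        n = int(ok.sum())
        rows.append(
            {
                "group": grp,
                "n": n,
                "freq": float((col[ok] == allele).sum() / n) if n else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if out["freq"].isna().any():
        log.warning("frequency undefined for empty group(s)")
    return out


def directional_check(
    freqs: list[float] | np.ndarray, delta: float = 0.01
) -> tuple[bool, float]:
    """Is the allele frequency non-decreasing along the ordered groups?

    The ordering is the domestication axis (wild -> landrace -> cultivar).
    Dips smaller than ``delta`` are tolerated.  Returns the verdict and the
    average frequency change per transition.
    """
    f = np.asarray([x for x in freqs if np.isfinite(x)], dtype=float)
    if len(f) < 2:
        raise GradmapError("need >=2 groups with defined frequency")
    steps = np.diff(f)
    return bool((steps >= -delta).all()), float(steps.mean())


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def pi(haps: np.ndarray) -> float:
    """Average pairwise difference per site among haplotypes.

    Per site with alternate frequency p among n called haplotypes the mean
    pairwise difference is 2 p (1-p) n/(n-1) (exactly the enumeration over
    all haplotype pairs); pi averages this over usable sites.  Sites with
    fewer than two called haplotypes are unusable.
    """
    haps = np.asarray(haps)
    if haps.shape[0] < 2:
        raise GradmapError("pi needs >= 2 haplotypes")
    called = (haps >= 0).sum(axis=0).astype(float)
    alt = (haps == 1).sum(axis=0)
    usable = called >= 2
    if not usable.any():
        raise GradmapError("no usable site (need >= 2 called haplotypes)")
    p = alt[usable] / called[usable]
    n = called[usable]
    per_site = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(per_site.mean())


def _window_grid(pos: np.ndarray, window_bp: int, step_bp: int) -> list[tuple[int, int]]:
    lo, hi = int(pos.min()), int(pos.max())
    wins = []
    start = lo
    while True:
        wins.append((start, start + window_bp - 1))
        if start + window_bp - 1 >= hi:
            break
        start += step_bp
    return wins


def window_scan(
    hap: GroupedHaplotypes,
    window_bp: int = 100_000,
    step_bp: int = 20_000,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group pi in sliding physical windows.

    Returns chrom, start_bp, end_bp, n_sites and one ``pi_<group>`` column
    per group; windows with no usable site are masked (NaN).
    """
    use_groups = list(pd.unique(hap.groups)) if groups is None else groups
    wins = _window_grid(hap.pos, window_bp, step_bp)
    rows = []
    for start, end in wins:
        inside = (hap.pos >= start) & (hap.pos <= end)
        row = {"chrom": hap.chrom, "start_bp": start, "end_bp": end, "n_sites": int(inside.sum())}
        for grp in use_groups:
            sub = hap.haps[hap.groups == grp][:, inside]
            try:
                row[f"pi_{grp}"] = pi(sub) if inside.any() else np.nan
            except GradmapError:
                row[f"pi_{grp}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sweep scanning and selection pressure
# ---------------------------------------------------------------------------

@dataclass
class SweepScanResult:
    focal_pos: int
    windows: pd.DataFrame          # start_bp, end_bp, pi_favored, pi_unfavored, ratio, in_valley
    valley_start: int | None
    valley_end: int | None

    @property
    def valley_span(self) -> int:
        if self.valley_start is None:
            return 0
        return self.valley_end - self.valley_start + 1


def sweep_scan(
    hap: GroupedHaplotypes,
    focal_pos: int,
    favored_mask: np.ndarray,
    span_bp: int = 500_000,
    window_bp: int = 100_000,
    step_bp: int = 20_000,
    valley_cut: float = 0.25,
) -> SweepScanResult:
    """Allele-contrast pi-ratio sweep scan around a focal gene.

    Within ``span_bp`` of the focal position, each window's ratio
    pi(favoured accessions) / pi(unfavoured accessions) is computed
    (masked where the unfavoured class has no diversity); the valley is
    the maximal run of windows with ratio below ``valley_cut`` that
    contains the focal gene.
    """
    favored_mask = np.asarray(favored_mask, dtype=bool)
    if favored_mask.all() or not favored_mask.any():
        raise GradmapError("both allele classes must be populated")
    lo, hi = focal_pos - span_bp, focal_pos + span_bp
    inside = (hap.pos >= lo) & (hap.pos <= hi)
    if not inside.any():
        raise GradmapError("no sites within the scan span")
    pos = hap.pos[inside]
    fav, unf = hap.haps[favored_mask][:, inside], hap.haps[~favored_mask][:, inside]
    rows = []
    for start, end in _window_grid(pos, window_bp, step_bp):
        m = (pos >= start) & (pos <= end)
        if not m.any():
            rows.append((start, end, np.nan, np.nan, np.nan))
            continue
        try:
            pf, pu = pi(fav[:, m]), pi(unf[:, m])
        except GradmapError:
            rows.append((start, end, np.nan, np.nan, np.nan))
            continue
        ratio = pf / pu if pu > 0 else np.nan
        rows.append((start, end, pf, pu, ratio))
    df = pd.DataFrame(rows, columns=["start_bp", "end_bp", "pi_favored", "pi_unfavored", "ratio"])
    below = (df["ratio"] < valley_cut).to_numpy()
    df["in_valley"] = False
    v_start = v_end = None
    # maximal run of below-threshold windows containing the focal position
    i = 0
    while i < len(df):
        if below[i]:
            j = i
            while j + 1 < len(df) and below[j + 1]:
                j += 1
            run_start, run_end = int(df.loc[i, "start_bp"]), int(df.loc[j, "end_bp"])
            if run_start <= focal_pos <= run_end:
                v_start, v_end = run_start, run_end
                df.loc[i:j, "in_valley"] = True
                break
            i = j + 1
        else:
            i += 1
    if v_start is None:
        log.info("no pi-ratio valley below %.2f contains the focal gene", valley_cut)
    return SweepScanResult(
        focal_pos=focal_pos, windows=df, valley_start=v_start, valley_end=v_end
    )


def selection_pressure(
    hap: GroupedHaplotypes,
    region: tuple[int, int],
    numerator_group: str = "cultivar",
    denominator_group: str = "landrace",
    window_bp: int = 100_000,
    step_bp: int = 20_000,
) -> float:
    """Mean cultivar/landrace pi ratio over a gene region's windows.

    Windows where the denominator group's pi is zero (or either pi is
    undefined) are masked.
    """
    scan = window_scan(hap, window_bp, step_bp, groups=[numerator_group, denominator_group])
    lo, hi = region
    sub = scan[(scan["end_bp"] >= lo) & (scan["start_bp"] <= hi)]
    num = sub[f"pi_{numerator_group}"].to_numpy(dtype=float)
    den = sub[f"pi_{denominator_group}"].to_numpy(dtype=float)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    if not ok.any():
        raise GradmapError("no window with defined pi ratio in region")
    return float((num[ok] / den[ok]).mean())
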