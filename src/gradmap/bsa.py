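"""Bulked-segregant analysis.

Two pools of phenotypic extremes (top and bottom 15% of an F2 gradient
population by default) are contrasted marker by marker.  In read mode the
SNP index of a bulk at a marker is the fraction of reads carrying the
high-parent (alternate) allele; at a marker tightly linked to the causal
locus the index approaches 1 in the concordant bulk and 0 in the other,
while unlinked markers sit near 0.5 in both.  Delta(SNP index) = high-bulk
index minus low-bulk index.  In chip mode the pooled genotype calls of the
two bulk DNAs are compared directly: a marker discriminates when at least
one bulk is homozygous and the calls differ.

Candidate regions are runs of extreme windows (read mode) or runs of
discriminating markers (chip mode), padded to a working interval for
marker design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeCallMatrix, GradmapError, MarkerMap
from .simulate import Population, bulk_allele_freq, simulate_reads

log = logging.getLogger("gradmap.bsa")


@dataclass
class BulkPair:
    """Index arrays (into the population) of the two phenotype-extreme bulks."""

    high_idx: np.ndarray
    low_idx: np.ndarray
    high_ids: list[str]
    low_ids: list[str]


@dataclass
class SNPIndexTrack:
    """Per-marker SNP indices of the two bulks and their difference."""

    df: pd.DataFrame  # marker, chrom, pos_bp, index_high, index_low, delta, depth_high, depth_low


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    support: int        # markers or windows backing the region
    peak: float         # peak |delta| (read mode) or support count (chip mode)
    mode: str           # "read-index" | "chip"


def make_bulks(pop: Population, fraction: float = 0.15, min_size: int = 30) -> BulkPair:
    """Top/bottom ``fraction`` of the population by phenotype.

    Bulks expand to ``min_size`` (with a warning) when the fraction is too
    small; ties at the quantile break by stable accession-id order.
    """
    if pop.phenotypes is None:
        raise GradmapError("population must be phenotyped before bulking")
    n = len(pop)
    k = int(np.floor(fraction * n))
    if k < 1:
        raise GradmapError("fraction * n < 1: no individuals to bulk")
    if k < min_size:
        warnings.warn(f"bulk of {k} below min_size; expanded to {min_size}")
        k = min_size
    if n < 2 * k:
        raise GradmapError(f"population of {n} too small for two bulks of {k}")
    if np.ptp(pop.phenotypes) == 0:
        warnings.warn("all phenotypes equal; bulks are arbitrary (first/last by id)")
    order = np.lexsort((np.array(pop.ids), pop.phenotypes))  # stable in id at ties
    low, high = order[:k], order[-k:]
    return BulkPair(
        high_idx=np.sort(high),
        low_idx=np.sort(low),
        high_ids=[pop.ids[i] for i in np.sort(high)],
        low_ids=[pop.ids[i] for i in np.sort(low)],
    )


def snp_index(counts: pd.DataFrame, mmap: MarkerMap, min_depth: int = 10) -> SNPIndexTrack:
    """SNP-index track from a long read-count table (marker, bulk, ref, alt).

    index = alt / (ref + alt) per bulk per marker; markers below
    ``min_depth`` total reads in a bulk are masked (NaN) rather than scored.
    """
    wide = counts.pivot(index="marker", columns="bulk", values=["ref_count", "alt_count"])
    for b in ("high", "low"):
        if ("ref_count", b) not in wide.columns:
            raise GradmapError(f"read-count table lacks bulk {b!r}")
    df = mmap.df[["marker", "chrom", "pos_bp"]].copy()
    df = df[df["marker"].isin(wide.index)].reset_index(drop=True)
    out = {}
    for b in ("high", "low"):
        ref = wide.loc[df["marker"], ("ref_count", b)].to_numpy(dtype=float)
        alt = wide.loc[df["marker"], ("alt_count", b)].to_numpy(dtype=float)
        depth = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(depth >= min_depth, alt / np.where(depth > 0, depth, 1), np.nan)
        out[f"index_{b}"] = idx
        out[f"depth_{b}"] = depth.astype(int)
    df["index_high"] = out["index_high"]
    df["index_low"] = out["index_low"]
    df["delta"] = df["index_high"] - df["index_low"]
    df["depth_high"] = out["depth_high"]
    df["depth_low"] = out["depth_low"]
    return SNPIndexTrack(df)


def bulk_read_counts(
    pop: Population, bulks: BulkPair, depth: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Emit a long read-count table for both bulks of a population."""
    rows = []
    for name, idx in (("high", bulks.high_idx), ("low", bulks.low_idx)):
        freq = bulk_allele_freq(pop, idx)
        ref, alt = simulate_reads(freq, depth, rng)
        rows.append(
            pd.DataFrame(
                {
                    "marker": pop.mmap.markers,
                    "bulk": name,
                    "ref_count": ref,
                    "alt_count": alt,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def smooth_track(
    track: SNPIndexTrack,
    window_bp: int = 1_000_000,
    step_bp: int = 200_000,
    min_markers: int = 1,
) -> pd.DataFrame:
    """Sliding-window mean of delta over physical windows per chromosome.

    Windows with fewer than ``min_markers`` scored (unmasked) markers are
    masked.  Returns chrom, start_bp, end_bp, mean_delta, n_markers.
    """
    rows = []
    for chrom, sub in track.df.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        delta = sub["delta"].to_numpy(dtype=float)
        lo, hi = int(pos.min()), int(pos.max())
        start = lo
        while True:
            end = start + window_bp - 1
            inside = (pos >= start) & (pos <= end) & ~np.isnan(delta)
            n = int(inside.sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": start,
                    "end_bp": end,
                    "mean_delta": float(delta[inside].mean()) if n >= min_markers else np.nan,
                    "n_markers": n,
                }
            )
            if end >= hi:
                break
            start += step_bp
    return pd.DataFrame(rows)


def chip_call(
    bulk_calls: pd.DataFrame,
    mmap: MarkerMap,
    min_markers: int = 3,
    max_gap_bp: int = 2_000_000,
) -> list[CandidateRegion]:
    """Candidate regions from pooled chip-style calls of the two bulk DNAs.

    ``bulk_calls`` has columns ``high`` and ``low`` of calls in {A,B,H,.}
    indexed by marker.  A marker discriminates when at least one bulk call
    is homozygous and the two calls differ; runs of >= ``min_markers``
    discriminating markers within ``max_gap_bp`` merge into regions.
    """
    df = mmap.df[["marker", "chrom", "pos_bp"]].merge(
        bulk_calls, left_on="marker", right_index=True, how="inner"
    )
    hi, lo = df["high"].to_numpy(dtype=str), df["low"].to_numpy(dtype=str)
    disc = (hi != lo) & (np.isin(hi, ["A", "B"]) | np.isin(lo, ["A", "B"])) & (hi != ".") & (lo != ".")
    regions: list[CandidateRegion] = []
    for chrom, sub in df.assign(disc=disc).groupby("chrom", sort=False):
        run: list[int] = []
        prev_pos = None
        for _, row in sub.iterrows():
            if row["disc"] and (prev_pos is None or not run or row["pos_bp"] - prev_pos <= max_gap_bp):
                run.append(int(row["pos_bp"]))
            elif row["disc"]:
                _flush_chip_run(regions, chrom, run, min_markers)
                run = [int(row["pos_bp"])]
            else:
                _flush_chip_run(regions, chrom, run, min_markers)
                run = []
            prev_pos = int(row["pos_bp"])
        _flush_chip_run(regions, chrom, run, min_markers)
    return regions


def _flush_chip_run(regions: list, chrom: str, run: list[int], min_markers: int) -> None:
    if len(run) >= min_markers:
        regions.append(
            CandidateRegion(
                chrom=str(chrom),
                start_bp=run[0],
                end_bp=run[-1],
                support=len(run),
                peak=float(len(run)),
                mode="chip",
            )
        )


def pooled_bulk_calls(pop: Population, bulks: BulkPair) -> pd.DataFrame:
    """Array-style pooled call per bulk per marker.

    The bulk call is A when the high-parent allele frequency in the pool is
    >= 0.9, B when <= 0.1, else H (mimics cluster calling on pooled DNA).
    """
    out = {}
    for name, idx in (("high", bulks.high_idx), ("low", bulks.low_idx)):
        f = bulk_allele_freq(pop, idx)
        out[name] = np.where(f >= 0.9, "A", np.where(f <= 0.1, "B", "H"))
    return pd.DataFrame(out, index=pd.Index(pop.mmap.markers, name="marker"))


def call_candidate(
    windows: pd.DataFrame,
    threshold: float = 0.5,
    pad_bp: int = 1_000_000,
) -> list[CandidateRegion]:
    """Candidate regions from a smoothed delta track.

    Contiguous windows with |mean delta| >= ``threshold`` merge; regions are
    ranked by peak |delta| and padded by ``pad_bp`` on each side into the
    working interval genotyping markers are designed in.
    """
    if windows.empty:
        raise GradmapError("empty window track")
    regions: list[CandidateRegion] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start_bp")
        hot = sub["mean_delta"].abs() >= threshold
        cur: list[pd.Series] = []
        prev_end = None
        for (_, row), h in zip(sub.iterrows(), hot):
            contiguous = prev_end is not None and row["start_bp"] <= prev_end + 1
            if h and cur and contiguous:
                cur.append(row)
            elif h:
                _flush_windows(regions, chrom, cur, pad_bp)
                cur = [row]
            else:
                _flush_windows(regions, chrom, cur, pad_bp)
                cur = []
            prev_end = row["end_bp"]
        _flush_windows(regions, chrom, cur, pad_bp)
    if not regions:
        log.info("no candidate region exceeds |delta| threshold %.2f", threshold)
    return sorted(regions, key=lambda r: -r.peak)


def _flush_windows(regions: list, chrom: str, cur: list, pad_bp: int) -> None:
    if not cur:
        return
    start = int(min(r["start_bp"] for r in cur))
    end = int(max(r["end_bp"] for r in cur))
    regions.append(
        CandidateRegion(
            chrom=str(chrom),
            start_bp=max(1, start - pad_bp),
            end_bp=end + pad_bp,
            support=len(cur),
            peak=float(max(abs(r["mean_delta"]) for r in cur)),
            mode="read-index",
        )
    )


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "support": r.support,
                "peak": r.peak,
                "mode": r.mode,
            }
            for r in regions
        ],
        columns=["chrom", "start_bp", "end_bp", "support", "peak", "mode"],
    )
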