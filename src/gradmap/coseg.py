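"""The co-segregation standard, single-locus model classification,
fine mapping and replacement-family selection.

A candidate QTL is verified when the two homozygous flanking-marker
genotype classes (AA and BB, requiring identical calls at both flanks)
have distinguishable phenotypes, heterozygotes and recombinants
disregarded.  "Distinguishable" is operationalised as a Welch two-sample
test at a stringent alpha plus a bound on the midpoint-threshold
misclassification fraction between the two homozygous classes.

A verified locus is classified into one of 12 single-locus genetic models:
three effect classes (complete dominant, semi-dominant/additive,
over-dominant) x two allele orientations (high- or low-value allele
carries the effect) x two boundary states (discrete vs partially
overlapping phenotype classes), with expected phenotype-class ratios
3:1 / 1:3 (complete dominance), 1:2:1 (semi-dominance) and 1:1:2 / 2:1:1
(over-dominance) in an F2.

Recombinants between the flanks, useless for verification, are the raw
material of fine mapping: each informative recombinant's inferred QTL
genotype pins the locus to one side of its breakpoint, and the narrowed
interval is the intersection of the consistent constraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeCallMatrix, GradmapError, MarkerMap
from .simulate import Architecture, Population, genotype_calls, phenotype_population, self_population

log = logging.getLogger("gradmap.coseg")

JOINT_CLASSES = ("AA", "BB", "HH", "recombinant", "missing")


@dataclass
class FlankClassification:
    """Joint genotype class over the two flanking markers, per individual."""

    classes: pd.Series  # index accession, values in JOINT_CLASSES
    left: str
    right: str

    def ids(self, cls: str) -> pd.Index:
        return self.classes.index[self.classes == cls]

    def counts(self) -> dict[str, int]:
        return {c: int((self.classes == c).sum()) for c in JOINT_CLASSES}


@dataclass
class CosegResult:
    verified: bool
    status: str                  # "verified" | "not_verified" | "undetermined"
    statistic: float             # Welch t on AA vs BB
    p_value: float
    overlap: float               # midpoint misclassification fraction, AA+BB
    model_id: str                # e.g. "complete-dominant/high/discrete" or "none"
    class_stats: pd.DataFrame    # per class: n, mean, sd
    pve_f2gp: float | None
    segregation_p: float | None  # chi-square of the model's expected class ratio
    dominance: float | None = None  # degree of dominance h_hat = d_hat / a_hat


@dataclass
class RecombinantRecord:
    """An individual with discordant flanking-marker calls."""

    id: str
    left_call: str
    right_call: str
    break_left: str        # last marker consistent with the left flank
    break_right: str       # first marker consistent with the right flank
    break_left_bp: int
    break_right_bp: int
    phenotype: float | None = None
    inferred_genotype: str | None = None   # "AA" | "BB" | "ambiguous"
    consistent_side: str | None = None     # "left" | "right" | "conflict"


@dataclass
class FineMapResult:
    chrom: str
    start_bp: int
    end_bp: int
    support: pd.DataFrame  # per boundary marker: consistent recombinants abutting it
    n_informative: int
    n_conflicts: int


# ---------------------------------------------------------------------------
# Flank classification and verification
# ---------------------------------------------------------------------------

def classify_flanks(calls: GenotypeCallMatrix, left: str, right: str) -> FlankClassification:
    """Assign each individual a joint class over [left, right] flanks."""
    lc = calls.column(left).to_numpy(dtype=str)
    rc = calls.column(right).to_numpy(dtype=str)
    out = np.full(len(lc), "recombinant", dtype=object)
    out[(lc == ".") | (rc == ".")] = "missing"
    for sym, cls in (("A", "AA"), ("B", "BB"), ("H", "HH")):
        out[(lc == sym) & (rc == sym)] = cls
    return FlankClassification(
        classes=pd.Series(out, index=calls.calls.index), left=left, right=right
    )


def _class_pheno(flanks: FlankClassification, phen: pd.Series, cls: str) -> np.ndarray:
    vals = phen.reindex(flanks.ids(cls)).dropna()
    return vals.to_numpy(dtype=float)


def _class_stats(flanks: FlankClassification, phen: pd.Series) -> pd.DataFrame:
    rows = []
    for cls in ("AA", "HH", "BB", "recombinant", "missing"):
        v = _class_pheno(flanks, phen, cls)
        rows.append(
            {
                "class": cls,
                "n": len(v),
                "mean": float(np.mean(v)) if len(v) else np.nan,
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def _midpoint_overlap(aa: np.ndarray, bb: np.ndarray) -> float:
    """Fraction of homozygotes on the wrong side of the class-mean midpoint."""
    mid = (aa.mean() + bb.mean()) / 2.0
    if aa.mean() >= bb.mean():
        wrong = (aa < mid).sum() + (bb > mid).sum()
    else:
        wrong = (aa > mid).sum() + (bb < mid).sum()
    return float(wrong) / (len(aa) + len(bb))


def coseg_test(
    flanks: FlankClassification,
    phenotypes: pd.Series,
    alpha: float = 1e-3,
    max_overlap: float = 0.20,
    min_class_size: int = 8,
) -> CosegResult:
    """Verify a candidate QTL by the co-segregation standard.

    Verified iff the Welch two-sample test on the AA vs BB phenotypes
    rejects at ``alpha`` AND the midpoint misclassification fraction across
    the two homozygous classes is <= ``max_overlap``.  Heterozygotes,
    recombinants and missing calls never enter the verdict.  With fewer
    than ``min_class_size`` members in either homozygous class the result
    is "undetermined", never a silent pass.
    """
    aa = _class_pheno(flanks, phenotypes, "AA")
    bb = _class_pheno(flanks, phenotypes, "BB")
    cs = _class_stats(flanks, phenotypes)
    if len(aa) < min_class_size or len(bb) < min_class_size:
        return CosegResult(
            verified=False,
            status="undetermined",
            statistic=np.nan,
            p_value=np.nan,
            overlap=np.nan,
            model_id="none",
            class_stats=cs,
            pve_f2gp=None,
            segregation_p=None,
        )
    if np.var(aa) == 0 and np.var(bb) == 0:
        # degenerate noiseless classes: identical means are indistinguishable,
        # distinct means are perfectly separated
        t, p = (0.0, 1.0) if aa.mean() == bb.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(aa, bb, equal_var=False)
    overlap = _midpoint_overlap(aa, bb)
    verified = bool(p < alpha and overlap <= max_overlap)
    pve = pve_f2gp(flanks, phenotypes) if verified else None
    return CosegResult(
        verified=verified,
        status="verified" if verified else "not_verified",
        statistic=float(t),
        p_value=float(p),
        overlap=overlap,
        model_id="none",
        class_stats=cs,
        pve_f2gp=pve,
        segregation_p=None,
    )


# ---------------------------------------------------------------------------
# 12-model classification
# ---------------------------------------------------------------------------

_RATIOS = {
    # phenotype-class expected F2 fractions, classes ordered low -> high value
    ("complete-dominant", "high"): {"classes": 2, "expected": (0.25, 0.75)},   # 3:1 high
    ("complete-dominant", "low"): {"classes": 2, "expected": (0.75, 0.25)},    # 1:3
    ("semi-dominant", "high"): {"classes": 3, "expected": (0.25, 0.5, 0.25)},  # 1:2:1
    ("semi-dominant", "low"): {"classes": 3, "expected": (0.25, 0.5, 0.25)},
    ("over-dominant", "high"): {"classes": 3, "expected": (0.25, 0.25, 0.5)},  # 1:1:2
    ("over-dominant", "low"): {"classes": 3, "expected": (0.5, 0.25, 0.25)},   # 2:1:1
}


def classify_model(
    flanks: FlankClassification,
    phenotypes: pd.Series,
    tau: float = 0.25,
) -> tuple[str, dict]:
    """Classify a verified locus into one of the 12 single-locus models.

    The degree of dominance is estimated from the three genotype-class
    means, h_hat = (mean_H - midparent) / (0.5 (mean_AA - mean_BB)):
    |h_hat| <= tau -> semi-dominant; 1-tau <= |h_hat| <= 1+tau -> complete
    dominant; |h_hat| > 1+tau -> over-dominant; values in the gap give
    model "none" with diagnostics.  Orientation comes from the sign of
    h_hat for dominance classes and from which parent carries the
    high-value allele for the additive class.  Boundary state is
    "discrete" when the phenotype classes do not overlap at all, else
    "partially-overlapping".  The observed phenotype-class counts are
    tested by chi-square against the model's expected F2 ratio.
    """
    aa = _class_pheno(flanks, phenotypes, "AA")
    bb = _class_pheno(flanks, phenotypes, "BB")
    hh = _class_pheno(flanks, phenotypes, "HH")
    if len(aa) == 0 or len(bb) == 0 or len(hh) == 0:
        return "none", {"reason": "need all three genotype classes"}
    m_aa, m_bb, m_h = aa.mean(), bb.mean(), hh.mean()
    half_diff = 0.5 * (m_aa - m_bb)
    if half_diff == 0:
        return "none", {"reason": "homozygous class means coincide"}
    h_hat = (m_h - 0.5 * (m_aa + m_bb)) / half_diff

    if abs(h_hat) <= tau:
        effect = "semi-dominant"
        orient = "high" if m_aa > m_bb else "low"
    elif 1 - tau <= abs(h_hat) <= 1 + tau:
        effect = "complete-dominant"
        orient = "high" if h_hat > 0 else "low"
    elif abs(h_hat) > 1 + tau:
        effect = "over-dominant"
        orient = "high" if h_hat > 0 else "low"
    else:
        return "none", {"reason": "ambiguous dominance", "h_hat": float(h_hat)}

    # Phenotype classes under the model: complete dominance pools H with the
    # homozygote it mimics; the other models keep three classes.
    if effect == "complete-dominant":
        dominant = aa if h_hat > 0 else bb
        recessive = bb if h_hat > 0 else aa
        class_values = [recessive, np.concatenate([dominant, hh])]
        if h_hat <= 0:  # dominant class is the LOW-value one; order low -> high
            class_values = class_values[::-1]
            counts = (len(class_values[0]), len(class_values[1]))
        else:
            counts = (len(recessive), len(dominant) + len(hh))
    else:
        ordered = sorted([("AA", aa), ("BB", bb), ("HH", hh)], key=lambda kv: kv[1].mean())
        class_values = [v for _, v in ordered]
        counts = tuple(len(v) for v in class_values)

    spec = _RATIOS[(effect, orient)]
    expected = np.array(spec["expected"]) * sum(counts)
    chi_p = float(stats.chisquare(np.array(counts, dtype=float), expected).pvalue)

    # Boundary state: do adjacent phenotype classes overlap in range?
    discrete = True
    for lo_v, hi_v in zip(class_values[:-1], class_values[1:]):
        if lo_v.max() >= hi_v.min():
            discrete = False
            break
    boundary = "discrete" if discrete else "partially-overlapping"

    model_id = f"{effect}/{orient}/{boundary}"
    diag = {
        "h_hat": float(h_hat),
        "class_counts": counts,
        "segregation_p": chi_p,
        "boundary": boundary,
    }
    return model_id, diag


def pve_f2gp(flanks: FlankClassification, phenotypes: pd.Series) -> float:
    """Phenotypic variance explained within one F2 gradient population.

    One-way ANOVA R-squared (between-class sum of squares over total) over
    the three flanking-marker genotype classes AA / HH / BB.
    """
    groups = [
        _class_pheno(flanks, phenotypes, c)
        for c in ("AA", "HH", "BB")
    ]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise GradmapError("PVE undefined: fewer than two populated genotype classes")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = ((allv - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    return float(min(1.0, ss_between / ss_total))


# ---------------------------------------------------------------------------
# Replacement families
# ---------------------------------------------------------------------------

def select_replacement_family(
    f2: Population,
    arch: Architecture,
    left: str,
    right: str,
    family_size: int,
    rng: np.random.Generator,
    max_candidates: int = 12,
    **coseg_kw,
):
    """Self candidate F2 lines and return the first family that verifies.

    Candidates are lines heterozygous at both flanks, searched in
    medium-value, then low-value, then high-value phenotype order (the
    middle of the distribution is most likely to be segregating only at
    the target locus).  Each candidate is selfed into a family of
    ``family_size``, phenotyped under the architecture, and checked by the
    co-segregation standard at the same flanks.
    """
    if f2.phenotypes is None:
        raise GradmapError("F2 must be phenotyped to rank replacement candidates")
    dos = f2.dosage()
    il, ir = f2.mmap.index_of(left), f2.mmap.index_of(right)
    het = np.flatnonzero((dos[:, il] == 1) & (dos[:, ir] == 1))
    if het.size == 0:
        return None, []
    phen = f2.phenotypes[het]
    med = np.median(phen)
    # medium first, then low, then high
    order = het[np.argsort(np.abs(phen - med), kind="stable")]
    low_first = het[np.argsort(phen, kind="stable")]
    seen, ranked = set(), []
    for cand in list(order) + list(low_first) + list(low_first[::-1]):
        if cand not in seen:
            seen.add(cand)
            ranked.append(cand)
    diagnostics = []
    for i in ranked[:max_candidates]:
        line = Population(
            f2.label + "_line", f2.mmap, f2.haps[i : i + 1], ids=[f2.ids[i]]
        )
        fam = self_population(line, family_size, rng)
        phenotype_population(fam, arch, rng)
        calls = genotype_calls(fam)
        flanks = classify_flanks(calls, left, right)
        res = coseg_test(flanks, fam.phenotype_table().means(), **coseg_kw)
        diagnostics.append({"line": f2.ids[i], "status": res.status, "p": res.p_value})
        if res.verified:
            return (fam, res), diagnostics
    return None, diagnostics


# ---------------------------------------------------------------------------
# Recombinant screening and fine mapping
# ---------------------------------------------------------------------------

def screen_recombinants(
    calls: GenotypeCallMatrix,
    mmap: MarkerMap,
    left: str,
    right: str,
    phenotypes: pd.Series | None = None,
) -> list[RecombinantRecord]:
    """All individuals with discordant flanking-marker calls.

    The breakpoint interval is bounded by the last genotyped marker (from
    the left) whose call matches the left flank and the first whose call
    matches the right flank; with no informative internal markers the
    breakpoint is the whole interval.
    """
    il, ir = mmap.index_of(left), mmap.index_of(right)
    if mmap.chrom_of(left) != mmap.chrom_of(right) or il >= ir:
        raise GradmapError("flanks must be ordered markers on one chromosome")
    inner = mmap.df.iloc[il : ir + 1]
    marker_names = [m for m in inner["marker"] if m in calls.calls.columns]
    if left not in marker_names or right not in marker_names:
        raise GradmapError("both flanking markers must be genotyped")
    sub = calls.calls[marker_names]
    pos = {m: int(mmap.df.loc[mmap.index_of(m), "pos_bp"]) for m in marker_names}
    records = []
    for acc, row in sub.iterrows():
        lc, rc = str(row[left]), str(row[right])
        if lc == rc or lc == "." or rc == ".":
            continue
        # walk inwards: last marker matching the left call, first matching right
        bl, br = left, right
        for m in marker_names:
            if str(row[m]) == lc:
                bl = m
            elif str(row[m]) == rc:
                br = m
                break
        records.append(
            RecombinantRecord(
                id=str(acc),
                left_call=lc,
                right_call=rc,
                break_left=bl,
                break_right=br,
                break_left_bp=pos[bl],
                break_right_bp=pos[br],
                phenotype=None if phenotypes is None else float(phenotypes.get(acc, np.nan)),
            )
        )
    return records


def fine_map(
    recombinants: list[RecombinantRecord],
    phenotypes: pd.Series,
    mean_aa: float,
    mean_bb: float,
    candidate_interval: tuple[str, int, int],
    epsilon: float | None = None,
) -> FineMapResult:
    """Narrow a QTL interval from recombinant breakpoints and phenotypes.

    Each recombinant's QTL genotype is inferred by the nearest homozygous
    class mean (ambiguous, and excluded, within ``epsilon`` of the
    midpoint; default epsilon is 5% of the class-mean separation).  A
    recombinant whose inferred genotype matches its left-flank call places
    the locus left of its breakpoint's right edge; matching the right
    flank places it right of the breakpoint's left edge.  The interval is
    the intersection of the constraints of the largest consistent set
    (one-sided bounds, so the consistent majority is found by sweeping
    candidate positions); recombinants outside that set are counted as
    conflicts.
    """
    chrom, cand_lo, cand_hi = candidate_interval
    sep = abs(mean_aa - mean_bb)
    if sep == 0:
        raise GradmapError("fine mapping needs distinct homozygous class means")
    eps = 0.05 * sep if epsilon is None else epsilon
    mid = (mean_aa + mean_bb) / 2.0

    lower: list[tuple[int, RecombinantRecord]] = []  # locus > bp
    upper: list[tuple[int, RecombinantRecord]] = []  # locus < bp
    n_ambig = 0
    for rec in recombinants:
        if rec.phenotype is None or not np.isfinite(rec.phenotype):
            n_ambig += 1
            continue
        if abs(rec.phenotype - mid) <= eps:
            rec.inferred_genotype = "ambiguous"
            n_ambig += 1
            continue
        geno = "AA" if abs(rec.phenotype - mean_aa) < abs(rec.phenotype - mean_bb) else "BB"
        rec.inferred_genotype = geno
        sym = geno[0]  # "A" or "B"
        if rec.left_call == sym:
            rec.consistent_side = "left"
            upper.append((rec.break_right_bp, rec))
        elif rec.right_call == sym:
            rec.consistent_side = "right"
            lower.append((rec.break_left_bp, rec))
        else:
            # phenotype says homozygous for an allele neither flank carries
            rec.consistent_side = "conflict"
            n_ambig += 0  # counted as conflict below via exclusion
    informative = lower + upper
    if not informative:
        raise GradmapError("no informative recombinant with unambiguous phenotype")

    # One-sided constraints: find the position satisfying the most of them.
    cuts = sorted({cand_lo, cand_hi} | {b for b, _ in lower} | {b for b, _ in upper})
    probes = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        probes.append((a + b) / 2.0)
    best_n, best_probe = -1, None
    for x in probes:
        n_ok = sum(1 for b, _ in lower if x > b) + sum(1 for b, _ in upper if x < b)
        if n_ok > best_n:
            best_n, best_probe = n_ok, x
    consistent_lower = [(b, r) for b, r in lower if best_probe > b]
    consistent_upper = [(b, r) for b, r in upper if best_probe < b]
    n_conflicts = (
        len(informative) - len(consistent_lower) - len(consistent_upper)
        + sum(1 for r in recombinants if r.consistent_side == "conflict")
    )
    start = max([cand_lo] + [b for b, _ in consistent_lower])
    end = min([cand_hi] + [b for b, _ in consistent_upper])
    if start >= end:
        raise GradmapError(
            f"empty fine-map interval: conflicting constraints at {chrom}:{start}-{end}"
        )
    support_rows: dict[str, int] = {}
    for _, r in consistent_lower:
        support_rows[r.break_left] = support_rows.get(r.break_left, 0) + 1
    for _, r in consistent_upper:
        support_rows[r.break_right] = support_rows.get(r.break_right, 0) + 1
    support = pd.DataFrame(
        sorted(support_rows.items()), columns=["marker", "n_recombinants"]
    )
    return FineMapResult(
        chrom=chrom,
        start_bp=int(start),
        end_bp=int(end),
        support=support,
        n_informative=len(consistent_lower) + len(consistent_upper),
        n_conflicts=int(n_conflicts),
    )
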