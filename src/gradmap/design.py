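"""Gradient-cross experimental design.

The design engine turns a phenotyped core collection into a plan of
gradient crosses.  The central quantity is the phenotypic difference index

    PDI = (high parent mean - low parent mean) / low parent mean,

a dimensionless fraction.  Accessions are partitioned into gradient groups
with near-identical trait values (within-group PDI below ~5%) such that
adjacent groups differ by a small step (PDI roughly 8-25%).  One cross per
adjacent group pair yields a series of F2 gradient populations, each of
which is expected to segregate for very few (usually one) causal loci.

The minimum number of crosses needed to tile the collection's trait range
at a given PDI step is

    N = ceil( ((max - min) / min) / PDI_threshold ),

with a 20% default threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GradmapError, PhenotypeTable


@dataclass
class GradientGroup:
    """A set of accessions with near-identical trait means."""

    members: list[str]
    mean: float
    within_pdi: float  # (max member mean - min member mean) / min member mean

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CrossPlan:
    """One proposed gradient cross between adjacent groups."""

    parent_low: str
    parent_high: str
    mean_low: float
    mean_high: float
    pdi: float
    rank: int  # adjacency rank, 1 = lowest pair
    flag: str = ""  # non-empty when pdi falls outside the advised band


def compute_pdi(low_mean: float, high_mean: float) -> float:
    """Phenotypic difference index between two parental means.

    Swaps the arguments (with a warning) if given in the wrong order; the
    low mean must be positive because it is the denominator.
    """
    if high_mean < low_mean:
        warnings.warn("high_mean < low_mean; swapping parents")
        low_mean, high_mean = high_mean, low_mean
    if low_mean <= 0:
        raise GradmapError("PDI undefined: low parent mean must be > 0")
    return (high_mean - low_mean) / low_mean


def min_crosses(
    collection_min: float, collection_max: float, pdi_threshold: float = 0.20
) -> int:
    """Minimum number of gradient crosses to span a collection's trait range.

    Ceiling of the collection-wide PDI divided by the per-cross PDI
    threshold; never below 1.
    """
    if pdi_threshold <= 0 or pdi_threshold > 1:
        raise GradmapError(f"pdi_threshold must be in (0, 1], got {pdi_threshold}")
    if not (0 < collection_min <= collection_max):
        raise GradmapError("need collection_max >= collection_min > 0")
    n = compute_pdi(collection_min, collection_max) / pdi_threshold
    return max(1, math.ceil(n))


def group_gradient(
    table: PhenotypeTable,
    within_pdi: float = 0.05,
    between_pdi_range: tuple[float, float] = (0.08, 0.25),
) -> tuple[list[GradientGroup], pd.DataFrame]:
    """Partition a core collection into ordered gradient groups.

    Accessions are sorted by their replicate-mean phenotype and greedily
    agglomerated left to right while the group's spread (max vs min member
    mean, as a PDI) stays below ``within_pdi``.  Returns the ordered groups
    and a table of adjacent group-mean PDIs, flagged when outside
    ``between_pdi_range``.
    """
    means = table.means().dropna()
    if len(means) == 0:
        raise GradmapError("empty trait column: no accession has a finite mean")
    if (means <= 0).any():
        raise GradmapError("gradient grouping needs positive trait means (PDI denominators)")
    means = means.sort_values(kind="stable")

    groups: list[GradientGroup] = []
    cur: list[str] = []
    cur_min = math.nan
    for acc, m in means.items():
        if cur and (m - cur_min) / cur_min >= within_pdi:
            vals = means[cur]
            groups.append(GradientGroup(cur, float(vals.mean()), compute_pdi(vals.min(), vals.max())))
            cur = []
        if not cur:
            cur_min = float(m)
        cur.append(acc)
    vals = means[cur]
    groups.append(GradientGroup(cur, float(vals.mean()), compute_pdi(vals.min(), vals.max())))

    lo, hi = between_pdi_range
    rows = []
    for i in range(len(groups) - 1):
        pdi = compute_pdi(groups[i].mean, groups[i + 1].mean)
        rows.append(
            {
                "rank": i + 1,
                "mean_low": groups[i].mean,
                "mean_high": groups[i + 1].mean,
                "pdi": pdi,
                "flag": "" if lo <= pdi <= hi else "outside_advised_band",
            }
        )
    adjacency = pd.DataFrame(rows, columns=["rank", "mean_low", "mean_high", "pdi", "flag"])
    return groups, adjacency


def _shared_alleles(allele_table: pd.DataFrame, a: str, b: str) -> int:
    if a not in allele_table.index or b not in allele_table.index:
        return 0
    ra, rb = allele_table.loc[a], allele_table.loc[b]
    ok = ra.notna() & rb.notna()
    return int((ra[ok] == rb[ok]).sum())


def propose_crosses(
    groups: list[GradientGroup],
    table: PhenotypeTable,
    known_allele_table: pd.DataFrame | None = None,
    between_pdi_range: tuple[float, float] = (0.08, 0.25),
) -> list[CrossPlan]:
    """Propose one cross per adjacent gradient group pair.

    Without allele information each group is represented by the accession
    nearest its mean.  Given a known-gene allele table (accession x gene),
    the pair of representatives maximising the number of shared known-gene
    alleles is chosen for each adjacent pair, so segregation at already
    cloned loci is minimised; ties fall back to proximity to group means.
    """
    if len(groups) < 2:
        raise GradmapError("need >=2 gradient groups to propose crosses")
    means = table.means()
    lo, hi = between_pdi_range
    plans: list[CrossPlan] = []
    for i in range(len(groups) - 1):
        g_lo, g_hi = groups[i], groups[i + 1]
        if known_allele_table is None:
            p_lo = min(g_lo.members, key=lambda a: (abs(means[a] - g_lo.mean), a))
            p_hi = min(g_hi.members, key=lambda a: (abs(means[a] - g_hi.mean), a))
        else:
            best = None
            for a in g_lo.members:
                for b in g_hi.members:
                    score = (
                        -_shared_alleles(known_allele_table, a, b),
                        abs(means[a] - g_lo.mean) + abs(means[b] - g_hi.mean),
                        a,
                        b,
                    )
                    if best is None or score < best[0]:
                        best = (score, a, b)
            _, p_lo, p_hi = best
        m_lo, m_hi = float(means[p_lo]), float(means[p_hi])
        if m_hi < m_lo:  # representatives may invert the group order
            p_lo, p_hi, m_lo, m_hi = p_hi, p_lo, m_hi, m_lo
        pdi = compute_pdi(m_lo, m_hi)
        plans.append(
            CrossPlan(
                parent_low=p_lo,
                parent_high=p_hi,
                mean_low=m_lo,
                mean_high=m_hi,
                pdi=pdi,
                rank=i + 1,
                flag="" if lo <= pdi <= hi else "outside_advised_band",
            )
        )
    return plans


def crosses_to_frame(plans: list[CrossPlan]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": p.rank,
                "parent_low": p.parent_low,
                "parent_high": p.parent_high,
                "mean_low": p.mean_low,
                "mean_high": p.mean_high,
                "pdi": p.pdi,
                "flag": p.flag,
            }
            for p in plans
        ]
    )


def groups_to_frame(groups: list[GradientGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": i + 1,
                "mean": g.mean,
                "within_pdi": g.within_pdi,
                "n_members": len(g),
                "members": ",".join(g.members),
            }
            for i, g in enumerate(groups)
        ]
    )
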