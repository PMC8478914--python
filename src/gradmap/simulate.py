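"""Forward genetic simulation of gradient crosses.

Diploid individuals carry two haplotypes over a marker map, with alleles
coded by parent of origin (0 = low-value parent, 1 = high-value parent).
Meiosis places crossovers independently in each inter-marker interval with
Haldane recombination fractions r = (1 - exp(-2 d_Morgan)) / 2 (no
interference); chromosomes assort independently.

Phenotypes follow the Falconer single-locus convention: at each causal
locus the three genotypes contribute -a (low homozygote), d (heterozygote)
and +a (high homozygote) around the trait baseline, summed over loci, plus
Normal(0, sigma_e^2) environmental noise.  The verbal effect classes map
onto d/a: complete dominance d = +/-a, semi-dominance (additivity) d = 0,
over-dominance |d| > a.

Bulk sequencing is emulated with a Poisson total depth per marker and
binomial sampling of alternate-allele reads at the bulk's allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenotypeCallMatrix, GradmapError, MarkerMap, PhenotypeTable

__all__ = [
    "QTLocus",
    "Architecture",
    "Individual",
    "Population",
    "simulate_gamete",
    "phenotype",
    "phenotype_population",
    "cross",
    "self_population",
    "extract_nil_ll",
    "simulate_reads",
    "bulk_allele_freq",
    "genotype_calls",
    "f2_from_inbreds",
    "uniform_map",
]


@dataclass
class QTLocus:
    """A causal locus: additive effect a >= 0, dominance deviation d (signed).

    The locus must coincide with a marker position of the simulation map
    (use an ungenotyped pseudo-marker for loci between assay markers).
    """

    chrom: str
    pos_bp: int
    a: float
    d: float = 0.0
    high_parent: str = "P_high"

    def __post_init__(self) -> None:
        if self.a < 0:
            raise GradmapError("additive effect a must be >= 0")

    @property
    def effect_class(self) -> str:
        if self.a == 0:
            return "null"
        h = self.d / self.a
        if abs(h) > 1:
            return "over-dominant"
        if abs(abs(h) - 1) < 1e-9:
            return "complete-dominant"
        if abs(h) < 1e-9:
            return "semi-dominant"
        return "partial-dominant"


@dataclass
class Architecture:
    """The true multi-QTL genetic model driving a simulation."""

    mu: float
    sigma_e: float
    loci: list[QTLocus]
    mmap: MarkerMap

    def __post_init__(self) -> None:
        if self.sigma_e < 0:
            raise GradmapError("sigma_e must be >= 0")
        seen = set()
        for q in self.loci:
            key = (q.chrom, q.pos_bp)
            if key in seen:
                raise GradmapError(f"duplicate QTL position {key}")
            seen.add(key)

    def locus_indices(self) -> np.ndarray:
        """Marker-map index of each causal locus."""
        idx = []
        df = self.mmap.df
        for q in self.loci:
            hit = df.index[(df["chrom"] == q.chrom) & (df["pos_bp"] == q.pos_bp)]
            if len(hit) == 0:
                raise GradmapError(
                    f"QTL at {q.chrom}:{q.pos_bp} has no matching marker in the map"
                )
            idx.append(int(hit[0]))
        return np.array(idx, dtype=int)

    def to_toml(self, path) -> None:
        """Serialise the true parameters (flat TOML) for recovery tests."""
        with open(path, "w") as fh:
            fh.write("[architecture]\n")
            fh.write(f"mu = {self.mu}\nsigma_e = {self.sigma_e}\n\n")
            for q in self.loci:
                fh.write("[[architecture.loci]]\n")
                fh.write(f'chrom = "{q.chrom}"\npos_bp = {q.pos_bp}\n')
                fh.write(f"a = {q.a}\nd = {q.d}\nhigh_parent = \"{q.high_parent}\"\n\n")

    @classmethod
    def from_toml(cls, path, mmap: MarkerMap) -> "Architecture":
        import tomllib

        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)["architecture"]
        loci = [
            QTLocus(
                chrom=str(l["chrom"]),
                pos_bp=int(l["pos_bp"]),
                a=float(l["a"]),
                d=float(l["d"]),
                high_parent=str(l.get("high_parent", "P_high")),
            )
            for l in cfg.get("loci", [])
        ]
        return cls(mu=float(cfg["mu"]), sigma_e=float(cfg["sigma_e"]), loci=loci, mmap=mmap)


@dataclass
class Individual:
    """One diploid plant: two haplotypes over the marker map."""

    id: str
    hap1: np.ndarray  # int8, 0 = low-parent allele, 1 = high-parent allele
    hap2: np.ndarray
    generation: str = "F2"
    phenotype: float | None = None

    def dosage(self) -> np.ndarray:
        """High-allele count per marker (0, 1, 2)."""
        return (self.hap1 + self.hap2).astype(np.int8)


class Population:
    """A generation of individuals sharing one marker map.

    Backed by arrays (n x 2 x m haplotypes, n phenotypes) for speed;
    iterating yields :class:`Individual` views.
    """

    def __init__(
        self,
        label: str,
        mmap: MarkerMap,
        haps: np.ndarray,
        ids: list[str] | None = None,
        phenotypes: np.ndarray | None = None,
        provenance: dict | None = None,
    ):
        haps = np.asarray(haps, dtype=np.int8)
        if haps.ndim != 3 or haps.shape[1] != 2 or haps.shape[2] != len(mmap):
            raise GradmapError("haplotype array must be n x 2 x n_markers")
        if haps.shape[0] == 0:
            raise GradmapError("population must be non-empty")
        self.label = label
        self.mmap = mmap
        self.haps = haps
        self.ids = list(ids) if ids is not None else [f"{label}_{i+1}" for i in range(len(haps))]
        self.phenotypes = None if phenotypes is None else np.asarray(phenotypes, dtype=float)
        self.provenance = provenance or {}

    def __len__(self) -> int:
        return self.haps.shape[0]

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Individual:
        return Individual(
            id=self.ids[i],
            hap1=self.haps[i, 0],
            hap2=self.haps[i, 1],
            generation=self.label,
            phenotype=None if self.phenotypes is None else float(self.phenotypes[i]),
        )

    def dosage(self) -> np.ndarray:
        """n x m matrix of high-allele counts."""
        return self.haps.sum(axis=1, dtype=np.int16).astype(np.int8)

    def dosage_at(self, marker: str) -> np.ndarray:
        return self.dosage()[:, self.mmap.index_of(marker)]

    def phenotype_table(self, trait: str = "trait") -> PhenotypeTable:
        if self.phenotypes is None:
            raise GradmapError("population is not phenotyped")
        return PhenotypeTable(
            pd.DataFrame({"rep1": self.phenotypes}, index=pd.Index(self.ids, name="accession")),
            trait=trait,
        )


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _gametes_from(haps2: np.ndarray, mmap: MarkerMap, rng: np.random.Generator, n: int) -> np.ndarray:
    """n recombinant gametes from one parent's (2 x m) haplotype pair."""
    m = haps2.shape[1]
    if m == 1:
        phase = rng.integers(0, 2, size=(n, 1))
    else:
        r = mmap.recomb_fractions()
        start = rng.integers(0, 2, size=(n, 1))
        switch = rng.random((n, m - 1)) < r
        phase = (start + np.concatenate([np.zeros((n, 1), dtype=int), np.cumsum(switch, axis=1)], axis=1)) % 2
    return np.where(phase == 0, haps2[0], haps2[1]).astype(np.int8)


def simulate_gamete(parent: Individual, mmap: MarkerMap, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete (Haldane intervals, no interference)."""
    return _gametes_from(np.stack([parent.hap1, parent.hap2]), mmap, rng, 1)[0]


def cross(p1: Individual, p2: Individual, n: int, rng: np.random.Generator, mmap: MarkerMap) -> Population:
    """n F1 offspring, one gamete from each parent."""
    if n <= 0:
        raise GradmapError("cross needs n >= 1 offspring")
    if p1.hap1.shape != p2.hap1.shape or p1.hap1.shape[0] != len(mmap):
        raise GradmapError("parents must share the population's marker map")
    g1 = _gametes_from(np.stack([p1.hap1, p1.hap2]), mmap, rng, n)
    g2 = _gametes_from(np.stack([p2.hap1, p2.hap2]), mmap, rng, n)
    haps = np.stack([g1, g2], axis=1)
    return Population("F1", mmap, haps, provenance={"parents": (p1.id, p2.id)})


_NEXT_GEN = {"F1": "F2", "F2": "F3", "F3": "F4", "F4": "F5"}


def self_population(pop: Population, per_parent: int, rng: np.random.Generator) -> Population:
    """Self every individual; offspring take two independent gametes."""
    if per_parent <= 0:
        raise GradmapError("per_parent must be >= 1")
    out = []
    for i in range(len(pop)):
        g1 = _gametes_from(pop.haps[i], pop.mmap, rng, per_parent)
        g2 = _gametes_from(pop.haps[i], pop.mmap, rng, per_parent)
        out.append(np.stack([g1, g2], axis=1))
    haps = np.concatenate(out, axis=0)
    label = _NEXT_GEN.get(pop.label, pop.label + "_selfed")
    return Population(label, pop.mmap, haps, provenance={"parents": pop.ids, "selfed_from": pop.label})


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _genetic_values(dosage: np.ndarray, arch: Architecture) -> np.ndarray:
    idx = arch.locus_indices()
    g = np.zeros(dosage.shape[0])
    for k, q in zip(idx, arch.loci):
        dk = dosage[:, k]
        g += np.where(dk == 2, q.a, np.where(dk == 1, q.d, -q.a))
    return arch.mu + g


def phenotype(ind: Individual, arch: Architecture, rng: np.random.Generator) -> float:
    """Trait value of one individual under the architecture."""
    g = _genetic_values(ind.dosage()[None, :], arch)[0]
    return float(g + rng.normal(0.0, arch.sigma_e)) if arch.sigma_e > 0 else float(g)


def phenotype_population(pop: Population, arch: Architecture, rng: np.random.Generator) -> Population:
    """Assign trait values to every individual (in place; returns pop)."""
    g = _genetic_values(pop.dosage(), arch)
    if arch.sigma_e > 0:
        g = g + rng.normal(0.0, arch.sigma_e, size=len(pop))
    pop.phenotypes = g
    return pop


# ---------------------------------------------------------------------------
# NIL-LL extraction, read emission, call matrices
# ---------------------------------------------------------------------------

def extract_nil_ll(pop: Population, region: tuple[str, str]) -> Population | None:
    """Individuals heterozygous at both flanking markers of a QTL region.

    These are the near-isogenic-line-like lines whose selfed progeny supply
    fine-mapping recombinants.  Returns None (with a warning) if empty.
    """
    left, right = region
    if pop.mmap.chrom_of(left) != pop.mmap.chrom_of(right):
        raise GradmapError("NIL-LL flanking markers must be on one chromosome")
    dos = pop.dosage()
    keep = (dos[:, pop.mmap.index_of(left)] == 1) & (dos[:, pop.mmap.index_of(right)] == 1)
    if not keep.any():
        import warnings

        warnings.warn("no NIL-LL individuals (none heterozygous at both flanks)")
        return None
    sub = Population(
        pop.label + "_NIL-LL",
        pop.mmap,
        pop.haps[keep],
        ids=[i for i, k in zip(pop.ids, keep) if k],
        phenotypes=None if pop.phenotypes is None else pop.phenotypes[keep],
        provenance={"from": pop.label, "region": region},
    )
    return sub


def simulate_reads(
    bulk_allele_freq: np.ndarray, depth: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (ref_count, alt_count) for a pooled bulk.

    Total reads per marker ~ Poisson(depth); alternate reads ~ Binomial at
    the bulk's alternate-allele frequency.  No sequencing error by default.
    """
    f = np.asarray(bulk_allele_freq, dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise GradmapError("bulk allele frequencies must lie in [0, 1]")
    if depth <= 0:
        raise GradmapError("mean depth must be > 0")
    total = rng.poisson(depth, size=f.shape)
    alt = rng.binomial(total, f)
    return total - alt, alt


def bulk_allele_freq(pop: Population, member_idx: np.ndarray) -> np.ndarray:
    """High-parent (alternate) allele frequency per marker within a bulk."""
    return pop.dosage()[member_idx].mean(axis=0) / 2.0


def genotype_calls(pop: Population, markers: list[str] | None = None) -> GenotypeCallMatrix:
    """Convert true dosages to an A/H/B call matrix (no genotyping error)."""
    dos = pop.dosage()
    cols = pop.mmap.markers if markers is None else markers
    idx = [pop.mmap.index_of(m) for m in cols]
    sym = np.array([".", "B", "H", "A"])  # dosage -1 unused; 0->B, 1->H, 2->A
    calls = pd.DataFrame(
        sym[dos[:, idx] + 1], index=pd.Index(pop.ids, name="accession"), columns=cols
    )
    return GenotypeCallMatrix(calls)


# ---------------------------------------------------------------------------
# Convenience constructors
# ---------------------------------------------------------------------------

def uniform_map(
    n_markers: int,
    chrom: str = "chr1",
    spacing_bp: int = 100_000,
    cm_per_mb: float = 4.0,
    prefix: str = "M",
    start_bp: int = 1,
) -> MarkerMap:
    """Evenly spaced single-chromosome marker map (rice-like ~4 cM/Mb)."""
    pos = start_bp + spacing_bp * np.arange(n_markers)
    df = pd.DataFrame(
        {
            "marker": [f"{prefix}{i+1}" for i in range(n_markers)],
            "chrom": chrom,
            "pos_bp": pos.astype(int),
            "pos_cM": pos / 1e6 * cm_per_mb,
        }
    )
    return MarkerMap(df)


def inbred(mmap: MarkerMap, allele: int, id: str = "P") -> Individual:
    """Fully homozygous line carrying one parental allele everywhere."""
    h = np.full(len(mmap), allele, dtype=np.int8)
    return Individual(id=id, hap1=h.copy(), hap2=h.copy(), generation="P")


def f2_from_inbreds(
    arch: Architecture, n: int, rng: np.random.Generator, phenotyped: bool = True
) -> Population:
    """F2 gradient population from two fully inbred contrasting parents."""
    p_low = inbred(arch.mmap, 0, "P_low")
    p_high = inbred(arch.mmap, 1, "P_high")
    f1 = cross(p_low, p_high, 1, rng, arch.mmap)
    f2 = self_population(f1, n, rng)
    f2.ids = [f"F2_{i+1}" for i in range(n)]
    if phenotyped:
        phenotype_population(f2, arch, rng)
    return f2
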