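"""Synthetic study fixtures.

Everything the mapping pipeline consumes can be generated here from a
single seed: a phenotyped core collection segregating at a handful of
functional loci with domestication-graded allele frequencies, F2 gradient
populations with genotype-call matrices and bulk read counts, and grouped
population-genetic haplotypes/VCFs with a constructed sweep valley.  The
defaults emulate the rice grain-size study conditions: a 541-accession
core collection, eight functional genes explaining two-thirds of the
trait variance with one major gene, ~200-plant F2 populations, 15%
extreme bulks at 50x depth, and 100 kb/20 kb diversity windows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bsa import bulk_read_counts, make_bulks
from .io import (
    MarkerMap,
    PhenotypeTable,
    write_allele_table,
    write_genotype_calls,
    write_marker_map,
    write_phenotype_table,
    write_read_counts,
    write_vcf,
    GroupedGenotypes,
)
from .simulate import (
    Architecture,
    QTLocus,
    f2_from_inbreds,
    genotype_calls,
    uniform_map,
)
from .popgen import GroupedHaplotypes

# gene name, number of alleles, effect scale (trait units); the first gene is
# the major one, mirroring a grain-length-like architecture
GENE_PRESETS: list[tuple[str, int, float]] = [
    ("GS3", 6, 2.0),
    ("GW5", 3, 1.0),
    ("GL7", 3, 0.7),
    ("GW7", 2, 0.55),
    ("GW8", 2, 0.45),
    ("GL1", 3, 0.4),
    ("GS2", 2, 0.3),
    ("GW5_1", 2, 0.3),
]

GROUP_FRACTIONS = {"wild": 0.15, "landrace": 0.55, "cultivar": 0.30}
# favoured (high-value) allele frequency along the domestication axis
FAVORED_FREQ = {"wild": 0.12, "landrace": 0.45, "cultivar": 0.80}


def simulate_core_collection(
    n: int = 541,
    h2: float = 0.67,
    seed: int | np.random.Generator = 0,
    genes: list[tuple[str, int, float]] | None = None,
    baseline: float = 8.0,
    replicates: int = 3,
    measurement_sd: float = 0.02,
):
    """A phenotyped core collection segregating at functional loci.

    Each accession draws one allele per gene with group-dependent
    frequencies (the favoured, highest-effect allele accumulates from wild
    to landrace to cultivar); the environmental SD is set so the realised
    genetic values explain ``h2`` of the trait variance.

    Returns ``(alleles, phenotypes, truth)``: an accession x gene allele
    frame, a :class:`PhenotypeTable` with group labels, and a dict with the
    generating allele effects, sigma_e and per-accession genetic values.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = GENE_PRESETS if genes is None else genes
    groups = rng.choice(
        list(GROUP_FRACTIONS), size=n, p=list(GROUP_FRACTIONS.values())
    )
    ids = [f"ACC{i+1:04d}" for i in range(n)]
    alleles = pd.DataFrame(index=pd.Index(ids, name="accession"))
    g_val = np.zeros(n)
    effects: dict[str, dict[str, float]] = {}
    for gene, k, scale in genes:
        labels = [f"{gene}-{j+1}" for j in range(k)]
        eff = np.sort(rng.normal(0.0, scale, size=k))
        effects[gene] = dict(zip(labels, eff))
        favored = labels[-1]  # highest-effect allele is the selected one
        calls = np.empty(n, dtype=object)
        for grp in GROUP_FRACTIONS:
            m = groups == grp
            p_fav = FAVORED_FREQ[grp]
            rest = rng.dirichlet(np.ones(k - 1)) * (1 - p_fav)
            probs = np.append(rest, p_fav)
            calls[m] = rng.choice(labels, size=m.sum(), p=probs)
        alleles[gene] = calls
        g_val += np.vectorize(effects[gene].get)(calls)
    var_g = g_val.var()
    sigma_e = float(np.sqrt(var_g * (1 - h2) / h2))
    trait = baseline + g_val + rng.normal(0.0, sigma_e, size=n)
    values = pd.DataFrame(
        {
            f"rep{r+1}": trait + rng.normal(0.0, measurement_sd, size=n)
            for r in range(replicates)
        },
        index=alleles.index,
    )
    table = PhenotypeTable(values, group_label=pd.Series(groups, index=alleles.index), trait="grain_length")
    truth = {"h2": h2, "sigma_e": sigma_e, "effects": effects, "genetic_values": g_val}
    return alleles, table, truth


def single_locus_architecture(
    a: float = 1.0,
    d: float = 0.0,
    sigma_e: float = 0.0,
    mu: float = 8.0,
    n_markers: int = 21,
    qtl_index: int = 10,
    spacing_bp: int = 100_000,
    chrom: str = "chr3",
) -> Architecture:
    """One-QTL architecture on an evenly spaced single-chromosome map."""
    mmap = uniform_map(n_markers, chrom=chrom, spacing_bp=spacing_bp)
    q = QTLocus(
        chrom=chrom,
        pos_bp=int(mmap.df.loc[qtl_index, "pos_bp"]),
        a=a,
        d=d,
    )
    return Architecture(mu=mu, sigma_e=sigma_e, loci=[q], mmap=mmap)


def sigma_e_for_pve(a: float, d: float, pve: float) -> float:
    """Environmental SD giving a target single-locus F2 PVE.

    The F2 genotypic variance at one locus is a^2/2 + d^2/4 (Falconer
    decomposition); sigma_e scales the residual share accordingly.
    """
    var_g = a**2 / 2.0 + d**2 / 4.0
    if not 0 < pve <= 1:
        raise ValueError("pve must be in (0, 1]")
    return float(np.sqrt(var_g * (1 - pve) / pve)) if pve < 1 else 0.0


def simulate_sweep_haplotypes(
    n_per_class: int = 60,
    span_bp: int = 1_000_000,
    spacing_bp: int = 400,
    focal_pos: int = 500_000,
    valley: tuple[int, int] | None = (350_000, 650_000),
    suppression: float = 0.10,
    seed: int | np.random.Generator = 0,
    labels: tuple[str, str] = ("favored", "unfavored"),
) -> GroupedHaplotypes:
    """Two allele-class haplotype panels with a constructed sweep valley.

    Site frequencies are uniform in (0.1, 0.5); within ``valley`` the
    favoured class's per-site heterozygosity is suppressed to
    ``suppression`` of the unfavoured class's (no valley when None).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.arange(1, span_bp + 1, spacing_bp, dtype=np.int64)
    p = rng.uniform(0.1, 0.5, size=len(pos))
    p_fav = p.copy()
    if valley is not None:
        inside = (pos >= valley[0]) & (pos <= valley[1])
        het = p[inside] * (1 - p[inside])
        p_fav[inside] = (1 - np.sqrt(1 - 4 * suppression * het)) / 2
    fav = (rng.random((n_per_class, len(pos))) < p_fav).astype(np.int8)
    unf = (rng.random((n_per_class, len(pos))) < p).astype(np.int8)
    haps = np.vstack([fav, unf])
    groups = np.array([labels[0]] * n_per_class + [labels[1]] * n_per_class, dtype=object)
    return GroupedHaplotypes(haps, groups, pos, chrom="chr3")


def simulate_grouped_genotypes(
    n_per_group: dict[str, int] | None = None,
    span_bp: int = 600_000,
    spacing_bp: int = 1_000,
    diversity_scale: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr5",
) -> GroupedGenotypes:
    """Diploid grouped genotypes with group-graded diversity (for VCF I/O).

    Each group's per-site heterozygosity is the base level times its
    ``diversity_scale`` entry, emulating diversity loss along the
    domestication axis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_per_group = n_per_group or {"wild": 30, "landrace": 40, "cultivar": 30}
    diversity_scale = diversity_scale or {"wild": 1.0, "landrace": 0.7, "cultivar": 0.35}
    pos = np.arange(1, span_bp + 1, spacing_bp, dtype=np.int64)
    p = rng.uniform(0.1, 0.5, size=len(pos))
    samples, groups, rows = [], [], []
    for grp, n in n_per_group.items():
        s = diversity_scale[grp]
        het = p * (1 - p)
        pg = (1 - np.sqrt(np.clip(1 - 4 * s * het, 0, 1))) / 2
        dos = (
            (rng.random((n, len(pos))) < pg).astype(np.int8)
            + (rng.random((n, len(pos))) < pg).astype(np.int8)
        )
        rows.append(dos)
        samples += [f"{grp[:4].upper()}{i+1:03d}" for i in range(n)]
        groups += [grp] * n
    return GroupedGenotypes(
        samples=samples,
        groups=groups,
        chrom=np.array([chrom] * len(pos)),
        pos=pos,
        dosage=np.vstack(rows),
    )


def make_fixture_suite(outdir: str | Path, seed: int = 0, config: dict | None = None) -> dict:
    """Write the full synthetic input suite to ``outdir``; returns file paths.

    Products: (a) core-collection phenotypes and functional-marker alleles,
    (b) an F2 gradient population (marker map, phenotypes, genotype calls,
    true architecture), (c) extreme-bulk read counts, (d) a grouped VCF plus
    group table for the population-genetic scans.  Deterministic by seed.
    """
    cfg = config or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    r_core, r_f2, r_reads, r_pop = [np.random.default_rng(s) for s in ss.spawn(4)]

    paths: dict[str, Path] = {}

    # (a) core collection
    alleles, table, truth = simulate_core_collection(
        n=int(cfg.get("n_accessions", 541)), h2=float(cfg.get("h2", 0.67)), seed=r_core
    )
    paths["core_phenotypes"] = outdir / "core_phenotypes.tsv"
    paths["core_alleles"] = outdir / "core_alleles.tsv"
    write_phenotype_table(table, paths["core_phenotypes"])
    write_allele_table(alleles, paths["core_alleles"])

    # (b) one F2 gradient population under a single semi-dominant QTL
    arch = single_locus_architecture(
        a=float(cfg.get("a", 1.0)),
        d=float(cfg.get("d", 0.0)),
        sigma_e=float(cfg.get("sigma_e", sigma_e_for_pve(1.0, 0.0, 0.85))),
    )
    f2 = f2_from_inbreds(arch, int(cfg.get("n_f2", 200)), r_f2)
    paths["f2_map"] = outdir / "f2gp_map.tsv"
    paths["f2_phenotypes"] = outdir / "f2gp_phenotypes.tsv"
    paths["f2_calls"] = outdir / "f2gp_calls.tsv"
    paths["architecture"] = outdir / "f2gp_architecture.toml"
    write_marker_map(arch.mmap, paths["f2_map"])
    write_phenotype_table(f2.phenotype_table(), paths["f2_phenotypes"])
    write_genotype_calls(genotype_calls(f2), paths["f2_calls"])
    arch.to_toml(paths["architecture"])

    # (c) bulk read counts from the two phenotype extremes
    bulks = make_bulks(f2, fraction=float(cfg.get("bulk_fraction", 0.15)), min_size=int(cfg.get("bulk_min", 30)))
    counts = bulk_read_counts(f2, bulks, depth=float(cfg.get("depth", 50.0)), rng=r_reads)
    paths["read_counts"] = outdir / "f2gp_readcounts.tsv"
    write_read_counts(counts, paths["read_counts"])

    # (d) grouped VCF for the diversity scans
    geno = simulate_grouped_genotypes(seed=r_pop)
    paths["vcf"] = outdir / "popgen.vcf"
    paths["groups"] = outdir / "popgen_groups.tsv"
    write_vcf(paths["vcf"], geno.samples, geno.chrom, geno.pos, geno.dosage)
    pd.DataFrame({"accession": geno.samples, "group": geno.groups}).to_csv(
        paths["groups"], sep="\t", index=False
    )

    with open(outdir / "SEED.txt", "w") as fh:
        fh.write(f"{seed}\n")
    return {k: str(v) for k, v in paths.items()}
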