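"""Tabular and VCF input/output.

All files are tab-separated UTF-8 text with a header line; lines starting
with ``#`` are comments.  Coordinates are 1-based inclusive base pairs
throughout (VCF convention); candidate regions exported as BED are converted
to 0-based half-open on the way out.  The missing genotype symbol in call
matrices is ``.``.

No science lives here: every function either parses, validates or
serialises one of the package's domain tables.
"""

from __future__ import annotations

import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("gradmap")

CALL_ALPHABET = frozenset({"A", "B", "H", "."})


class GradmapError(ValueError):
    """Raised on malformed or inconsistent input."""


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Replicated phenotype measurements for a set of accessions.

    ``values`` is an accession x replicate frame (float, trait units);
    ``group_label`` optionally tags each accession (e.g. wild / landrace /
    cultivar, or free text).
    """

    values: pd.DataFrame
    group_label: pd.Series | None = None
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise GradmapError(f"duplicate accession id: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).any(axis=1).all():
            bad = self.values.index[
                ~np.isfinite(self.values.to_numpy(dtype=float)).any(axis=1)
            ][0]
            raise GradmapError(f"accession {bad!r} has no finite trait value")

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    def means(self) -> pd.Series:
        """Per-accession mean over replicates (the unit all PDI logic uses)."""
        return self.values.mean(axis=1)

    def __len__(self) -> int:
        return len(self.values)


def read_phenotype_table(path: str | Path, trait: str = "trait") -> PhenotypeTable:
    """Read a phenotype TSV: first column accession id, then replicate columns.

    A column named ``group`` (or ``group_label``) is treated as the accession
    label, every other column as a numeric trait replicate, order preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise GradmapError(f"{path}: need an id column plus >=1 trait column")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise GradmapError(f"{path}: duplicate accession id: {dup!r}")
    df = df.set_index(id_col)
    group = None
    for g in ("group", "group_label"):
        if g in df.columns:
            group = df.pop(g)
            break
    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        cell = df[col]
        empty = cell.isna() | (cell.str.strip() == "")
        if empty.any():
            row = cell.index[empty][0]
            raise GradmapError(f"{path}: empty trait cell at row {row!r}, column {col!r}")
        try:
            values[col] = cell.astype(float)
        except ValueError:
            bad = cell.index[pd.to_numeric(cell, errors="coerce").isna()][0]
            raise GradmapError(
                f"{path}: non-numeric trait cell at row {bad!r}, column {col!r}"
            ) from None
    return PhenotypeTable(values=values, group_label=group, trait=trait)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    df = table.values.copy()
    if table.group_label is not None:
        df["group"] = table.group_label
    df.index.name = "accession"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Marker maps
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered marker positions: physical (bp, 1-based) and genetic (cM).

    Within a chromosome bp must strictly increase and cM must not decrease.
    """

    df: pd.DataFrame  # columns: marker, chrom, pos_bp, pos_cM

    def __post_init__(self) -> None:
        need = ["marker", "chrom", "pos_bp", "pos_cM"]
        if list(self.df.columns[:4]) != need:
            raise GradmapError(f"marker map needs columns {need}")
        if self.df["marker"].duplicated().any():
            dup = self.df["marker"][self.df["marker"].duplicated()].iloc[0]
            raise GradmapError(f"duplicate marker name: {dup!r}")
        if (self.df["pos_bp"] <= 0).any():
            raise GradmapError("marker positions must be positive 1-based bp")
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if not sub["pos_bp"].is_monotonic_increasing or sub["pos_bp"].duplicated().any():
                raise GradmapError(f"{chrom}: bp positions must strictly increase")
            if not sub["pos_cM"].is_monotonic_increasing:
                raise GradmapError(f"{chrom}: cM positions must be non-decreasing")
        self.df = self.df.reset_index(drop=True)

    @property
    def markers(self) -> list[str]:
        return list(self.df["marker"])

    def __len__(self) -> int:
        return len(self.df)

    def index_of(self, marker: str) -> int:
        hit = np.flatnonzero(self.df["marker"].to_numpy() == marker)
        if hit.size == 0:
            raise GradmapError(f"marker {marker!r} not in map")
        return int(hit[0])

    def chrom_of(self, marker: str) -> str:
        return str(self.df.loc[self.index_of(marker), "chrom"])

    def recomb_fractions(self) -> np.ndarray:
        """Haldane recombination fraction per adjacent marker interval.

        r = (1 - exp(-2 d_Morgan)) / 2 within a chromosome; 0.5 across
        chromosome boundaries (independent assortment).
        """
        cm = self.df["pos_cM"].to_numpy(dtype=float)
        chrom = self.df["chrom"].to_numpy()
        d = np.diff(cm) / 100.0
        r = (1.0 - np.exp(-2.0 * d)) / 2.0
        r[chrom[1:] != chrom[:-1]] = 0.5
        return r

    def subset(self, markers: list[str]) -> "MarkerMap":
        keep = self.df[self.df["marker"].isin(markers)]
        return MarkerMap(keep.reset_index(drop=True))


def haldane(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: cM distance -> recombination fraction."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["pos_bp"] = df["pos_bp"].astype(int)
    df["pos_cM"] = df["pos_cM"].astype(float)
    df["marker"] = df["marker"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    return MarkerMap(df)


def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    mmap.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype call matrices (A / B / H / .)
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCallMatrix:
    """Accessions x markers matrix of calls in {A, B, H, .}.

    A = high-value-parent homozygote, B = low-value-parent homozygote,
    H = heterozygote, '.' = missing.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        seen = set(np.unique(self.calls.to_numpy(dtype=str)))
        bad = seen - CALL_ALPHABET
        if bad:
            raise GradmapError(f"invalid genotype call symbols: {sorted(bad)}")

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    def column(self, marker: str) -> pd.Series:
        if marker not in self.calls.columns:
            raise GradmapError(f"marker {marker!r} not genotyped")
        return self.calls[marker]


def read_genotype_calls(path: str | Path) -> GenotypeCallMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)
    return GenotypeCallMatrix(df)


def write_genotype_calls(mat: GenotypeCallMatrix, path: str | Path) -> None:
    out = mat.calls.copy()
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Bulk read counts
# ---------------------------------------------------------------------------

def read_read_counts(path: str | Path) -> pd.DataFrame:
    """Read a bulk read-count TSV: marker, bulk, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"marker", "bulk", "ref_count", "alt_count"}
    if not need.issubset(df.columns):
        raise GradmapError(f"{path}: read-count table needs columns {sorted(need)}")
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise GradmapError(f"{path}: negative read counts")
    return df


def write_read_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Functional-marker allele tables
# ---------------------------------------------------------------------------

def read_allele_table(path: str | Path) -> pd.DataFrame:
    """Long-format allele table (accession, gene, allele) -> wide frame.

    Returns an accession x gene frame of allele labels (NaN for missing).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"accession", "gene", "allele"}
    if not need.issubset(df.columns):
        raise GradmapError(f"{path}: allele table needs columns {sorted(need)}")
    wide = df.pivot(index="accession", columns="gene", values="allele")
    wide.columns.name = None
    return wide


def write_allele_table(wide: pd.DataFrame, path: str | Path) -> None:
    long = wide.stack().rename("allele").reset_index()
    long.columns = ["accession", "gene", "allele"]
    long.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class GroupedGenotypes:
    """Biallelic diploid dosages with a group label per sample.

    ``dosage`` is samples x sites (0/1/2 alt-allele count, -1 missing).
    """

    samples: list[str]
    groups: list[str]
    chrom: np.ndarray
    pos: np.ndarray       # 1-based bp
    dosage: np.ndarray    # int8, samples x sites


def read_genotype_vcf(
    path: str | Path,
    sample_groups: dict[str, str] | None = None,
    multiallelic: str = "drop",
) -> GroupedGenotypes:
    """Read a diploid VCF into a grouped biallelic dosage matrix.

    Multi-allelic records are dropped (default) or split into one biallelic
    pseudo-site per alternate allele (``multiallelic="split"``).  Samples not
    present in ``sample_groups`` are labelled ``"ungrouped"``; mapped samples
    absent from the VCF trigger a warning and are skipped.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "split"):
        raise GradmapError(f"multiallelic must be 'drop' or 'split', got {multiallelic!r}")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    sample_groups = dict(sample_groups or {})
    for s in set(sample_groups) - set(samples):
        warnings.warn(f"sample {s!r} in group mapping absent from VCF; skipped")
    groups = [sample_groups.get(s, "ungrouped") for s in samples]

    chroms: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if rec.genotypes is None:
            raise GradmapError(f"{path}: record without GT at {rec.CHROM}:{rec.POS}")
        alts = rec.ALT
        if len(alts) != 1:
            if multiallelic == "drop":
                continue
            gts = np.array([g[:2] for g in rec.genotypes], dtype=int)
            for ai in range(1, len(alts) + 1):
                dos = (gts == ai).sum(axis=1).astype(np.int8)
                dos[(gts < 0).any(axis=1)] = -1
                chroms.append(rec.CHROM)
                pos.append(rec.POS)
                rows.append(dos)
            continue
        gts = np.array([g[:2] for g in rec.genotypes], dtype=int)
        dos = (gts == 1).sum(axis=1).astype(np.int8)
        dos[(gts < 0).any(axis=1)] = -1
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        rows.append(dos)
    if not rows:
        raise GradmapError(f"{path}: no usable biallelic sites")
    return GroupedGenotypes(
        samples=samples,
        groups=groups,
        chrom=np.array(chroms),
        pos=np.array(pos, dtype=np.int64),
        dosage=np.stack(rows, axis=1),
    )


def write_vcf(
    path: str | Path,
    samples: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    dosage: np.ndarray,
    ref: str = "A",
    alt: str = "T",
) -> None:
    """Write unphased diploid genotypes as a minimal VCF v4.2 text file."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(np.asarray(chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(len(pos)):
            calls = "\t".join(gt_str[int(d)] for d in dosage[:, j])
            fh.write(f"{chrom[j]}\t{int(pos[j])}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n")


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (accession, group) into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Config, BED, logging
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions (chrom, start_bp, end_bp 1-based inclusive) as BED.

    BED is 0-based half-open, so start shifts down by one.
    """
    out = regions.copy()
    out["start_bp"] = out["start_bp"].astype(int) - 1
    out["end_bp"] = out["end_bp"].astype(int)
    out[["chrom", "start_bp", "end_bp"]].to_csv(path, sep="\t", index=False, header=False)


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
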