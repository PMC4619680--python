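"""Readers, writers and shared preprocessing.

Genotypes are held as an accessions x SNPs score matrix (haploid/inbred
{0,1} coding by default, {0,1,2} accepted) with per-SNP chromosome and
1-based position metadata.  Gene annotations are canonicalized to 1-based
inclusive coordinates whatever the input dialect (GFF3 or BED).  Trait and
environmental columns are standardized on a declared fitting set so that
unphenotyped accessions end up on the fitted scale.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AccessionTable",
    "GeneAnnotation",
    "ColumnScaler",
    "read_genotypes",
    "write_genotypes",
    "read_annotation",
    "standardize_columns",
    "pc1_trait",
]


class GenotypeParseError(ValueError):
    """Malformed genotype file (row length, allele coding...)."""


class CoordinateError(ValueError):
    """Inconsistent genomic coordinates."""


@dataclass
class GenotypeMatrix:
    """n accessions x m biallelic SNPs with genomic coordinates.

    ``scores`` is a float array so that missing calls can be held as NaN;
    non-missing entries must lie in {0, 1} (haploid/inbred) or {0, 1, 2}
    (diploid dosage), declared via ``coding``.
    """

    accession_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    scores: np.ndarray
    coding: str = "01"  # "01" or "012"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=int)
        n, m = self.scores.shape
        if n != len(self.accession_ids) or m != len(self.snp_ids):
            raise ValueError("score matrix shape inconsistent with id lists")
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("per-SNP metadata length != number of SNPs")
        allowed = {0.0, 1.0} if self.coding == "01" else {0.0, 1.0, 2.0}
        vals = set(np.unique(self.scores[~np.isnan(self.scores)]))
        if not vals <= allowed:
            raise GenotypeParseError(
                f"scores contain values {sorted(vals - allowed)} outside coding {self.coding!r}"
            )
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise CoordinateError(f"positions not strictly increasing on {c}")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    def missing_fraction(self) -> float:
        return float(np.isnan(self.scores).mean())

    def snp_missing_fraction(self) -> np.ndarray:
        return np.isnan(self.scores).mean(axis=0)

    def monomorphic(self) -> np.ndarray:
        """Boolean mask of SNPs with at most one observed allele state."""
        out = np.zeros(self.m, dtype=bool)
        for j in range(self.m):
            col = self.scores[:, j]
            out[j] = len(np.unique(col[~np.isnan(col)])) <= 1
        return out

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (missing ignored)."""
        max_dose = 1.0 if self.coding == "01" else 2.0
        freq = np.nanmean(self.scores, axis=0) / max_dose
        return np.minimum(freq, 1.0 - freq)

    def imputed_scores(self) -> np.ndarray:
        """Scores with per-SNP mean imputation of missing calls."""
        X = self.scores.copy()
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = mu[idx[1]]
        return X


@dataclass
class AccessionTable:
    """Accession-level table: observed trait(s), environmental columns, coords."""

    data: pd.DataFrame
    trait_cols: list[str] = field(default_factory=list)
    env_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.data["accession_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicated accession id {dup!r}")
        if len(set(self.env_cols)) != len(self.env_cols):
            raise ValueError("environmental column names not unique")
        self.data = self.data.copy()
        self.data["accession_id"] = ids

    @property
    def accession_ids(self) -> list[str]:
        return self.data["accession_id"].tolist()

    def env_matrix(self) -> np.ndarray:
        return self.data[self.env_cols].to_numpy(dtype=float)

    def traits(self) -> np.ndarray:
        return self.data[self.trait_cols].to_numpy(dtype=float)


@dataclass
class GeneAnnotation:
    """Gene records with canonical 1-based inclusive coordinates."""

    table: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            dup = t["gene_id"][t["gene_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if (t["start"] > t["end"]).any():
            bad = t[t["start"] > t["end"]].iloc[0]
            raise CoordinateError(f"gene {bad['gene_id']} has start > end")
        self.table = t.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(
    path: str,
    format_tag: str = "delimited",
    map_path: str | None = None,
    coding: str = "01",
    sep: str = ",",
) -> GenotypeMatrix:
    """Read a genotype matrix.

    ``delimited``: header row of SNP ids, first column the accession id,
    missing entries "NA".  SNP coordinates come from ``map_path`` (columns
    snp_id, chrom, pos); without a map, SNPs are placed consecutively on
    chromosome "1".

    ``plink_text``: PLINK-style .ped/.map text; ``path`` is the .ped file and
    ``map_path`` (default: same stem with .map) supplies coordinates.  Alleles
    A/B are counted as dosage of B; "0 0" is missing.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format_tag == "delimited":
        return _read_delimited(path, map_path, coding, sep)
    if format_tag == "plink_text":
        return _read_plink_text(path, map_path, coding)
    raise ValueError(f"unknown genotype format {format_tag!r}")


def _read_delimited(path, map_path, coding, sep) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        snp_ids = header[1:]
        acc, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(sep)
            if len(parts) != len(header):
                raise GenotypeParseError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {len(header)}"
                )
            acc.append(parts[0])
            try:
                rows.append([np.nan if v == "NA" else float(v) for v in parts[1:]])
            except ValueError as e:
                raise GenotypeParseError(f"{path}: line {lineno}: {e}") from None
    scores = np.asarray(rows, dtype=float)
    chrom, pos = _load_map(map_path, snp_ids)
    return GenotypeMatrix(acc, snp_ids, chrom, pos, scores, coding=coding)


def _load_map(map_path, snp_ids):
    if map_path is None:
        return np.array(["1"] * len(snp_ids), dtype=object), np.arange(1, len(snp_ids) + 1)
    m = pd.read_csv(map_path, sep=None, engine="python", dtype={"snp_id": str, "chrom": str})
    m = m.set_index("snp_id").loc[snp_ids]
    return m["chrom"].to_numpy(dtype=object), m["pos"].to_numpy(dtype=int)


def _read_plink_text(path, map_path, coding) -> GenotypeMatrix:
    if map_path is None:
        map_path = os.path.splitext(path)[0] + ".map"
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    acc, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(mp):
                raise GenotypeParseError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {6 + 2 * len(mp)}"
                )
            acc.append(parts[1])  # IID
            alleles = parts[6:]
            row = []
            for a1, a2 in zip(alleles[::2], alleles[1::2]):
                if a1 == "0" or a2 == "0":
                    row.append(np.nan)
                else:
                    for a in (a1, a2):
                        if a not in ("A", "B"):
                            raise GenotypeParseError(
                                f"{path}: line {lineno}: unknown allele code {a!r}"
                            )
                    dose = (a1 == "B") + (a2 == "B")
                    row.append(dose if coding == "012" else min(dose, 1))
            rows.append(row)
    scores = np.asarray(rows, dtype=float)
    return GenotypeMatrix(
        acc, mp["snp_id"].tolist(), mp["chrom"].to_numpy(dtype=object),
        mp["pos"].to_numpy(dtype=int), scores, coding=coding,
    )


def write_genotypes(G: GenotypeMatrix, path: str, map_path: str | None = None, sep: str = ",") -> None:
    """Write the delimited dialect (and optionally the SNP map)."""
    with open(path, "w") as fh:
        fh.write(sep.join(["accession_id"] + G.snp_ids) + "\n")
        for i, a in enumerate(G.accession_ids):
            vals = [
                "NA" if np.isnan(v) else str(int(v)) for v in G.scores[i]
            ]
            fh.write(sep.join([a] + vals) + "\n")
    if map_path is not None:
        pd.DataFrame({"snp_id": G.snp_ids, "chrom": G.chrom, "pos": G.pos}).to_csv(
            map_path, index=False
        )


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotation(path: str, format_tag: str | None = None) -> GeneAnnotation:
    """Read gene records from GFF3 (type == gene) or BED4.

    BED's half-open 0-based intervals are converted to 1-based inclusive.
    """
    if format_tag is None:
        format_tag = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    if format_tag == "gff3":
        return _read_gff3(path)
    if format_tag == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {format_tag!r}")


def _read_gff3(path) -> GeneAnnotation:
    import gffutils

    with tempfile.TemporaryDirectory() as td:
        db = gffutils.create_db(
            path, os.path.join(td, "ann.db"), force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        recs = []
        for g in db.features_of_type("gene"):
            gid = g.attributes.get("ID", [g.id])[0]
            recs.append((gid, g.seqid, g.start, g.end, g.strand or "."))
    return GeneAnnotation(pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end", "strand"]))


def _read_bed(path) -> GeneAnnotation:
    t = pd.read_csv(
        path, sep=r"\s+", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start0", "end0", "gene_id"], dtype={"chrom": str, "gene_id": str},
    )
    out = pd.DataFrame(
        {
            "gene_id": t["gene_id"],
            "chrom": t["chrom"],
            "start": t["start0"] + 1,  # 0-based half-open -> 1-based inclusive
            "end": t["end0"],
            "strand": ".",
        }
    )
    return GeneAnnotation(out)


# ---------------------------------------------------------------------------
# standardization and trait preprocessing


@dataclass
class ColumnScaler:
    """Per-column mean/SD learned on a fitting set, applied anywhere."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[self.columns] = (df[self.columns] - self.mean) / self.sd
        return out

    def transform_array(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def standardize_columns(
    table: AccessionTable, columns: list[str], fit_ids: list[str] | None = None
) -> tuple[AccessionTable, ColumnScaler]:
    """Center/scale ``columns`` using mean and SD computed on ``fit_ids`` only.

    The same affine map is applied to every row, so held-out accessions are
    expressed on the fitting-set scale.  SD uses denominator n (population
    convention); a zero-variance column on the fitting set is an error.
    """
    df = table.data
    if fit_ids is None:
        fit_ids = table.accession_ids
    mask = df["accession_id"].isin(set(map(str, fit_ids)))
    if not mask.any():
        raise ValueError("fit_ids do not intersect the table")
    sub = df.loc[mask, columns].to_numpy(dtype=float)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0)
    for c, s in zip(columns, sd):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {c!r} has zero variance on the fitting set")
    scaler = ColumnScaler(list(columns), mean, sd)
    out = AccessionTable(scaler.transform(df), table.trait_cols, table.env_cols)
    return out, scaler


def pc1_trait(traits: np.ndarray, use_correlation: bool = True) -> tuple[np.ndarray, float]:
    """First principal component of a multi-trait matrix.

    Used to reduce replicate trait measurements (e.g. the same phenotype
    scored under several conditions) to a single axis.  Columns are
    standardized (correlation-matrix PCA) by default.  The sign is fixed so
    the loading vector has positive sum.  Returns (scores, fraction of
    variance explained by PC1).
    """
    Y = np.asarray(traits, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need an n x t matrix with t >= 2")
    if np.isnan(Y).any():
        raise ValueError("missing values not allowed; drop incomplete accessions first")
    Yc = Y - Y.mean(axis=0)
    if use_correlation:
        sd = Yc.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant trait column")
        Yc = Yc / sd
    cov = Yc.T @ Yc / Yc.shape[0]
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    load = V[:, 0]
    if load.sum() < 0:
        load = -load
    return Yc @ load, float(w[0] / w.sum())
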