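"""Readers, writers and shared domain types.

All genomic positions are 1-based (VCF convention) and intervals are
inclusive on both ends.  Dosages count copies of the effect allele ``a1``
(for VCF input the ALT allele) and live in [0, 2]; missing dosages are
``NaN`` and are never imputed.  Summary-statistics tables use the
GCTA ``.ma``-style tab-separated dialect with CHR/BP added::

    SNP  CHR  BP  A1  A2  FREQ  BETA  SE  P  N
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "GeneAnnotation",
    "CellCountMatrix",
    "SummaryStatsTable",
    "PhasedAlleleCounts",
    "CovariateTable",
    "read_genotypes",
    "write_genotypes",
    "read_counts",
    "write_counts",
    "read_sumstats",
    "write_sumstats",
    "read_annotation",
    "write_annotation",
    "read_covariates",
    "write_covariates",
    "read_allele_counts",
    "write_allele_counts",
    "harmonize_alleles",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SUMSTATS_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "eaf", "beta", "se", "p", "n"]
_SUMSTATS_HEADER = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N"]

#: accepted column-name synonyms for summary-statistics input (lower-cased)
SUMSTATS_SYNONYMS: dict[str, str] = {
    "snp": "snp", "rsid": "snp", "variant_id": "snp", "id": "snp", "markername": "snp",
    "chr": "chrom", "chrom": "chrom", "chromosome": "chrom",
    "bp": "pos", "pos": "pos", "position": "pos", "base_pair_location": "pos",
    "a1": "a1", "effect_allele": "a1", "alt": "a1",
    "a2": "a2", "other_allele": "a2", "ref": "a2",
    "freq": "eaf", "eaf": "eaf", "af": "eaf", "effect_allele_frequency": "eaf", "maf": "eaf",
    "beta": "beta", "b": "beta", "effect": "beta",
    "se": "se", "standard_error": "se", "stderr": "se",
    "p": "p", "pval": "p", "pvalue": "p", "p_value": "p",
    "n": "n", "samplesize": "n", "n_total": "n",
}


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic variant; ``a1`` is the effect (counted) allele."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    eaf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1 (got {self.pos})")
        if self.a1 == self.a2:
            raise ValueError(f"{self.id}: a1 and a2 are identical ({self.a1})")
        if np.isfinite(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.id}: eaf {self.eaf} outside [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.a1) == self.a2


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix with variant metadata."""

    subjects: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicated subject ids")
        ids = self.variant_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated variant ids")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise ValueError(f"{bad} dosages outside [0, 2]")

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_ids.index(variant_id)]

    def eaf(self) -> np.ndarray:
        """Empirical effect-allele frequency, dosage column mean / 2."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [lookup[i] for i in ids]
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=[self.variants[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_subjects(self, subjects: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.subjects)}
        idx = [lookup[s] for s in subjects]
        return GenotypeMatrix(
            subjects=list(subjects),
            variants=list(self.variants),
            dosage=self.dosage[idx, :].copy(),
        )


@dataclass
class CellCountMatrix:
    """Sparse cells x genes UMI counts plus per-cell metadata.

    ``cell_meta`` must carry one row per cell with columns
    ``cell_id, subject_id, cell_type, batch`` in matrix row order.
    """

    counts: scipy.sparse.csr_matrix
    cell_meta: pd.DataFrame
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        required = {"cell_id", "subject_id", "cell_type", "batch"}
        missing = required - set(self.cell_meta.columns)
        if missing:
            raise ValueError(f"cell_meta lacks columns: {sorted(missing)}")
        if self.counts.shape[0] != len(self.cell_meta):
            raise FormatError(
                f"count matrix has {self.counts.shape[0]} cells but metadata "
                f"has {len(self.cell_meta)} rows"
            )
        if self.counts.shape[1] != len(self.gene_ids):
            raise FormatError(
                f"count matrix has {self.counts.shape[1]} genes but gene table "
                f"has {len(self.gene_ids)} rows"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]


@dataclass
class SummaryStatsTable:
    """Per-variant association summary statistics for one trait.

    ``table`` columns: snp, chrom, pos, a1, a2, eaf, beta, se, p, n.
    """

    trait: str
    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"summary-stats table lacks columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, snps: Sequence[str]) -> "SummaryStatsTable":
        keep = self.table[self.table["snp"].isin(set(snps))]
        return SummaryStatsTable(self.trait, keep.copy(), self.n_dropped)

    @property
    def z(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()


@dataclass
class PhasedAlleleCounts:
    """Phased per-subject UMI counts at het sites: a1 vs total."""

    table: pd.DataFrame

    _COLS = ["subject_id", "cell_type", "variant_id", "gene_id", "a1_umis", "total_umis"]

    def __post_init__(self) -> None:
        missing = [c for c in self._COLS if c not in self.table.columns]
        if missing:
            raise FormatError(f"allele-count table lacks columns: {missing}")
        t = self.table
        if ((t["a1_umis"] < 0) | (t["a1_umis"] > t["total_umis"])).any():
            raise ValueError("a1_umis outside [0, total_umis]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CovariateTable:
    """Per-subject covariates: age, sex, RIN, PMI, batch, pathology score."""

    table: pd.DataFrame

    _REQUIRED = ["subject_id", "age", "sex", "rin", "pmi", "batch"]

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"covariate table lacks columns: {missing}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicated subject rows in covariate table")
        if "pathology_score" in self.table.columns:
            score = self.table["pathology_score"].dropna()
            if (score < 0).any():
                raise ValueError("pathology_score must be >= 0")
        self.table = self.table.set_index("subject_id", drop=False)

    def aligned(self, subjects: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in subjects if s not in self.table.index]
        if missing:
            raise KeyError(f"subjects absent from covariate table: {missing[:5]}")
        return self.table.loc[list(subjects)]


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or a dosage TSV.

    For VCF the ALT allele becomes the counted allele ``a1`` (GT genotypes
    are converted to ALT allele counts; DS fields pass through).
    Multi-allelic sites are rejected with a logged warning, duplicated
    variant ids raise.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if "".join(path.suffixes).endswith((".vcf", ".vcf.gz")) else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in seen:
            raise FormatError(f"duplicated variant id {vid!r} in {path}")
        seen.add(vid)
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col[col < 0] = np.nan
        else:
            col = np.empty(len(subjects))
            for i, gt in enumerate(rec.genotypes):
                alleles = gt[:-1]
                col[i] = np.nan if any(a < 0 for a in alleles) else float(sum(alleles))
        eaf = float(np.nanmean(col) / 2.0) if np.isfinite(col).any() else float("nan")
        variants.append(
            VariantRecord(id=vid, chrom=str(rec.CHROM), pos=int(rec.POS),
                          a1=str(rec.ALT[0]), a2=str(rec.REF), eaf=eaf)
        )
        columns.append(col)
    if n_multi:
        logger.warning("%s: rejected %d multi-allelic site(s)", path, n_multi)
    dosage = np.column_stack(columns) if columns else np.empty((len(subjects), 0))
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


def _variant_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".variants.tsv")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse dosage TSV {path}: {exc}") from exc
    ids = [str(c) for c in df.columns]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicated variant id in header of {path}")
    sidecar = _variant_sidecar(path)
    if sidecar.exists():
        meta = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str})
        lookup = {r.id: r for r in (VariantRecord(
            id=str(row["id"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            a1=str(row["a1"]), a2=str(row["a2"]), eaf=float(row["eaf"]))
            for _, row in meta.iterrows())}
        variants = [lookup[v] for v in ids]
    else:
        variants = [VariantRecord(id=v, chrom="0", pos=i + 1, a1="A", a2="B")
                    for i, v in enumerate(ids)]
    return GenotypeMatrix(
        subjects=[str(s) for s in df.index],
        variants=variants,
        dosage=df.to_numpy(dtype=float),
    )


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage TSV (subjects x variants) plus a variant-metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(gm.dosage, index=gm.subjects, columns=gm.variant_ids)
    df.to_csv(path, sep="\t", index_label="subject_id", float_format="%.6g")
    meta = pd.DataFrame(
        [(v.id, v.chrom, v.pos, v.a1, v.a2, v.eaf) for v in gm.variants],
        columns=["id", "chrom", "pos", "a1", "a2", "eaf"],
    )
    meta.to_csv(_variant_sidecar(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# single-cell counts I/O (Matrix Market triplet + genes.tsv + cells.tsv)
# ---------------------------------------------------------------------------

def read_counts(directory: str | Path) -> CellCountMatrix:
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    genes_path = directory / "genes.tsv"
    cells_path = directory / "cells.tsv"
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(p)
    counts = scipy.sparse.csr_matrix(scipy.io.mmread(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    if counts.shape[1] != len(genes):
        raise FormatError(
            f"{genes_path} lists {len(genes)} genes but {mtx_path} has "
            f"{counts.shape[1]} gene columns")
    if counts.shape[0] != len(cells):
        raise FormatError(
            f"{cells_path} lists {len(cells)} cells but {mtx_path} has "
            f"{counts.shape[0]} cell rows")
    return CellCountMatrix(counts=counts, cell_meta=cells,
                           gene_ids=[str(g) for g in genes["gene_id"]])


def write_counts(ccm: CellCountMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", scipy.sparse.coo_matrix(ccm.counts))
    pd.DataFrame({"gene_id": ccm.gene_ids}).to_csv(
        directory / "genes.tsv", sep="\t", index=False)
    ccm.cell_meta.to_csv(directory / "cells.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary statistics I/O
# ---------------------------------------------------------------------------

def read_sumstats(path: str | Path, trait: str | None = None,
                  synonyms: dict[str, str] | None = None) -> SummaryStatsTable:
    """Read a GWAS/eQTL summary-statistics TSV.

    Rows with ``se <= 0`` or ``p`` outside (0, 1] are dropped with a logged
    count (available as ``.n_dropped``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    mapping = dict(SUMSTATS_SYNONYMS)
    if synonyms:
        mapping.update({k.lower(): v for k, v in synonyms.items()})
    renamed = {}
    for col in df.columns:
        key = str(col).lower()
        if key in mapping:
            renamed[col] = mapping[key]
    df = df.rename(columns=renamed)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {missing}; required names "
            f"(or synonyms): {_SUMSTATS_HEADER}")
    df = df[SUMSTATS_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    ok = (df["se"] > 0) & (df["p"] > 0) & (df["p"] <= 1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d row(s) with invalid se or p", path, n_dropped)
    return SummaryStatsTable(trait=trait or path.stem, table=df[ok], n_dropped=n_dropped)


def write_sumstats(stats: SummaryStatsTable, path: str | Path) -> None:
    out = stats.table[SUMSTATS_COLUMNS].copy()
    out.columns = _SUMSTATS_HEADER
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.start), int(r.end),
                           str(r.strand)) for r in df.itertuples()]


def write_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t"))


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.table.to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str | Path) -> PhasedAlleleCounts:
    return PhasedAlleleCounts(pd.read_csv(path, sep="\t"))


def write_allele_counts(pac: PhasedAlleleCounts, path: str | Path) -> None:
    pac.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(stats: SummaryStatsTable,
                      reference: Sequence[VariantRecord],
                      palindromic_eaf_window: tuple[float, float] = (0.4, 0.6),
                      ) -> SummaryStatsTable:
    """Align effect alleles and effect direction to a reference panel.

    Where the stats alleles are swapped relative to the reference, beta is
    negated and eaf replaced by 1 - eaf.  Strand-ambiguous palindromic
    variants (A/T, C/G) with eaf inside ``palindromic_eaf_window`` are
    dropped, as are variants whose allele pair does not match the reference.
    """
    ref = {v.id: v for v in reference}
    lo, hi = palindromic_eaf_window
    rows = []
    n_dropped = 0
    for row in stats.table.itertuples(index=False):
        v = ref.get(row.snp)
        if v is None:
            n_dropped += 1
            continue
        palindromic = _COMPLEMENT.get(str(row.a1)) == str(row.a2)
        if palindromic and lo <= float(row.eaf) <= hi:
            n_dropped += 1
            continue
        if (row.a1, row.a2) == (v.a1, v.a2):
            rows.append(row)
        elif (row.a1, row.a2) == (v.a2, v.a1):
            rows.append(row._replace(a1=v.a1, a2=v.a2,
                                     beta=-row.beta, eaf=1.0 - row.eaf))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("harmonize_alleles(%s): dropped %d variant(s)",
                    stats.trait, n_dropped)
    out = pd.DataFrame(rows, columns=stats.table.columns)
    return SummaryStatsTable(trait=stats.trait, table=out,
                             n_dropped=stats.n_dropped + n_dropped)
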