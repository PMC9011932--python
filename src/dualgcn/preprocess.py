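"""Data-preparation rules: sample/drug filters, log transforms, z-scoring,
IC50 conventions, and the clinical segment-to-gene copy-number transform.

Conventions fixed here and relied on everywhere else:

* expression is log2(TPM + 1); copy number is log2(CN + 1) with CN the
  relative copy number;
* IC50 is stored as the natural log of a µM concentration and never
  re-transformed internally;
* genomic coordinates are 1-based inclusive (Ensembl convention); BED input
  is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_CANCER_TYPE_SIZE = 10


@dataclass(frozen=True)
class ResponseRecord:
    """One drug–sample response: natural-log IC50 in µM."""

    drug_id: str
    sample_id: str
    ln_ic50: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ln_ic50):
            raise ValueError(
                f"non-finite ln_ic50 for ({self.drug_id}, {self.sample_id})")


@dataclass(frozen=True)
class SegmentCNV:
    """A segment of constant relative copy-number ratio (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    ratio: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.ratio < 0:
            raise ValueError("copy-number ratio must be >= 0")


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic span, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def filter_cell_lines(samples: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Apply the cell-line inclusion rules.

    ``samples`` needs columns ``sample_id``, ``cancer_type`` (NaN/empty =
    unannotated), ``expr_available``, ``cnv_available``. Removes samples with
    missing expression or CNV, missing cancer-type annotation, and then every
    sample whose cancer type retains fewer than 10 samples. Returns the
    surviving table and a per-sample removal log.
    """
    if samples.empty:
        raise ValueError("sample table is empty")
    removal: list[tuple[str, str]] = []
    keep = samples.copy()

    bad_expr = ~keep["expr_available"].astype(bool)
    bad_cnv = ~keep["cnv_available"].astype(bool)
    no_type = keep["cancer_type"].isna() | (keep["cancer_type"].astype(str).str.strip() == "")
    for _, row in keep[bad_expr].iterrows():
        removal.append((row["sample_id"], "expr-missing"))
    for _, row in keep[~bad_expr & bad_cnv].iterrows():
        removal.append((row["sample_id"], "cnv-missing"))
    for _, row in keep[~bad_expr & ~bad_cnv & no_type].iterrows():
        removal.append((row["sample_id"], "cancer-type-missing"))
    keep = keep[~(bad_expr | bad_cnv | no_type)]

    sizes = keep["cancer_type"].value_counts()
    small = sizes[sizes < MIN_CANCER_TYPE_SIZE].index
    for _, row in keep[keep["cancer_type"].isin(small)].iterrows():
        removal.append((row["sample_id"], "cancer-type-too-small"))
    keep = keep[~keep["cancer_type"].isin(small)]
    if keep.empty:
        logger.warning("all samples removed by cell-line filters")
    return keep.reset_index(drop=True), removal


def filter_drugs(drugs: pd.DataFrame) -> pd.DataFrame:
    """Keep only drugs with a unique 1:1 PubChem mapping.

    Drops drugs without a PubChem identifier, and every member of any group
    of distinct GDSC identifiers that share one PubChem identifier.
    """
    keep = drugs.copy()
    pubchem = keep["pubchem_id"].astype(str).str.strip()
    keep = keep[~keep["pubchem_id"].isna() & (pubchem != "") & (pubchem.str.lower() != "nan")]
    shared = (keep.groupby("pubchem_id")["gdsc_id"].nunique())
    ambiguous = shared[shared > 1].index
    return keep[~keep["pubchem_id"].isin(ambiguous)].reset_index(drop=True)


def transform_expression(tpm):
    """log2(TPM + 1); accepts scalars or arrays."""
    tpm = np.asarray(tpm, dtype=float)
    if np.any(tpm < 0):
        raise ValueError("TPM values must be non-negative")
    out = np.log2(tpm + 1.0)
    return float(out) if out.ndim == 0 else out


def transform_cnv(cn):
    """log2(CN + 1) with CN the relative copy number; accepts scalars or arrays."""
    cn = np.asarray(cn, dtype=float)
    if np.any(cn < 0):
        raise ValueError("copy numbers must be non-negative")
    out = np.log2(cn + 1.0)
    return float(out) if out.ndim == 0 else out


class ZScoreNormalizer:
    """Per-gene standardization fit on training samples only.

    Uses population standard deviation; genes constant in training map to 0
    (with a logged warning) rather than dividing by zero.
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.std_: pd.Series | None = None

    def fit(self, features: pd.DataFrame) -> "ZScoreNormalizer":
        """``features`` is genes × samples (rows indexed by gene symbol)."""
        if features.shape[1] < 2:
            raise ValueError("z-score fit needs at least 2 training samples")
        self.mean_ = features.mean(axis=1)
        self.std_ = features.std(axis=1, ddof=0)
        n_const = int((self.std_ == 0).sum())
        if n_const:
            logger.warning("%d constant gene rows map to 0 under z-scoring", n_const)
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("normalizer is not fit")
        mean = self.mean_.reindex(features.index)
        std = self.std_.reindex(features.index)
        out = features.sub(mean, axis=0).div(std.replace(0.0, np.inf), axis=0)
        return out.fillna(0.0)

    def fit_transform(self, features: pd.DataFrame) -> pd.DataFrame:
        return self.fit(features).transform(features)

    def to_dict(self) -> dict:
        return {"genes": list(self.mean_.index),
                "mean": self.mean_.to_list(), "std": self.std_.to_list()}

    @classmethod
    def from_dict(cls, d: dict) -> "ZScoreNormalizer":
        norm = cls()
        norm.mean_ = pd.Series(d["mean"], index=d["genes"])
        norm.std_ = pd.Series(d["std"], index=d["genes"])
        return norm


def fit_zscore(features: pd.DataFrame) -> ZScoreNormalizer:
    """Functional alias for :meth:`ZScoreNormalizer.fit`."""
    return ZScoreNormalizer().fit(features)


def apply_zscore(normalizer: ZScoreNormalizer, features: pd.DataFrame) -> pd.DataFrame:
    return normalizer.transform(features)


def segment_to_gene_cnv(segments: list[SegmentCNV], gene: GeneInterval) -> float:
    """Collapse segment-level copy number onto one gene.

    With K segments intersecting the gene, intersection lengths l_s, gene
    length L and segment ratios c_s, returns

        log2( sum_s c_s * l_s/L + (1 - sum_s l_s/L) + 1 )

    i.e. a length-weighted mean ratio with uncovered gene portions counted at
    the neutral ratio 1. Overlapping segments within the gene are an error:
    the formula presumes a partition of the covered portion.
    """
    L = gene.length
    clipped: list[tuple[int, int, float]] = []
    for seg in segments:
        if seg.chrom != gene.chrom:
            continue
        lo, hi = max(seg.start, gene.start), min(seg.end, gene.end)
        if lo <= hi:
            clipped.append((lo, hi, seg.ratio))
    clipped.sort()
    for (lo1, hi1, _), (lo2, _, _) in zip(clipped, clipped[1:]):
        if lo2 <= hi1:
            raise ValueError(
                f"gene {gene.gene}: segments overlap within the gene "
                f"([{lo1},{hi1}] and starting {lo2})")
    covered = sum(hi - lo + 1 for lo, hi, _ in clipped)
    if covered > L:
        raise ValueError(f"gene {gene.gene}: covered length {covered} exceeds {L}")
    weighted = sum(c * (hi - lo + 1) / L for lo, hi, c in clipped)
    return float(np.log2(weighted + (1.0 - covered / L) + 1.0))


# ---------------------------------------------------------------- file I/O

def read_omics_tsv(path: str | Path) -> pd.DataFrame:
    """Genes × samples TSV; first column = gene symbol."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_response_tsv(path: str | Path) -> list[ResponseRecord]:
    """TSV with columns drug_id, sample_id, ln_ic50."""
    df = pd.read_csv(path, sep="\t")
    return [ResponseRecord(str(r.drug_id), str(r.sample_id), float(r.ln_ic50))
            for r in df.itertuples()]


def read_segments_tsv(path: str | Path) -> list[SegmentCNV]:
    """SEG-style TSV with columns sample, chrom, start, end, ratio (1-based)."""
    df = pd.read_csv(path, sep="\t")
    return [SegmentCNV(str(r.sample), str(r.chrom), int(r.start), int(r.end),
                       float(r.ratio)) for r in df.itertuples()]


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Gene spans from BED (0-based half-open, >= 4 columns, name in col 4)
    or from a headered TSV (gene, chrom, start, end; 1-based inclusive)."""
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if first.startswith("gene\t"):
        df = pd.read_csv(path, sep="\t")
        return [GeneInterval(str(r.gene), str(r.chrom), int(r.start), int(r.end))
                for r in df.itertuples()]
    out = []
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith(("track", "#")):
            continue
        f = ln.split("\t")
        out.append(GeneInterval(gene=f[3], chrom=f[0],
                                start=int(f[1]) + 1, end=int(f[2])))
    return out
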