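"""Preprocessing of paired expression / copy-number matrices.

The pipeline order is fixed: expression counts are filtered on CPM, then
normalised with upper-quartile FPKM; copy-number values are cleaned
(all-missing genes dropped, remaining gaps mean-imputed); the two sources
are restricted to their shared genes and patients (three-way intersection
with the clinical table); finally each matrix is min-max scaled per gene
into [0, 1] so it can feed a sigmoid autoencoder.

All matrices are genes x patients DataFrames with gene identifiers as the
index and patient identifiers as columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScaledMatrix",
    "compute_cpm",
    "filter_low_expression",
    "fpkm_uq",
    "clean_cna",
    "match_genes",
    "minmax_scale",
    "preprocess_bundle",
]

log = logging.getLogger(__name__)


@dataclass
class ScaledMatrix:
    """A genes x patients matrix scaled into [0, 1].

    Attributes
    ----------
    values : DataFrame, genes x patients, every entry in [0, 1]
    source_tag : {"expression", "cna", "concatenated"}
    dropped_genes : genes removed because their range was degenerate
    """

    values: pd.DataFrame
    source_tag: str
    dropped_genes: tuple[str, ...] = ()

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.columns


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: entry(g, s) = counts(g, s) * 1e6 / colsum(s)."""
    colsum = counts.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"zero total count for patient(s): {list(zero.index)}")
    return counts * 1e6 / colsum


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.Index:
    """Genes with CPM >= `min_cpm` in at least `min_samples` patients.

    Unexpressed (all-zero) genes never qualify and are removed.  Order of the
    surviving genes is preserved.
    """
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {counts.shape[1]} available patients"
        )
    cpm = compute_cpm(counts)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    kept = counts.index[keep]
    log.info("CPM filter: %d -> %d genes", counts.shape[0], len(kept))
    return kept


def fpkm_uq(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Upper-quartile FPKM.

    entry(g, s) = counts(g, s) * 1e9 / (UQ(s) * length(g)) where UQ(s) is the
    75th percentile of the *positive* counts of sample s (zeros excluded so
    sparse samples do not drag the quartile to 0).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:5])
        raise ValueError(f"gene lengths missing for genes such as {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    arr = counts.to_numpy(dtype=float)
    uq = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        pos = arr[:, j][arr[:, j] > 0]
        uq[j] = np.percentile(pos, 75) if pos.size else 0.0
    bad = np.flatnonzero(uq == 0)
    if bad.size:
        raise ValueError(
            f"zero upper-quartile count for patient(s): {list(counts.columns[bad])}"
        )
    vals = arr * 1e9 / (uq[None, :] * lengths.to_numpy()[:, None])
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def clean_cna(cna: pd.DataFrame) -> pd.DataFrame:
    """Drop genes missing in every patient; mean-impute remaining gaps."""
    all_na = cna.isna().all(axis=1)
    out = cna.loc[~all_na]
    if all_na.any():
        log.info("CNA clean: dropped %d all-missing genes", int(all_na.sum()))
    n_imputed = int(out.isna().to_numpy().sum())
    if n_imputed:
        out = out.T.fillna(out.mean(axis=1)).T
        log.info("CNA clean: mean-imputed %d missing entries", n_imputed)
    return out


def match_genes(
    expr: pd.DataFrame,
    cna: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to shared genes (sorted) and shared patients.

    Patients are intersected across both omics sources and, when given, the
    clinical table's ``patient_id`` column; the expression matrix's column
    order is preserved for the survivors.
    """
    shared_genes = sorted(set(expr.index) & set(cna.index))
    if not shared_genes:
        raise ValueError("no genes shared between expression and CNA matrices")
    shared_pat = set(expr.columns) & set(cna.columns)
    if clinical is not None:
        shared_pat &= set(clinical["patient_id"])
    patients = [p for p in expr.columns if p in shared_pat]
    if not patients:
        raise ValueError("no patients shared across sources (and clinical table)")
    log.info(
        "gene match: %d & %d -> %d genes; %d patients retained",
        expr.shape[0], cna.shape[0], len(shared_genes), len(patients),
    )
    return expr.loc[shared_genes, patients], cna.loc[shared_genes, patients]


def minmax_scale(matrix: pd.DataFrame, source_tag: str = "expression") -> ScaledMatrix:
    """Per-gene linear scaling into [0, 1]; constant genes are dropped.

    Every retained gene attains both 0 and 1 somewhere across patients.
    """
    arr = matrix.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("matrix contains non-finite values")
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = (hi - lo).ravel()
    constant = span == 0
    dropped = tuple(matrix.index[constant])
    if dropped:
        log.info("min-max scale: dropped %d constant genes", len(dropped))
    keep = ~constant
    scaled = (arr[keep] - lo[keep]) / (hi[keep] - lo[keep])
    values = pd.DataFrame(scaled, index=matrix.index[keep], columns=matrix.columns)
    return ScaledMatrix(values=values, source_tag=source_tag, dropped_genes=dropped)


def preprocess_bundle(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    cna: pd.DataFrame,
    clinical: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 3,
) -> tuple[ScaledMatrix, ScaledMatrix, pd.DataFrame]:
    """Full preprocessing: filter -> FPKM-UQ -> clean -> match -> scale.

    Returns the matched expression and CNA ScaledMatrix pair (identical gene
    and patient order) and the clinical table aligned to the same patients.
    """
    kept = filter_low_expression(counts, min_cpm=min_cpm, min_samples=min_samples)
    expr = fpkm_uq(counts.loc[kept], gene_lengths)
    cna_clean = clean_cna(cna)
    expr_m, cna_m = match_genes(expr, cna_clean, clinical)
    s_expr = minmax_scale(expr_m, "expression")
    s_cna = minmax_scale(cna_m, "cna")
    # scaling may drop constant genes from either side; re-intersect so the
    # matched pair shares an identical gene order
    shared = s_expr.values.index.intersection(s_cna.values.index)
    s_expr.values = s_expr.values.loc[shared]
    s_cna.values = s_cna.values.loc[shared]
    clin = clinical[clinical["patient_id"].isin(s_expr.patient_ids)]
    clin = clin.set_index("patient_id").loc[list(s_expr.patient_ids)].reset_index()
    log.info(
        "preprocess: final matched matrices %d genes x %d patients",
        len(shared), s_expr.values.shape[1],
    )
    return s_expr, s_cna, clin
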