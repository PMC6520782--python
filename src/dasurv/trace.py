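"""Trace feature-level Cox coefficients back to gene-level weights.

For the one-input model the gene score is the weight matrix times the Cox
coefficient vector, w_g = sum_i W[g, i] * B[i].  For the two-input model no
direct genes x features weight matrix exists; the dimensionally consistent
construction composes each source's first-layer weights with the matching
half of the second-layer weights (composite = W1 @ W2_half, genes x
features) before applying B.  Gene scores are filtered on |w_g| at a cutoff
(0.01 by default) and exported as ranked lists consumable by enrichment
tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .da import OneInputDA, TwoInputDA

__all__ = [
    "GeneWeightVector",
    "GeneList",
    "trace_one_input",
    "trace_two_input",
    "filter_genes",
    "export_gene_list",
]

log = logging.getLogger(__name__)


@dataclass
class GeneWeightVector:
    """Per-gene traced weight w_g for one model/source."""

    weights: pd.Series      # gene_id -> w_g
    source_tag: str         # expression | cna | concatenated:<side> | concatenated

    @property
    def gene_ids(self) -> pd.Index:
        return self.weights.index


@dataclass
class GeneList:
    """Genes passing the |w_g| cutoff, ranked by |w_g| descending."""

    ranked: pd.Series       # gene_id -> w_g, in rank order
    cutoff: float

    def __len__(self) -> int:
        return len(self.ranked)


def trace_one_input(
    W: np.ndarray | pd.DataFrame,
    B: np.ndarray | pd.Series,
    gene_ids=None,
    source_tag: str = "expression",
) -> GeneWeightVector:
    """w_g = sum_i W[g, i] * B[i] for a genes x features weight matrix."""
    if isinstance(W, pd.DataFrame):
        gene_ids = W.index if gene_ids is None else gene_ids
        W = W.to_numpy()
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float).ravel()
    if W.ndim != 2 or W.shape[1] != B.shape[0]:
        raise ValueError(f"shape mismatch: W {W.shape} vs B {B.shape}")
    wg = W @ B
    if gene_ids is None:
        gene_ids = pd.RangeIndex(W.shape[0])
    return GeneWeightVector(pd.Series(wg, index=pd.Index(gene_ids)), source_tag)


def trace_two_input(
    W1_a: np.ndarray,
    W1_b: np.ndarray,
    W2: np.ndarray,
    B: np.ndarray | pd.Series,
    gene_ids_a=None,
    gene_ids_b=None,
) -> tuple[GeneWeightVector, GeneWeightVector]:
    """Per-source gene scores for the concatenated model.

    ``W2``'s rows split into the source-a half (first ``hidden1`` rows) and
    the source-b half; composite_a = W1_a @ W2[:hidden1] has shape genes x
    features and is handled like a one-input weight matrix.
    """
    W1_a = np.asarray(W1_a, dtype=float)
    W1_b = np.asarray(W1_b, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    h1a, h1b = W1_a.shape[1], W1_b.shape[1]
    if W2.shape[0] != h1a + h1b:
        raise ValueError(
            f"W2 has {W2.shape[0]} rows but the sources' encode widths sum to {h1a + h1b}"
        )
    comp_a = W1_a @ W2[:h1a, :]
    comp_b = W1_b @ W2[h1a:, :]
    gwv_a = trace_one_input(comp_a, B, gene_ids_a, "concatenated:expression-side")
    gwv_b = trace_one_input(comp_b, B, gene_ids_b, "concatenated:cna-side")
    return gwv_a, gwv_b


def trace_model(model, B, gene_ids=None, gene_ids_b=None, source_tag="expression"):
    """Convenience dispatch on a trained model object.

    For a :class:`TwoInputDA` the combined "concatenated" score per shared
    gene is the sum of the two source-side scores (``combine="sum"``); a
    max-absolute alternative is available.
    """
    if isinstance(model, OneInputDA):
        return trace_one_input(model.W, B, gene_ids, source_tag)
    if isinstance(model, TwoInputDA):
        return trace_two_input(model.W1_a, model.W1_b, model.W2, B, gene_ids, gene_ids_b)
    raise TypeError(f"unsupported model type {type(model)!r}")


def combine_two_sided(
    gwv_a: GeneWeightVector, gwv_b: GeneWeightVector, mode: str = "sum"
) -> GeneWeightVector:
    """Combined concatenated gene score for genes shared by both sources.

    ``mode="sum"`` adds the two side scores; ``mode="maxabs"`` keeps the
    side score of larger magnitude.
    """
    shared = gwv_a.weights.index.intersection(gwv_b.weights.index)
    a = gwv_a.weights.loc[shared]
    b = gwv_b.weights.loc[shared]
    if mode == "sum":
        w = a + b
    elif mode == "maxabs":
        w = a.where(a.abs() >= b.abs(), b)
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    return GeneWeightVector(w, "concatenated")


def filter_genes(gwv: GeneWeightVector, cutoff: float = 0.01) -> GeneList:
    """Keep genes with |w_g| >= cutoff, ranked by |w_g| descending.

    Ties in |w_g| are broken by gene identifier.  An empty result is allowed
    (and logged).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    w = gwv.weights
    kept = w[w.abs() >= cutoff]
    order = sorted(kept.index, key=lambda g: (-abs(kept[g]), str(g)))
    ranked = kept.loc[order]
    if ranked.empty:
        log.warning("filter_genes: no genes pass |w_g| >= %g", cutoff)
    return GeneList(ranked, cutoff)


def export_gene_list(gene_list: GeneList, path: str | Path) -> tuple[Path, Path]:
    """Write the ranked list as plain text plus a two-column ranked TSV.

    ``<path>`` gets one gene per line (enrichment-tool input); the sibling
    ``<path stem>.ranked.tsv`` carries (gene_id, weight) pairs in rank order.
    Round-tripping the TSV preserves the ordering.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if gene_list.ranked.empty:
        path.write_text(f"# no genes passed |w_g| >= {gene_list.cutoff}\n")
    else:
        path.write_text("\n".join(str(g) for g in gene_list.ranked.index) + "\n")
    ranked_path = path.with_suffix(".ranked.tsv")
    df = gene_list.ranked.rename("weight").to_frame()
    df.to_csv(ranked_path, sep="\t", index_label="gene_id", float_format="%.8g")
    return path, ranked_path
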