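"""Cell/gene quality filters, log-CPM normalization and per-cell-type
expression summaries.

Filter rules (human defaults): genes detected in fewer than 3 cells are
removed first; then cells are removed if they detect fewer than 500
genes, exceed 20% mitochondrial content, or jointly exceed 10%
mitochondrial content with fewer than 1,500 total counts.  Expression is
normalized to log(CPM/100 + 1), i.e. natural log of counts-per-ten-
thousand plus one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import CountMatrix, NormalizedMatrix, ValidationError

CPM100_SCALE = 1e4  # CPM / 100


@dataclass
class QCThresholds:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 500
    max_mito_fraction: float = 0.20
    joint_mito_fraction: float = 0.10
    joint_min_counts: int = 1500
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        for f in (self.max_mito_fraction, self.joint_mito_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"mito fraction threshold {f} outside [0,1]")
        if self.joint_mito_fraction > self.max_mito_fraction:
            raise ValidationError(
                "joint_mito_fraction must not exceed max_mito_fraction"
            )


class QCFilter(BaseEstimator):
    """Quality filter over a CountMatrix.

    ``fit`` computes the gene and cell masks and a removal report;
    ``transform`` applies them.  The gene filter runs first, on all
    cells; cell rules are then evaluated on the gene-filtered matrix.

    Attributes
    ----------
    gene_mask_, cell_mask_ : boolean arrays of kept genes / cells
    report_ : dict of per-rule removal counts
    """

    def __init__(self, min_cells_per_gene: int = 3, min_genes_per_cell: int = 500,
                 max_mito_fraction: float = 0.20, joint_mito_fraction: float = 0.10,
                 joint_min_counts: int = 1500, mito_gene_prefix: str = "MT-"):
        self.min_cells_per_gene = min_cells_per_gene
        self.min_genes_per_cell = min_genes_per_cell
        self.max_mito_fraction = max_mito_fraction
        self.joint_mito_fraction = joint_mito_fraction
        self.joint_min_counts = joint_min_counts
        self.mito_gene_prefix = mito_gene_prefix

    def fit(self, cm: CountMatrix, y=None):
        X = cm.counts
        detected = (X > 0)
        cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
        gene_mask = cells_per_gene >= self.min_cells_per_gene

        Xg = X[:, gene_mask]
        genes_per_cell = np.asarray((Xg > 0).sum(axis=1)).ravel()
        total_counts = np.asarray(Xg.sum(axis=1)).ravel()
        mito = np.array(
            [g.startswith(self.mito_gene_prefix)
             for g, k in zip(cm.gene_ids, gene_mask) if k]
        )
        mito_counts = (np.asarray(Xg[:, mito].sum(axis=1)).ravel()
                       if mito.any() else np.zeros(cm.n_cells))
        with np.errstate(divide="ignore", invalid="ignore"):
            mito_frac = np.where(total_counts > 0, mito_counts / total_counts, 0.0)

        fail_genes = genes_per_cell < self.min_genes_per_cell
        fail_mito = mito_frac > self.max_mito_fraction
        fail_joint = (mito_frac > self.joint_mito_fraction) & \
                     (total_counts < self.joint_min_counts)
        cell_mask = ~(fail_genes | fail_mito | fail_joint)

        self.gene_mask_ = gene_mask
        self.cell_mask_ = cell_mask
        self.report_ = {
            "genes_in": cm.n_genes,
            "genes_removed_min_cells": int((~gene_mask).sum()),
            "cells_in": cm.n_cells,
            "cells_removed_min_genes": int(fail_genes.sum()),
            "cells_removed_max_mito": int(fail_mito.sum()),
            "cells_removed_joint_mito_counts": int(fail_joint.sum()),
            "cells_removed_total": int((~cell_mask).sum()),
            "cells_out": int(cell_mask.sum()),
            "genes_out": int(gene_mask.sum()),
        }
        if cell_mask.sum() == 0:
            raise ValidationError(f"QC removed every cell; report: {self.report_}")
        return self

    def transform(self, cm: CountMatrix) -> CountMatrix:
        return cm.subset(cell_mask=self.cell_mask_, gene_mask=self.gene_mask_)

    def fit_transform(self, cm: CountMatrix, y=None) -> CountMatrix:
        return self.fit(cm).transform(cm)


def qc_filter(cm: CountMatrix, thr: QCThresholds | None = None
              ) -> tuple[CountMatrix, dict]:
    """Apply the quality filters; returns (filtered matrix, report)."""
    thr = thr or QCThresholds()
    est = QCFilter(**vars(thr))
    out = est.fit_transform(cm)
    return out, est.report_


class LogCPM100Normalizer(TransformerMixin, BaseEstimator):
    """Per-cell depth normalization to ln(counts-per-10k + 1).

    Stateless in the sklearn sense (fit records provenance only); zero
    raw counts map to zero and doubling all counts of a cell leaves its
    values unchanged.
    """

    def fit(self, X, y=None):
        self.provenance_ = {
            "normalization": "log(CPM/100 + 1)",
            "scale": CPM100_SCALE,
            "log_base": "e",
        }
        return self

    def transform(self, X):
        X = sp.csr_matrix(X, dtype=float)
        totals = np.asarray(X.sum(axis=1)).ravel()
        if np.any(totals <= 0):
            bad = int(np.argmax(totals <= 0))
            raise ValidationError(
                f"cell at row {bad} has zero total counts; run QC first"
            )
        out = sp.diags(CPM100_SCALE / totals) @ X
        out.data = np.log1p(out.data)
        return out.tocsr()


def normalize_log_cpm100(cm: CountMatrix) -> NormalizedMatrix:
    norm = LogCPM100Normalizer().fit(cm.counts)
    return NormalizedMatrix(
        values=norm.transform(cm.counts),
        cell_ids=cm.cell_ids,
        gene_ids=cm.gene_ids,
        provenance=norm.provenance_,
    )


def profile_cell_types(norm: NormalizedMatrix, counts: CountMatrix,
                       labels=None) -> pd.DataFrame:
    """Per (cell_type, gene) summary: mean normalized expression, fraction
    of cells detecting the gene (raw count > 0) and cell count.

    Means use normalized values; fractions use raw detection, matching
    how expression gates are applied downstream.
    """
    if norm.gene_ids != counts.gene_ids or norm.cell_ids != counts.cell_ids:
        raise ValidationError("normalized and raw matrices are not aligned")
    if labels is None:
        labels = counts.cell_types.to_numpy()
    labels = np.asarray(labels)
    detected = counts.counts > 0
    rows = []
    for ct in sorted(pd.unique(labels).tolist()):
        mask = labels == ct
        n = int(mask.sum())
        mean_norm = np.asarray(norm.values[mask].mean(axis=0)).ravel()
        frac = np.asarray(detected[mask].mean(axis=0)).ravel()
        rows.append(pd.DataFrame({
            "cell_type": ct,
            "gene": counts.gene_ids,
            "mean_norm_expression": mean_norm,
            "fraction_expressing": frac,
            "n_cells": n,
        }))
    return pd.concat(rows, ignore_index=True)


def tfidf_markers(counts: CountMatrix, labels=None, top_n: int = 10,
                  min_cells: int = 2) -> pd.DataFrame:
    """Cluster marker ranking by TF-IDF on detection.

    score(gene, cluster) = tf * idf with tf = fraction of cluster cells
    detecting the gene and idf = ln(N_total / N_expressing_overall).
    Genes detected nowhere score 0.  Ties break by gene id.
    """
    if labels is None:
        labels = counts.cell_types.to_numpy()
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels).tolist())
    if len(clusters) < 2:
        raise ValidationError("marker ranking requires at least 2 clusters")
    detected = counts.counts > 0
    n_total = counts.n_cells
    n_expressing = np.asarray(detected.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        idf = np.where(n_expressing > 0, np.log(n_total / np.maximum(n_expressing, 1)), 0.0)
    frames = []
    for ct in clusters:
        mask = labels == ct
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {ct!r} has < {min_cells} cells; skipped")
            continue
        tf = np.asarray(detected[mask].mean(axis=0)).ravel()
        score = tf * idf
        df = pd.DataFrame({
            "cluster": ct, "gene": counts.gene_ids, "tf": tf, "idf": idf,
            "score": score,
        }).sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
        df = df.head(top_n).reset_index(drop=True)
        df.insert(2, "rank", np.arange(1, len(df) + 1))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
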