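"""Three-evidence transcription-factor analysis.

Evidence streams per (TF, cell type):

1. expression — one-vs-all DE of the TF's own transcript;
2. regulon activity — a signed, weighted mean of the z-scored expression
   of the TF's targets (activation targets add, repression targets
   subtract), tested one-vs-all on the z scale;
3. motif accessibility — per-cell deviation z-scores of the TF motif's
   peak set against a coverage-based expectation, corrected by
   GC/accessibility-matched background peak sets, tested one-vs-all.

A TF is prioritized in a cell type when its expression evidence passes
(log2FC > 0.5, adjusted p < 0.01) AND at least one activity evidence
passes (group-mean z difference > 0.75, adjusted p < 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    NormalizedMatrix,
    PeakAccessibility,
    RegulonSet,
    ValidationError,
)
from .de import WilcoxonOneVsAll


@dataclass
class TFPriorityThresholds:
    expr_log2fc_min: float = 0.5
    expr_padj_max: float = 0.01
    act_log2fc_min: float = 0.75
    act_padj_max: float = 0.01


class RegulonActivity(TransformerMixin, BaseEstimator):
    """Regulon-based TF activity scores from normalized expression.

    For each cell the signature is the per-gene z-score across cells;
    activity(TF, cell) = sum over targets of mode * weight * z(target)
    divided by sqrt(sum of squared weights) — a z-like signed mean.
    Regulons whose usable targets fall below ``min_targets`` are dropped
    with a warning.

    ``transform`` takes a cells x genes matrix and returns a TF x cells
    DataFrame (the orientation used by the activity DE step).
    """

    def __init__(self, regulons: RegulonSet | None = None, min_targets: int = 5):
        self.regulons = regulons
        self.min_targets = min_targets

    def fit(self, X, y=None, gene_ids=None):
        if self.regulons is None:
            raise ValidationError("RegulonActivity requires a RegulonSet")
        if gene_ids is None:
            raise ValidationError("fit requires gene_ids aligned with X columns")
        gene_idx = {g: j for j, g in enumerate(gene_ids)}
        self.tf_names_ = []
        self.target_idx_ = []
        self.target_sign_ = []
        dropped = []
        for tf in sorted(self.regulons.regulons):
            usable = [
                t for t in self.regulons.regulons[tf] if t.target_gene in gene_idx
            ]
            missing = len(self.regulons.regulons[tf]) - len(usable)
            if missing:
                warnings.warn(f"regulon {tf!r}: {missing} target(s) absent; dropped")
            if len(usable) < self.min_targets:
                dropped.append(tf)
                continue
            self.tf_names_.append(tf)
            self.target_idx_.append(np.array([gene_idx[t.target_gene] for t in usable]))
            self.target_sign_.append(
                np.array([t.mode * t.weight for t in usable], dtype=float)
            )
        if dropped:
            warnings.warn(f"regulons excluded (below target floor): {dropped}")
        if not self.tf_names_:
            raise ValidationError("no regulon has enough usable targets")
        return self

    def score_signature(self, Z) -> np.ndarray:
        """Signed weighted-mean score from a cells x genes signature matrix.

        Linear in the signature: scaling Z by k scales every activity by k.
        """
        Z = np.asarray(Z, dtype=float)
        rows = []
        for idx, signw in zip(self.target_idx_, self.target_sign_):
            denom = np.sqrt(np.sum(signw**2))
            rows.append(Z[:, idx] @ signw / denom)
        return np.vstack(rows)

    def transform(self, X, cell_ids=None) -> pd.DataFrame:
        if sp.issparse(X):
            X = np.asarray(X.todense())
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant genes contribute zero signature
        Z = (X - mean) / sd
        act = pd.DataFrame(
            self.score_signature(Z), index=self.tf_names_,
            columns=cell_ids if cell_ids is not None else range(X.shape[0]),
        )
        act.attrs["source"] = "regulon"
        return act

    def fit_transform(self, X, y=None, gene_ids=None, cell_ids=None):
        return self.fit(X, gene_ids=gene_ids).transform(X, cell_ids=cell_ids)


def regulon_activity(norm: NormalizedMatrix, regulons: RegulonSet,
                     min_targets: int | None = None) -> pd.DataFrame:
    """TF x cells regulon activity from a NormalizedMatrix."""
    est = RegulonActivity(
        regulons=regulons,
        min_targets=min_targets if min_targets is not None else regulons.min_targets,
    )
    return est.fit_transform(norm.values, gene_ids=norm.gene_ids,
                             cell_ids=norm.cell_ids)


def filter_peaks(pa: PeakAccessibility, blacklist: pd.DataFrame | None,
                 cluster_labels, min_width: int = 210, max_width: int = 1500,
                 min_cluster_fraction: float = 0.04) -> PeakAccessibility:
    """Peak quality filters for accessibility data.

    Drops peaks that (1) overlap a blacklist interval by at least 1 bp,
    (2) have width outside [min_width, max_width] (inclusive bounds), or
    (3) are accessible in fewer than ``min_cluster_fraction`` of the
    cells of every cluster (a peak survives if at least one cluster
    reaches the fraction).
    """
    n = len(pa.peaks)
    keep = np.ones(n, dtype=bool)

    if blacklist is not None and len(blacklist):
        trees: dict[str, IntervalTree] = {}
        for r in blacklist.itertuples(index=False):
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
        for i, r in enumerate(pa.peaks.itertuples(index=False)):
            t = trees.get(r.chrom)
            if t is not None and t.overlap(r.start, r.end):
                keep[i] = False

    widths = pa.widths
    keep &= (widths >= min_width) & (widths <= max_width)

    labels = np.asarray(cluster_labels)
    if labels.shape[0] != len(pa.cell_ids):
        raise ValidationError("cluster labels do not match accessibility cells")
    accessible = pa.access > 0
    any_cluster = np.zeros(n, dtype=bool)
    for cl in pd.unique(labels):
        mask = labels == cl
        frac = np.asarray(accessible[:, mask].mean(axis=1)).ravel()
        any_cluster |= frac >= min_cluster_fraction
    keep &= any_cluster

    if not keep.any():
        raise ValidationError("peak filtering removed every peak")
    return pa.subset_peaks(keep)


class MotifDeviations(BaseEstimator):
    """Per-cell motif accessibility deviation z-scores.

    For a peak set S, the expected accessibility in a cell is the
    total accessibility of S over all cells scaled by the cell's share
    of total fragments; the raw deviation is (observed - expected) /
    expected.  Each motif's raw deviation is standardized against
    ``n_background`` background peak sets built by matching every motif
    peak to a randomly chosen near neighbour in the standardized
    (GC content, mean accessibility) plane.

    Parameters
    ----------
    n_background : number of background peak sets per motif
    k_neighbors : neighbour pool size per peak for background sampling
    seed : RNG seed for background sampling

    Attributes
    ----------
    deviations_ : TF x cells DataFrame of deviation z-scores
    dropped_motifs_ : motifs with degenerate background spread
    """

    def __init__(self, n_background: int = 50, k_neighbors: int = 25,
                 seed: int = 0):
        self.n_background = n_background
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit(self, pa: PeakAccessibility, y=None):
        rng = np.random.default_rng(self.seed)
        A = sp.csr_matrix(pa.access, dtype=float)
        n_peaks, n_cells = A.shape
        cell_totals = np.asarray(A.sum(axis=0)).ravel()
        grand_total = cell_totals.sum()
        if grand_total <= 0:
            raise ValidationError("accessibility matrix is empty")
        cell_share = cell_totals / grand_total
        peak_totals = np.asarray(A.sum(axis=1)).ravel()

        # background matching space: standardized (GC, mean accessibility)
        feats = np.column_stack([pa.gc_content, peak_totals / n_cells])
        mu, sdev = feats.mean(axis=0), feats.std(axis=0)
        sdev[sdev == 0] = 1.0
        feats = (feats - mu) / sdev
        k = min(self.k_neighbors + 1, n_peaks)
        tree = cKDTree(feats)
        _, nbr = tree.query(feats, k=k)
        nbr = np.atleast_2d(nbr)
        # drop self-matches from each neighbour pool
        pools = []
        for i in range(n_peaks):
            row = [j for j in np.ravel(nbr[i]) if j != i]
            pools.append(np.array(row if row else [i]))

        def raw_deviation(idx: np.ndarray) -> np.ndarray:
            obs = np.asarray(A[idx].sum(axis=0)).ravel()
            expected = obs.sum() * cell_share
            with np.errstate(divide="ignore", invalid="ignore"):
                y = np.where(expected > 0, (obs - expected) / expected, 0.0)
            return y

        annot = pa.motif_annot.tocsc()
        rows, tf_names = [], []
        self.dropped_motifs_ = []
        for j, motif in enumerate(pa.motif_names):
            idx = annot[:, j].tocoo().row
            if idx.size == 0:
                self.dropped_motifs_.append(motif)
                continue
            y_obs = raw_deviation(idx)
            bg = np.empty((self.n_background, n_cells))
            for b in range(self.n_background):
                bg_idx = np.array([
                    pools[i][rng.integers(len(pools[i]))] for i in idx
                ])
                bg[b] = raw_deviation(bg_idx)
            sd_bg = bg.std(axis=0, ddof=1)
            if np.all(sd_bg == 0):
                warnings.warn(f"motif {motif!r}: degenerate background; dropped")
                self.dropped_motifs_.append(motif)
                continue
            sd_bg[sd_bg == 0] = sd_bg[sd_bg > 0].mean()
            rows.append((y_obs - bg.mean(axis=0)) / sd_bg)
            tf_names.append(pa.motif_tf.get(motif, motif))

        if not rows:
            raise ValidationError("no motif produced a usable deviation score")
        dev = pd.DataFrame(np.vstack(rows), index=tf_names, columns=pa.cell_ids)
        # motif families mapping to one TF collapse by max z
        dev = dev.groupby(level=0).max()
        dev.attrs["source"] = "motif"
        self.deviations_ = dev
        return self

    def fit_transform(self, pa: PeakAccessibility, y=None) -> pd.DataFrame:
        return self.fit(pa).deviations_


def motif_deviations(pa: PeakAccessibility, n_background: int = 50,
                     seed: int = 0, k_neighbors: int = 25) -> pd.DataFrame:
    return MotifDeviations(n_background=n_background, k_neighbors=k_neighbors,
                           seed=seed).fit_transform(pa)


def activity_de(activity: pd.DataFrame, labels, adjust: str = "bonferroni",
                min_cells: int = 3) -> pd.DataFrame:
    """One-vs-all DE on a TF x cells activity matrix.

    The matrix is z-transformed per TF across cells first; the reported
    "log2fc" is the difference of group means on the z scale (fold
    change is undefined for signed scores).
    """
    vals = activity.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (vals - mean) / sd
    est = WilcoxonOneVsAll(adjust=adjust, fc_mode="meandiff", min_cells=min_cells)
    return est.fit_predict(Z.T, np.asarray(labels),
                           feature_names=list(activity.index))


def prioritize(expr_de: pd.DataFrame, regulon_de: pd.DataFrame | None,
               motif_de: pd.DataFrame | None,
               thr: TFPriorityThresholds | None = None,
               tf_names=None) -> pd.DataFrame:
    """Combine the three evidence streams into per-(TF, cell type) verdicts.

    prioritized = expression passes AND (regulon OR motif activity
    passes).  An absent modality contributes False (not missing).  When
    ``tf_names`` is given, expression evidence is restricted to those
    genes; otherwise the union of TFs seen in the activity tables is
    used (falling back to all expr_de features when no activity table
    names any TF).
    """
    thr = thr or TFPriorityThresholds()

    def passing(de: pd.DataFrame | None, lfc_min: float, padj_max: float) -> set:
        if de is None or not len(de):
            return set()
        hit = de[(de["log2fc"] > lfc_min) & (de["p_adj"] < padj_max)]
        return set(zip(hit["feature"], hit["group"]))

    if tf_names is None:
        tf_names = set()
        for de in (regulon_de, motif_de):
            if de is not None and len(de):
                tf_names |= set(de["feature"])
        if not tf_names:
            tf_names = set(expr_de["feature"])
    tf_names = sorted(tf_names)
    groups = sorted(expr_de["group"].unique().tolist())

    expr_pass = passing(expr_de, thr.expr_log2fc_min, thr.expr_padj_max)
    reg_pass = passing(regulon_de, thr.act_log2fc_min, thr.act_padj_max)
    motif_pass = passing(motif_de, thr.act_log2fc_min, thr.act_padj_max)

    rows = []
    for tf in tf_names:
        for g in groups:
            e = (tf, g) in expr_pass
            r = (tf, g) in reg_pass
            m = (tf, g) in motif_pass
            rows.append({
                "tf": tf, "cell_type": g, "expr_pass": e, "regulon_pass": r,
                "motif_pass": m, "prioritized": e and (r or m),
            })
    return pd.DataFrame(rows)


def prioritized_tf_sets(priority: pd.DataFrame) -> dict[str, set]:
    """Map cell type -> set of prioritized TFs (for CellSign annotation)."""
    out: dict[str, set] = {}
    for r in priority[priority["prioritized"]].itertuples(index=False):
        out.setdefault(r.cell_type, set()).add(r.tf)
    return out
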