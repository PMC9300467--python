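"""TF evidence: regulon activity scores, peak filters, motif deviation
z-scores, activity DE and the prioritization rule."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from celltalk import (
    PeakAccessibility,
    RegulonSet,
    RegulonTarget,
    SimConfig,
    TFPriorityThresholds,
    ValidationError,
    activity_de,
    filter_peaks,
    motif_deviations,
    prioritize,
    regulon_activity,
)
from celltalk.datatypes import NormalizedMatrix
from celltalk.simulate import simulate_accessibility, simulate_dataset
from celltalk.tf_activity import RegulonActivity, prioritized_tf_sets


def make_regulons(n_targets=4, mode=1):
    return RegulonSet(
        regulons={"TFX": [RegulonTarget(f"t{i}", mode, 1.0) for i in range(n_targets)]},
        min_targets=2,
    )


class TestRegulonActivity:
    def test_closed_form_signature_score(self):
        est = RegulonActivity(make_regulons(4), min_targets=2)
        est.fit(np.zeros((1, 4)), gene_ids=["t0", "t1", "t2", "t3"])
        # all 4 targets at z=+2, weights 1 -> (2*4)/sqrt(4) = 4
        act = est.score_signature(np.full((1, 4), 2.0))
        assert act[0, 0] == pytest.approx(4.0)

    def test_linear_in_signature(self):
        est = RegulonActivity(make_regulons(4), min_targets=2)
        est.fit(np.zeros((1, 4)), gene_ids=["t0", "t1", "t2", "t3"])
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(6, 4))
        assert np.allclose(est.score_signature(3.0 * Z),
                           3.0 * est.score_signature(Z))

    def test_zero_signature_zero_activity(self):
        norm = NormalizedMatrix(
            values=sp.csr_matrix(np.ones((5, 4))),  # constant genes -> z = 0
            cell_ids=[f"c{i}" for i in range(5)],
            gene_ids=["t0", "t1", "t2", "t3"],
        )
        act = regulon_activity(norm, make_regulons(4), min_targets=2)
        assert np.allclose(act.to_numpy(), 0.0)

    def test_repression_flips_sign(self):
        est_a = RegulonActivity(make_regulons(4, mode=1), min_targets=2)
        est_r = RegulonActivity(make_regulons(4, mode=-1), min_targets=2)
        for est in (est_a, est_r):
            est.fit(np.zeros((1, 4)), gene_ids=["t0", "t1", "t2", "t3"])
        Z = np.random.default_rng(1).normal(size=(5, 4))
        assert np.allclose(est_a.score_signature(Z), -est_r.score_signature(Z))

    def test_small_regulon_dropped(self):
        regs = RegulonSet(
            regulons={
                "BIG": [RegulonTarget(f"t{i}", 1) for i in range(6)],
                "SMALL": [RegulonTarget(f"u{i}", 1) for i in range(6)],
            }, min_targets=5)
        norm = NormalizedMatrix(
            values=sp.csr_matrix(np.random.default_rng(0).poisson(
                1.0, size=(10, 6)).astype(float)),
            cell_ids=[f"c{i}" for i in range(10)],
            gene_ids=[f"t{i}" for i in range(6)],  # SMALL's targets all absent
        )
        with pytest.warns(UserWarning, match="SMALL"):
            act = regulon_activity(norm, regs)
        assert list(act.index) == ["BIG"]

    def test_planted_tf_highest_in_its_type(self, default_dataset):
        from celltalk import normalize_log_cpm100, qc_filter
        ds = default_dataset
        filtered, _ = qc_filter(ds.counts)
        norm = normalize_log_cpm100(filtered)
        act = regulon_activity(norm, ds.regulons)
        labels = filtered.cell_types.to_numpy()
        for ct, tfs in ds.truth.planted_active_tfs.items():
            for tf in tfs:
                means = {g: act.loc[tf, labels == g].mean()
                         for g in np.unique(labels)}
                assert max(means, key=means.get) == ct


def make_peaks(widths, access, chrom="chr1", start0=1000, gap=5000,
               n_motifs=1):
    n = len(widths)
    starts = []
    pos = start0
    for w in widths:
        starts.append(pos)
        pos += w + gap
    peaks = pd.DataFrame({
        "peak_id": [f"p{i}" for i in range(n)],
        "chrom": chrom, "start": starts,
        "end": [s + w for s, w in zip(starts, widths)],
    })
    access = sp.csr_matrix(np.asarray(access))
    annot = sp.csr_matrix(np.ones((n, n_motifs), dtype=np.int8))
    return PeakAccessibility(
        peaks=peaks, access=access,
        cell_ids=[f"c{i}" for i in range(access.shape[1])],
        motif_names=[f"m{j}" for j in range(n_motifs)],
        motif_annot=annot, motif_tf={f"m{j}": f"TF{j}" for j in range(n_motifs)},
        gc_content=np.full(n, 0.5),
    )


class TestFilterPeaks:
    def test_width_bounds_inclusive(self):
        widths = [209, 210, 1500, 1501]
        access = np.ones((4, 10))
        pa = make_peaks(widths, access)
        out = filter_peaks(pa, None, ["k"] * 10)
        assert list(out.peaks["peak_id"]) == ["p1", "p2"]

    def test_accessibility_fraction_rule(self):
        widths = [300, 300]
        access = np.zeros((2, 100))
        access[0, :3] = 1   # 3% everywhere -> dropped
        access[1, :4] = 1   # 4% -> kept
        pa = make_peaks(widths, access)
        out = filter_peaks(pa, None, ["k"] * 100)
        assert list(out.peaks["peak_id"]) == ["p1"]

    def test_peak_survives_if_any_cluster_reaches_fraction(self):
        access = np.zeros((1, 100))
        access[0, :4] = 1  # 8% of cluster A (50 cells), 0% of B
        pa = make_peaks([300], access)
        out = filter_peaks(pa, None, ["A"] * 50 + ["B"] * 50)
        assert len(out.peaks) == 1

    def test_blacklist_single_bp_overlap(self):
        pa = make_peaks([300, 300], np.ones((2, 10)))
        p0 = pa.peaks.iloc[0]
        blacklist = pd.DataFrame([
            {"chrom": "chr1", "start": p0["end"] - 1, "end": p0["end"] + 50,
             "name": "bl"},
        ])
        out = filter_peaks(pa, blacklist, ["k"] * 10)
        assert list(out.peaks["peak_id"]) == ["p1"]

    def test_empty_result_fatal(self):
        pa = make_peaks([100], np.ones((1, 5)))  # width < 210
        with pytest.raises(ValidationError):
            filter_peaks(pa, None, ["k"] * 5)


class TestMotifDeviations:
    def test_null_mean_near_zero(self):
        ds = simulate_dataset(SimConfig(seed=3, motif_effect=0.0))
        labels = ds.counts.cell_meta.loc[
            ds.accessibility.cell_ids, "cell_type"].to_numpy()
        pa = filter_peaks(ds.accessibility, None, labels)
        dev = motif_deviations(pa, n_background=50, seed=0)
        assert np.all(np.abs(dev.mean(axis=1)) < 0.2)

    def test_planted_motif_sign_stable_across_seeds(self, default_dataset):
        # the truth layout is seed-independent; only the draws vary
        truth = default_dataset.truth
        cells_per_type = default_dataset.config.cells_per_type
        types = default_dataset.config.cell_types
        labels = np.repeat(types, cells_per_type)
        for seed in range(20):
            pa = simulate_accessibility(SimConfig(seed=seed), truth)
            dev = motif_deviations(pa, n_background=20, seed=seed)
            for ct, tfs in truth.planted_motif_tfs.items():
                for tf in tfs:
                    assert dev.loc[tf, labels == ct].mean() > 0

    def test_column_permutation_equivariance(self, small_dataset):
        pa = small_dataset.accessibility
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pa.cell_ids))
        pa_perm = PeakAccessibility(
            peaks=pa.peaks, access=pa.access[:, perm],
            cell_ids=[pa.cell_ids[i] for i in perm],
            motif_names=pa.motif_names, motif_annot=pa.motif_annot,
            motif_tf=pa.motif_tf, gc_content=pa.gc_content,
        )
        d0 = motif_deviations(pa, n_background=10, seed=4)
        d1 = motif_deviations(pa_perm, n_background=10, seed=4)
        assert np.allclose(d0.to_numpy()[:, perm], d1.to_numpy())

    def test_seed_reproducibility(self, small_dataset):
        d0 = motif_deviations(small_dataset.accessibility, n_background=10, seed=9)
        d1 = motif_deviations(small_dataset.accessibility, n_background=10, seed=9)
        assert d0.equals(d1)


class TestActivityDE:
    def test_identical_groups_nothing_passes(self):
        rng = np.random.default_rng(0)
        act = pd.DataFrame(rng.normal(size=(4, 200)), index=list("ABCD"))
        labels = np.repeat(["x", "y"], 100)
        res = activity_de(act, labels)
        assert ((res["p_adj"] < 0.01) & (res["log2fc"] > 0.75)).sum() == 0

    def test_planted_tf_passes_thresholds(self, default_dataset):
        from celltalk import normalize_log_cpm100, qc_filter
        ds = default_dataset
        filtered, _ = qc_filter(ds.counts)
        norm = normalize_log_cpm100(filtered)
        act = regulon_activity(norm, ds.regulons)
        res = activity_de(act, filtered.cell_types.to_numpy())
        for ct, tfs in ds.truth.planted_active_tfs.items():
            for tf in tfs:
                row = res[(res["feature"] == tf) & (res["group"] == ct)].iloc[0]
                assert row["log2fc"] > 0.75 and row["p_adj"] < 0.01


class TestPrioritize:
    def _de(self, rows):
        return pd.DataFrame([
            {"feature": f, "group": g, "log2fc": l, "p_raw": p, "p_adj": p}
            for f, g, l, p in rows
        ])

    def test_expression_plus_one_activity(self):
        expr = self._de([("TFX", "T", 0.6, 1e-3)])
        reg = self._de([("TFX", "T", 0.8, 5e-3)])
        motif = self._de([("TFX", "T", 0.1, 0.9)])
        out = prioritize(expr, reg, motif)
        assert out.iloc[0]["prioritized"]

    def test_expression_below_gate_blocks(self):
        expr = self._de([("TFX", "T", 0.4, 1e-9)])
        reg = self._de([("TFX", "T", 2.0, 1e-9)])
        motif = self._de([("TFX", "T", 2.0, 1e-9)])
        out = prioritize(expr, reg, motif)
        assert not out.iloc[0]["prioritized"]

    def test_no_activity_evidence_blocks(self):
        expr = self._de([("TFX", "T", 2.0, 1e-9)])
        reg = self._de([("TFX", "T", 0.1, 0.5)])
        out = prioritize(expr, reg, None)
        row = out.iloc[0]
        assert row["expr_pass"] and not row["prioritized"]
        assert not row["motif_pass"]  # absent modality is False, not missing

    @pytest.mark.parametrize("lfc,padj,passes", [
        (0.5, 1e-3, False),    # "greater than 0.5" is strict
        (0.51, 1e-3, True),
        (0.6, 0.01, False),    # "adjusted P < 0.01" is strict
    ])
    def test_expression_gate_boundaries(self, lfc, padj, passes):
        expr = self._de([("TFX", "T", lfc, padj)])
        reg = self._de([("TFX", "T", 1.0, 1e-6)])
        out = prioritize(expr, reg, None)
        assert bool(out.iloc[0]["prioritized"]) is passes

    @pytest.mark.parametrize("lfc,padj,passes", [
        (0.75, 1e-3, False),   # "greater than 0.75" is strict
        (0.76, 1e-3, True),
    ])
    def test_activity_gate_boundaries(self, lfc, padj, passes):
        expr = self._de([("TFX", "T", 1.0, 1e-6)])
        reg = self._de([("TFX", "T", lfc, padj)])
        out = prioritize(expr, reg, None)
        assert bool(out.iloc[0]["prioritized"]) is passes

    def test_monotone_in_thresholds(self):
        expr = self._de([("TFX", "T", 0.6, 5e-3), ("TFY", "T", 1.2, 1e-4)])
        reg = self._de([("TFX", "T", 0.9, 5e-3), ("TFY", "T", 0.5, 1e-4)])
        strict = prioritize(expr, reg, None, TFPriorityThresholds())
        relaxed = prioritize(expr, reg, None, TFPriorityThresholds(
            expr_log2fc_min=0.3, expr_padj_max=0.05,
            act_log2fc_min=0.4, act_padj_max=0.05))
        s = set(map(tuple, strict[strict["prioritized"]][["tf", "cell_type"]].values))
        r = set(map(tuple, relaxed[relaxed["prioritized"]][["tf", "cell_type"]].values))
        assert s <= r

    def test_prioritized_sets_helper(self):
        expr = self._de([("TFX", "T", 1.0, 1e-6)])
        reg = self._de([("TFX", "T", 1.0, 1e-6)])
        out = prioritize(expr, reg, None)
        assert prioritized_tf_sets(out) == {"T": {"TFX"}}
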