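"""End-to-end orchestration: simulate/load -> QC -> DE -> TF analysis ->
interaction retrieval -> report.

Every stage writes a plain TSV intermediate so each step is independently
inspectable; the run report summarizes counts at each gate together with
the seed and a hash of the resolved configuration.  Stage outputs are
pure functions of (inputs, config, seed), so reruns with the same config
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ctio
from .ccc import (
    CCCThresholds,
    annotate_cellsign,
    filter_by_microenvironment,
    relevant_to_frame,
    retrieve_relevant,
)
from .datatypes import DEFAULT_ZONES, ValidationError
from .de import de_one_vs_all
from .qc import QCThresholds, normalize_log_cpm100, profile_cell_types, qc_filter, tfidf_markers
from .simulate import SimConfig, SyntheticDataset, read_truth, simulate_dataset, write_dataset
from .tf_activity import (
    TFPriorityThresholds,
    activity_de,
    filter_peaks,
    motif_deviations,
    prioritize,
    prioritized_tf_sets,
    regulon_activity,
)

log = logging.getLogger("celltalk")


@dataclass
class PipelineConfig:
    out_dir: str = "celltalk_run"
    input_dir: str | None = None        # dataset directory; None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    ccc: CCCThresholds = field(default_factory=CCCThresholds)
    tf: TFPriorityThresholds = field(default_factory=TFPriorityThresholds)
    adjust: str = "bonferroni"
    zone_filter: bool = True
    de_in_any_type: bool = False
    n_background: int = 50
    marker_top_n: int = 10
    blacklist_path: str | None = None
    zone_vocabulary: tuple = DEFAULT_ZONES
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_vocabulary"] = list(d["zone_vocabulary"])
        if d["sim"].get("zone_vocabulary") is not None:
            d["sim"]["zone_vocabulary"] = list(d["sim"]["zone_vocabulary"])
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land does not change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if sim.get("zone_vocabulary") is not None:
                sim["zone_vocabulary"] = tuple(sim["zone_vocabulary"])
            d["sim"] = SimConfig(**sim)
        for key, typ in (("qc", QCThresholds), ("ccc", CCCThresholds),
                         ("tf", TFPriorityThresholds)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if d.get("zone_vocabulary") is not None:
            d["zone_vocabulary"] = tuple(d["zone_vocabulary"])
        return cls(**d)


@dataclass
class RunReport:
    seed: int
    config_hash: str
    qc: dict
    n_de_genes_by_type: dict
    n_interactions_retrieved: int
    n_interactions_zone_filtered: int
    n_interactions_supported: int
    n_prioritized_tfs: int
    prioritized_tfs: dict
    out_dir: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_dataset(cfg: PipelineConfig) -> SyntheticDataset:
    if cfg.input_dir is None:
        log.info("simulating dataset (seed=%d)", cfg.sim.seed)
        return simulate_dataset(cfg.sim)
    d = Path(cfg.input_dir)
    counts = ctio.read_counts_mtx(d / "counts")
    pa = ctio.read_peaks(
        d / "atac" / "peaks.bed", d / "atac" / "accessibility.mtx",
        d / "atac" / "peak_motifs.tsv", d / "atac" / "atac_barcodes.tsv",
        d / "atac" / "peak_gc.tsv",
    )
    db = ctio.read_interaction_db(d / "partners.tsv", d / "interactions.tsv")
    cellsign = ctio.read_cellsign(d / "cellsign.tsv", db)
    env = ctio.read_microenvironments(d / "microenvironments.tsv",
                                      vocabulary=cfg.zone_vocabulary)
    regulons = ctio.read_regulons(d / "regulons.tsv")
    truth = None
    if (d / "truth_interactions.tsv").exists():
        truth = read_truth(d)
    return SyntheticDataset(
        config=cfg.sim, counts=counts, accessibility=pa, truth=truth,
        db=db, cellsign=cellsign, microenv=env, regulons=regulons,
    )


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order, writing every intermediate table."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _load_dataset(cfg)

    # --- QC + normalization -------------------------------------------------
    filtered, qc_report = qc_filter(ds.counts, cfg.qc)
    log.info("QC: %s", qc_report)
    ctio.write_table(pd.DataFrame([qc_report]), out / "qc_report.tsv")
    norm = normalize_log_cpm100(filtered)
    labels = filtered.cell_types.to_numpy()
    profile = profile_cell_types(norm, filtered, labels)
    ctio.write_table(profile, out / "profile.tsv",
                     sort_by=["cell_type", "gene"])
    markers = tfidf_markers(filtered, labels, top_n=cfg.marker_top_n)
    ctio.write_table(markers, out / "markers.tsv", sort_by=["cluster", "rank"])

    # --- gene-level one-vs-all DE ------------------------------------------
    expr_de = de_one_vs_all(norm.values.T, labels,
                            feature_names=norm.gene_ids, adjust=cfg.adjust)
    ctio.write_table(expr_de, out / "de_genes.tsv", sort_by=["group", "feature"])
    de_hits = expr_de[(expr_de["p_adj"] < cfg.ccc.de_padj_max)
                      & (expr_de["log2fc"] > cfg.ccc.de_log2fc_min)]
    n_de_by_type = de_hits.groupby("group").size().to_dict()

    # --- TF evidence: regulon activity -------------------------------------
    reg_act = regulon_activity(norm, ds.regulons)
    reg_de = activity_de(reg_act, labels, adjust=cfg.adjust)
    ctio.write_table(reg_de, out / "de_regulon_activity.tsv",
                     sort_by=["group", "feature"])

    # --- TF evidence: motif accessibility deviations ------------------------
    blacklist = (ctio.read_bed(cfg.blacklist_path)
                 if cfg.blacklist_path else None)
    atac_meta = ds.counts.cell_meta  # pre-QC: ATAC cells follow raw barcodes
    atac_labels = atac_meta.loc[ds.accessibility.cell_ids, "cell_type"].to_numpy()
    peaks = filter_peaks(ds.accessibility, blacklist, atac_labels)
    dev = motif_deviations(peaks, n_background=cfg.n_background, seed=cfg.seed)
    motif_de = activity_de(dev, atac_labels, adjust=cfg.adjust)
    ctio.write_table(motif_de, out / "de_motif_activity.tsv",
                     sort_by=["group", "feature"])

    # --- TF prioritization ---------------------------------------------------
    tf_names = set(reg_act.index) | set(dev.index)
    priority = prioritize(expr_de, reg_de, motif_de, cfg.tf, tf_names=tf_names)
    ctio.write_table(priority, out / "tf_priority.tsv",
                     sort_by=["tf", "cell_type"])
    active = prioritized_tf_sets(priority)

    # --- interaction retrieval ----------------------------------------------
    relevant = retrieve_relevant(profile, expr_de, ds.db, cfg.ccc,
                                 de_in_any_type=cfg.de_in_any_type)
    n_retrieved = len(relevant)
    if cfg.zone_filter:
        relevant = filter_by_microenvironment(relevant, ds.microenv)
    n_zone = len(relevant)
    relevant = annotate_cellsign(relevant, ds.cellsign, active, ds.db)
    rel_df = relevant_to_frame(relevant)
    ctio.write_table(rel_df, out / "relevant_interactions.tsv",
                     sort_by=["interaction_id", "sender_type", "receiver_type"])

    report = RunReport(
        seed=cfg.seed,
        config_hash=cfg.config_hash(),
        qc=qc_report,
        n_de_genes_by_type={str(k): int(v) for k, v in n_de_by_type.items()},
        n_interactions_retrieved=n_retrieved,
        n_interactions_zone_filtered=n_zone,
        n_interactions_supported=int(rel_df["supported"].sum()) if len(rel_df) else 0,
        n_prioritized_tfs=int(priority["prioritized"].sum()),
        prioritized_tfs={ct: sorted(tfs) for ct, tfs in sorted(active.items())},
        out_dir=str(out),
    )
    report_disk = report.to_dict()
    report_disk.pop("out_dir")  # keep on-disk artifacts path-independent
    (out / "report.json").write_text(
        json.dumps(report_disk, indent=2, sort_keys=True) + "\n"
    )
    cfg_disk = cfg.to_dict()
    cfg_disk.pop("out_dir")
    (out / "resolved_config.json").write_text(
        json.dumps(cfg_disk, indent=2, sort_keys=True, default=str) + "\n"
    )
    return report


# ---------------------------------------------------------------------------
# evaluation against planted truth


def _safe_ratio(num: int, den: int):
    return float(num) / den if den else float("nan")


def evaluate_run(relevant: pd.DataFrame, priority: pd.DataFrame,
                 truth) -> pd.DataFrame:
    """Precision/recall of recovered interactions and prioritized TFs.

    Interactions compare on (interaction_id, sender, receiver) triples,
    TFs on (tf, cell_type) pairs.  Metrics are NaN when undefined (no
    planted items for recall, nothing recovered for precision).
    """
    truth_set = {
        (p["interaction_id"], p["sender_type"], p["receiver_type"])
        for p in truth.planted_interactions
    }
    found = (set(zip(relevant["interaction_id"], relevant["sender_type"],
                     relevant["receiver_type"]))
             if len(relevant) else set())
    decoy_found = {f for f in found if f[0] in set(truth.decoys)}

    tf_truth = {
        (tf, ct) for ct, tfs in truth.planted_active_tfs.items() for tf in tfs
    }
    tf_found = (set(zip(priority.loc[priority["prioritized"], "tf"],
                        priority.loc[priority["prioritized"], "cell_type"]))
                if len(priority) else set())

    rows = [
        {
            "stage": "interactions",
            "n_truth": len(truth_set),
            "n_found": len(found),
            "n_correct": len(found & truth_set),
            "n_decoys_retained": len(decoy_found),
            "precision": _safe_ratio(len(found & truth_set), len(found)),
            "recall": _safe_ratio(len(found & truth_set), len(truth_set)),
        },
        {
            "stage": "tfs",
            "n_truth": len(tf_truth),
            "n_found": len(tf_found),
            "n_correct": len(tf_found & tf_truth),
            "n_decoys_retained": 0,
            "precision": _safe_ratio(len(tf_found & tf_truth), len(tf_found)),
            "recall": _safe_ratio(len(tf_found & tf_truth), len(tf_truth)),
        },
    ]
    return pd.DataFrame(rows)


def evaluate_against_truth(results_dir, truth_dir) -> pd.DataFrame:
    """File-based evaluation: pipeline outputs vs a written truth manifest."""
    rd, td = Path(results_dir), Path(truth_dir)
    relevant = pd.read_csv(rd / "relevant_interactions.tsv", sep="\t")
    priority = pd.read_csv(rd / "tf_priority.tsv", sep="\t")
    truth = read_truth(td)
    metrics = evaluate_run(relevant, priority, truth)
    ctio.write_table(metrics, rd / "evaluation.tsv", sort_by=["stage"])
    return metrics


def simulate_to_dir(sim: SimConfig, out_dir) -> SyntheticDataset:
    ds = simulate_dataset(sim)
    write_dataset(ds, out_dir)
    return ds
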