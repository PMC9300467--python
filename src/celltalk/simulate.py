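"""Synthetic single-cell datasets with planted ground truth.

The generator emulates the statistical structure the downstream gates
assume, not real gonadal biology: negative-binomial counts with
log-normal per-gene baselines and per-cell library sizes; cell-type
marker genes; ligand-receptor pairs whose partners are selectively
expressed and differentially up in the sender/receiver types; decoy
pairs that must NOT survive (wrong spatial zone, receptor below the
detection-fraction gate, or expressed everywhere with no differential
signal); TF regulons whose targets shift in the TF's active cell type;
and a binary peak accessibility matrix in which planted motifs gain
accessibility in their TF's cell type.

Every random draw flows from ``SimConfig.seed`` through
``numpy.random.default_rng`` so a fixed config reproduces byte-identical
datasets.  When an effect size is zero the corresponding entries still
appear in the database tables (so the pipeline has something to gate)
but are recorded as decoys / absent from the planted truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as ctio
from .datatypes import (
    CellSignTable,
    CountMatrix,
    DEFAULT_ZONES,
    Interaction,
    InteractionDB,
    MicroenvironmentTable,
    Partner,
    PeakAccessibility,
    RegulonSet,
    RegulonTarget,
    ValidationError,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator (defaults = the
    conditions exercised by the test-suite's planted-truth checks)."""

    n_cell_types: int = 6
    cells_per_type: int = 300
    n_genes: int = 1500
    nb_dispersion: float = 2.0          # NB shape theta; var = m + m^2/theta
    baseline_mean: float = 1.0          # scale of per-gene baseline means
    marker_log2fc: float = 3.0
    n_planted_interactions: int = 6
    n_decoy_interactions: int = 6
    planted_interaction_log2fc: float = 2.0
    zone_assignment: dict | None = None  # cell_type -> set of zones
    n_regulons: int = 3
    targets_per_regulon: int = 10
    regulon_effect: float = 1.0          # natural-log shift of target means
    n_peaks: int = 400
    n_motifs: int = 3
    motif_effect: float = 0.3            # added accessibility probability
    seed: int = 0
    # secondary knobs (held fixed across the study conditions)
    n_markers_per_type: int = 5
    library_sigma: float = 0.3           # per-cell log-normal size factor
    gene_sigma: float = 0.5              # per-gene log-normal baseline spread
    interaction_base: float = 0.05       # baseline mean of interaction genes
    decoy_express_base: float = 0.5      # mean of "expressed, no DE" decoy genes
    tf_base: float = 0.3
    tf_log2fc: float = 1.5               # TF transcript elevation in active type
    target_base: float = 0.5
    n_repressed_per_regulon: int = 2
    atac_base_prob: float = 0.1
    n_samples: int = 2
    zone_vocabulary: tuple = DEFAULT_ZONES

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "cells_per_type", "n_genes", "n_regulons",
                     "targets_per_regulon", "n_peaks", "n_motifs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("marker_log2fc", "planted_interaction_log2fc",
                     "regulon_effect", "motif_effect"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{name} must be >= 0 (negative effects would make planted "
                    "and decoy sets overlap)"
                )
        if self.n_peaks < self.n_motifs * 10:
            raise ValidationError(
                f"n_peaks={self.n_peaks} < 10 x n_motifs={self.n_motifs}: "
                "insufficient peaks per motif"
            )

    @property
    def cell_types(self) -> list[str]:
        return [f"ct{i}" for i in range(self.n_cell_types)]

    def zones_for(self, i: int) -> set[str]:
        ct = self.cell_types[i]
        if self.zone_assignment is not None:
            return set(self.zone_assignment[ct])
        nz = len(self.zone_vocabulary)
        return {self.zone_vocabulary[(i * nz) // self.n_cell_types]}


@dataclass
class SyntheticTruth:
    planted_interactions: list[dict]
    planted_active_tfs: dict[str, list[str]]
    planted_motif_tfs: dict[str, list[str]]
    decoys: list[str]
    markers_by_type: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        planted_ids = {p["interaction_id"] for p in self.planted_interactions}
        if planted_ids & set(self.decoys):
            raise ValidationError("planted and decoy interaction sets overlap")


@dataclass
class SyntheticDataset:
    """Bundle of everything one simulated study comprises."""

    config: SimConfig
    counts: CountMatrix
    accessibility: PeakAccessibility
    truth: SyntheticTruth
    db: InteractionDB
    cellsign: CellSignTable
    microenv: MicroenvironmentTable
    regulons: RegulonSet


# ---------------------------------------------------------------------------
# deterministic layout: which genes play which role, which pairs are planted


def _same_zone_pairs(cfg: SimConfig) -> list[tuple[int, int]]:
    pairs = []
    for rev in (False, True):
        for s in range(cfg.n_cell_types):
            for r in range(s + 1, cfg.n_cell_types):
                if cfg.zones_for(s) & cfg.zones_for(r):
                    pairs.append((r, s) if rev else (s, r))
    return pairs


def _cross_zone_pairs(cfg: SimConfig) -> list[tuple[int, int]]:
    return [
        (s, r)
        for s in range(cfg.n_cell_types)
        for r in range(cfg.n_cell_types)
        if s != r and not (cfg.zones_for(s) & cfg.zones_for(r))
    ]


def _build_layout(cfg: SimConfig) -> dict:
    """Assign gene names to roles and construct the database tables."""
    types = cfg.cell_types
    same = _same_zone_pairs(cfg)
    cross = _cross_zone_pairs(cfg)
    if not same:
        raise ValidationError("no same-zone cell-type pair; cannot plant interactions")

    genes: list[str] = []
    elevations: list[tuple[str, int, float]] = []  # (gene, type index, multiplier)
    base_means: dict[str, float] = {}

    def add_gene(name, base):
        genes.append(name)
        base_means[name] = base
        return name

    markers_by_type: dict[str, list[str]] = {t: [] for t in types}
    for ti, t in enumerate(types):
        for i in range(cfg.n_markers_per_type):
            g = add_gene(f"MRK{ti}_{i}", 0.1 * cfg.baseline_mean)
            if cfg.marker_log2fc > 0:
                elevations.append((g, ti, 2.0 ** cfg.marker_log2fc))
                markers_by_type[t].append(g)

    partners: dict[str, Partner] = {}
    interactions: list[Interaction] = []
    planted: list[dict] = []
    decoys: list[str] = []
    cellsign_rows: list[tuple[str, str, str]] = []
    lfc_mult = 2.0 ** cfg.planted_interaction_log2fc
    ibase = cfg.interaction_base * cfg.baseline_mean

    receptor_partner: dict[str, str] = {}
    for k in range(cfg.n_planted_interactions):
        s, r = same[k % len(same)]
        iid = f"I{k}"
        # ligand side: enzyme proxy every 4th interaction (k % 4 == 3)
        if k % 4 == 3:
            lg = add_gene(f"ENZ{k}", ibase)
            lig_id = f"smallmol_via_ENZ{k}"
            partners[lig_id] = Partner(lig_id, "enzyme_proxy", [lg])
            lig_genes = [lg]
        else:
            lg = add_gene(f"LIG{k}", ibase)
            lig_id = lg
            partners[lig_id] = Partner(lig_id, "gene", [lg])
            lig_genes = [lg]
        # receptor side: heteromeric complex every 4th interaction (k % 4 == 1)
        if k % 4 == 1:
            ra = add_gene(f"REC{k}A", ibase)
            rb = add_gene(f"REC{k}B", ibase)
            rec_id = f"cplx_REC{k}"
            partners[rec_id] = Partner(rec_id, "complex", [ra, rb])
            rec_genes = [ra, rb]
        else:
            rg = add_gene(f"REC{k}", ibase)
            rec_id = rg
            partners[rec_id] = Partner(rec_id, "gene", [rg])
            rec_genes = [rg]
        interactions.append(Interaction(iid, lig_id, rec_id, "ligand_receptor",
                                        "planted" if lfc_mult > 1 else "null"))
        receptor_partner[iid] = rec_id
        if lfc_mult > 1:
            for g in lig_genes:
                elevations.append((g, s, lfc_mult))
            for g in rec_genes:
                elevations.append((g, r, lfc_mult))
            planted.append({
                "interaction_id": iid,
                "sender_type": types[s],
                "receiver_type": types[r],
                "shared_zone": sorted(cfg.zones_for(s) & cfg.zones_for(r))[0],
            })
        else:
            decoys.append(iid)

    decoy_kinds = ["zone_mismatch", "sub_fraction", "no_de"]
    for k in range(cfg.n_decoy_interactions):
        kind = decoy_kinds[k % 3]
        iid = f"D{k}"
        if kind == "zone_mismatch":
            if not cross:
                kind = "sub_fraction"  # no disjoint-zone pair available
        if kind == "zone_mismatch":
            s, r = cross[k % len(cross)]
            lg = add_gene(f"DLIG{k}", ibase)
            rg = add_gene(f"DREC{k}", ibase)
            if lfc_mult > 1:
                elevations.append((lg, s, lfc_mult))
                elevations.append((rg, r, lfc_mult))
        elif kind == "sub_fraction":
            s, r = same[k % len(same)]
            lg = add_gene(f"DLIG{k}", ibase)
            rg = add_gene(f"DREC{k}", ibase)  # stays below the fraction gate
            if lfc_mult > 1:
                elevations.append((lg, s, lfc_mult))
        else:  # expressed everywhere, never DE
            s, r = same[k % len(same)]
            lg = add_gene(f"DLIG{k}", cfg.decoy_express_base * cfg.baseline_mean)
            rg = add_gene(f"DREC{k}", cfg.decoy_express_base * cfg.baseline_mean)
        partners[lg] = Partner(lg, "gene", [lg])
        partners[rg] = Partner(rg, "gene", [rg])
        interactions.append(Interaction(iid, lg, rg, "ligand_receptor", f"decoy:{kind}"))
        decoys.append(iid)

    # TF regulons: TF j is planted active in the receiver of planted
    # interaction j (when one exists), wiring CellSign support end to end.
    regulons: dict[str, list[RegulonTarget]] = {}
    planted_active: dict[str, list[str]] = {}
    tf_type_idx: list[int] = []
    for j in range(cfg.n_regulons):
        tf = f"TF{j}"
        if j < len(planted):
            tidx = types.index(planted[j]["receiver_type"])
        else:
            tidx = (2 * j + 1) % cfg.n_cell_types
        tf_type_idx.append(tidx)
        tf_gene = add_gene(tf, cfg.tf_base * cfg.baseline_mean)
        targets = []
        n_rep = min(cfg.n_repressed_per_regulon, cfg.targets_per_regulon - 1)
        for i in range(cfg.targets_per_regulon):
            mode = -1 if i >= cfg.targets_per_regulon - n_rep else 1
            tg = add_gene(f"TG{j}_{i}", cfg.target_base * cfg.baseline_mean)
            targets.append(RegulonTarget(tg, mode, 1.0))
            if cfg.regulon_effect > 0:
                mult = float(np.exp(mode * cfg.regulon_effect))
                elevations.append((tg, tidx, mult))
        regulons[tf] = targets
        if cfg.regulon_effect > 0:
            elevations.append((tf_gene, tidx, 2.0 ** cfg.tf_log2fc))
            planted_active.setdefault(types[tidx], []).append(tf)
        if j < cfg.n_planted_interactions:
            cellsign_rows.append((receptor_partner[f"I{j}"], tf, f"PMID:1000{j}"))

    planted_motifs: dict[str, list[str]] = {}
    if cfg.motif_effect > 0:
        for j in range(min(cfg.n_motifs, cfg.n_regulons)):
            planted_motifs.setdefault(types[tf_type_idx[j]], []).append(f"TF{j}")

    if len(genes) > cfg.n_genes:
        raise ValidationError(
            f"n_genes={cfg.n_genes} too small for the planted layout "
            f"({len(genes)} role genes)"
        )
    n_bg = cfg.n_genes - len(genes)
    for i in range(n_bg):
        add_gene(f"BG{i}", cfg.baseline_mean)  # per-gene spread applied later

    return {
        "genes": genes,
        "base_means": base_means,
        "elevations": elevations,
        "n_background": n_bg,
        "db": InteractionDB(partners=partners, interactions=interactions),
        "cellsign": CellSignTable(rows=cellsign_rows),
        "regulons": RegulonSet(regulons=regulons,
                               min_targets=min(5, cfg.targets_per_regulon)),
        "truth": SyntheticTruth(
            planted_interactions=planted,
            planted_active_tfs=planted_active,
            planted_motif_tfs=planted_motifs,
            decoys=decoys,
            markers_by_type=markers_by_type,
        ),
        "tf_type_idx": tf_type_idx,
    }


def microenvironment_table(cfg: SimConfig) -> MicroenvironmentTable:
    return MicroenvironmentTable(
        zones_by_type={cfg.cell_types[i]: cfg.zones_for(i)
                       for i in range(cfg.n_cell_types)},
        vocabulary=tuple(cfg.zone_vocabulary),
    )


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw the count matrix and return it with the planted-truth manifest."""
    cm, truth, _ = _simulate_counts_full(cfg)
    return cm, truth


def _simulate_counts_full(cfg: SimConfig):
    layout = _build_layout(cfg)
    rng = np.random.default_rng(cfg.seed)
    genes = layout["genes"]
    n_types, n_genes = cfg.n_cell_types, cfg.n_genes

    base = np.array([layout["base_means"][g] for g in genes])
    # background genes get a log-normal spread around the baseline scale
    bg_mask = np.array([g.startswith("BG") for g in genes])
    spread = rng.lognormal(mean=0.0, sigma=cfg.gene_sigma, size=int(bg_mask.sum()))
    base[bg_mask] = cfg.baseline_mean * spread

    M = np.tile(base, (n_types, 1))
    gene_idx = {g: j for j, g in enumerate(genes)}
    for g, ti, mult in layout["elevations"]:
        M[ti, gene_idx[g]] *= mult

    theta = cfg.nb_dispersion
    blocks, meta_rows, cell_ids = [], [], []
    for ti, ct in enumerate(cfg.cell_types):
        n = cfg.cells_per_type
        factors = rng.lognormal(mean=0.0, sigma=cfg.library_sigma, size=n)
        mean = np.outer(factors, M[ti])
        lam = rng.gamma(shape=theta, scale=mean / theta)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        zone = sorted(cfg.zones_for(ti))[0]
        for i in range(n):
            cid = f"cell_{ti:02d}_{i:04d}"
            cell_ids.append(cid)
            meta_rows.append({
                "barcode": cid, "cell_type": ct,
                "sample": f"sample{(i % cfg.n_samples)}", "zone": zone,
            })
    counts = sp.vstack(blocks).tocsr()
    meta = pd.DataFrame(meta_rows).set_index("barcode")
    cm = CountMatrix(counts=counts, cell_ids=cell_ids, gene_ids=genes, cell_meta=meta)
    return cm, layout["truth"], layout


def simulate_accessibility(cfg: SimConfig, truth: SyntheticTruth
                           ) -> PeakAccessibility:
    """Binary peaks x cells accessibility with planted motif enrichment.

    Peaks carrying a planted motif have their accessibility probability
    raised by ``motif_effect`` in cells of the motif TF's planted type.
    Peak widths are drawn inside the retained 210-1,500 bp range and GC
    content uniformly in [0.3, 0.7].
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n_peaks, n_motifs = cfg.n_peaks, cfg.n_motifs
    widths = rng.integers(210, 1501, size=n_peaks)
    gaps = rng.integers(1000, 5000, size=n_peaks)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(widths)[:-1]])
    peaks = pd.DataFrame({
        "peak_id": [f"peak_{i:05d}" for i in range(n_peaks)],
        "chrom": "chr1",
        "start": starts,
        "end": starts + widths,
    })
    gc = rng.uniform(0.3, 0.7, size=n_peaks)

    ppm = max(10, n_peaks // max(1, 2 * n_motifs))
    motif_names = [f"MOTIF_TF{j}" for j in range(n_motifs)]
    motif_tf = {f"MOTIF_TF{j}": f"TF{j}" for j in range(n_motifs)}
    annot = sp.lil_matrix((n_peaks, n_motifs), dtype=np.int8)
    for j in range(n_motifs):
        annot[j * ppm:(j + 1) * ppm, j] = 1

    types = cfg.cell_types
    labels = np.repeat(np.arange(cfg.n_cell_types), cfg.cells_per_type)
    cell_ids = [f"cell_{ti:02d}_{i:04d}"
                for ti in range(cfg.n_cell_types)
                for i in range(cfg.cells_per_type)]

    prob = np.full((n_peaks, len(cell_ids)), cfg.atac_base_prob)
    tf_planted_type = {
        tf: types.index(ct)
        for ct, tfs in truth.planted_motif_tfs.items() for tf in tfs
    }
    for j in range(n_motifs):
        tf = motif_tf[motif_names[j]]
        if tf in tf_planted_type:
            rows = np.arange(j * ppm, (j + 1) * ppm)
            cols = np.where(labels == tf_planted_type[tf])[0]
            prob[np.ix_(rows, cols)] = min(1.0, cfg.atac_base_prob + cfg.motif_effect)
    access = sp.csr_matrix((rng.random(prob.shape) < prob).astype(np.int8))

    return PeakAccessibility(
        peaks=peaks, access=access, cell_ids=cell_ids,
        motif_names=motif_names, motif_annot=annot.tocsr(),
        motif_tf=motif_tf, gc_content=gc,
    )


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full bundle: counts, accessibility, DB tables, truth."""
    cm, truth, layout = _simulate_counts_full(cfg)
    pa = simulate_accessibility(cfg, truth)
    return SyntheticDataset(
        config=cfg, counts=cm, accessibility=pa, truth=truth,
        db=layout["db"], cellsign=layout["cellsign"],
        microenv=microenvironment_table(cfg), regulons=layout["regulons"],
    )


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Emit the dataset exactly as the readers consume it, plus truth tables."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    ctio.write_counts_mtx(ds.counts, d / "counts")
    ctio.write_peaks(ds.accessibility, d / "atac")
    ctio.write_interaction_db(ds.db, d / "partners.tsv", d / "interactions.tsv")
    ctio.write_cellsign(ds.cellsign, d / "cellsign.tsv")
    ctio.write_microenvironments(ds.microenv, d / "microenvironments.tsv")
    ctio.write_regulons(ds.regulons, d / "regulons.tsv")

    ctio.write_table(
        pd.DataFrame(ds.truth.planted_interactions,
                     columns=["interaction_id", "sender_type", "receiver_type",
                              "shared_zone"]),
        d / "truth_interactions.tsv",
    )
    ctio.write_table(
        pd.DataFrame(
            [{"cell_type": ct, "tf": tf}
             for ct, tfs in ds.truth.planted_active_tfs.items() for tf in tfs],
            columns=["cell_type", "tf"]),
        d / "truth_tfs.tsv",
    )
    ctio.write_table(
        pd.DataFrame(
            [{"cell_type": ct, "tf": tf}
             for ct, tfs in ds.truth.planted_motif_tfs.items() for tf in tfs],
            columns=["cell_type", "tf"]),
        d / "truth_motif_tfs.tsv",
    )
    ctio.write_table(pd.DataFrame({"interaction_id": sorted(ds.truth.decoys)}),
                     d / "truth_decoys.tsv")
    cfg_dict = dataclasses.asdict(ds.config)
    cfg_dict["zone_vocabulary"] = list(cfg_dict["zone_vocabulary"])
    if cfg_dict["zone_assignment"] is not None:
        cfg_dict["zone_assignment"] = {
            k: sorted(v) for k, v in cfg_dict["zone_assignment"].items()
        }
    (d / "sim_config.json").write_text(json.dumps(cfg_dict, indent=2, sort_keys=True))


def read_truth(in_dir) -> SyntheticTruth:
    d = Path(in_dir)
    pi = pd.read_csv(d / "truth_interactions.tsv", sep="\t")
    tfs = pd.read_csv(d / "truth_tfs.tsv", sep="\t")
    mtf = pd.read_csv(d / "truth_motif_tfs.tsv", sep="\t")
    dec = pd.read_csv(d / "truth_decoys.tsv", sep="\t")
    active: dict[str, list[str]] = {}
    for r in tfs.itertuples(index=False):
        active.setdefault(r.cell_type, []).append(r.tf)
    motifs: dict[str, list[str]] = {}
    for r in mtf.itertuples(index=False):
        motifs.setdefault(r.cell_type, []).append(r.tf)
    return SyntheticTruth(
        planted_interactions=pi.to_dict("records"),
        planted_active_tfs=active,
        planted_motif_tfs=motifs,
        decoys=dec["interaction_id"].tolist() if len(dec) else [],
    )
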