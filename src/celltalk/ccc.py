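"""DEG-based ligand-receptor retrieval with heteromeric complex gates,
spatial microenvironment filtering and receptor-to-TF (CellSign) support.

An interaction is relevant for an ordered (sender, receiver) cell-type
pair when (1) every member gene of the ligand partner is detected in at
least ``min_fraction`` of sender cells and likewise the receptor partner
in receiver cells, and (2) at least one member gene of either partner is
differentially expressed in its own cell type (adjusted p strictly below
``de_padj_max`` and log2 fold change strictly above ``de_log2fc_min``).
Interactions whose sender and receiver types share no spatial zone are
excluded when a microenvironment table is supplied.  Finally each
retained interaction is annotated with the downstream TFs of its
receptor and flagged as supported when any of those TFs is active in the
receiver type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import (
    CellSignTable,
    InteractionDB,
    MicroenvironmentTable,
    ValidationError,
)


@dataclass
class CCCThresholds:
    min_fraction: float = 0.10      # inclusive: "at least 10%"
    de_padj_max: float = 0.01       # strict:    "below 0.01"
    de_log2fc_min: float = 0.2      # strict:    "above 0.2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_fraction <= 1.0):
            raise ValidationError("min_fraction must be in [0,1]")


@dataclass
class RelevantInteraction:
    interaction_id: str
    sender_type: str
    receiver_type: str
    de_partner: str          # "a" | "b" | "both"
    de_genes: list[str]
    shared_zones: set[str] = field(default_factory=set)
    cellsign_tfs: list[dict] = field(default_factory=list)
    supported: bool = False

    def to_record(self) -> dict:
        return {
            "interaction_id": self.interaction_id,
            "sender_type": self.sender_type,
            "receiver_type": self.receiver_type,
            "de_partner": self.de_partner,
            "de_genes": ",".join(sorted(self.de_genes)),
            "shared_zones": ",".join(sorted(self.shared_zones)),
            "cellsign_tfs": ",".join(
                f"{d['tf_gene']}:{'active' if d['active_in_receiver'] else 'inactive'}"
                for d in self.cellsign_tfs
            ),
            "supported": self.supported,
        }


def _fraction_lookup(profile: pd.DataFrame) -> dict:
    return {
        (r.cell_type, r.gene): r.fraction_expressing
        for r in profile.itertuples(index=False)
    }


def partner_expressed(profile, partner, cell_type: str,
                      min_fraction: float = 0.10) -> bool:
    """True iff every member gene of the partner is detected in at least
    ``min_fraction`` (inclusive) of the given cell type's cells.

    Enzyme-proxy partners are evaluated on their enzyme gene(s).  A
    member gene absent from the profile counts as fraction 0, with a
    warning.
    """
    frac = profile if isinstance(profile, dict) else _fraction_lookup(profile)
    for gene in partner.member_genes:
        key = (cell_type, gene)
        if key not in frac:
            warnings.warn(
                f"gene {gene!r} (partner {partner.partner_id!r}) absent from "
                f"profile for {cell_type!r}; treated as fraction 0"
            )
            return False
        if frac[key] < min_fraction:
            return False
    return True


def _de_pass_lookup(de: pd.DataFrame, thr: CCCThresholds) -> set:
    """(cell_type, gene) pairs meeting the DE gate."""
    if de is None or not len(de):
        return set()
    hit = de[(de["p_adj"] < thr.de_padj_max) & (de["log2fc"] > thr.de_log2fc_min)]
    return set(zip(hit["group"], hit["feature"]))


def retrieve_relevant(profile: pd.DataFrame, de: pd.DataFrame,
                      db: InteractionDB, thr: CCCThresholds | None = None,
                      de_in_any_type: bool = False
                      ) -> list[RelevantInteraction]:
    """Scan every interaction against every ordered cell-type pair.

    ``profile`` is the per-(cell_type, gene) expression summary and
    ``de`` the one-vs-all DE table computed on the same labels.  For
    ligand->receptor interactions partner_a is evaluated in the sender
    and partner_b in the receiver; undirected interactions are tested in
    both orientations.  By default a member gene satisfies the DE gate
    only if it is DE in the cell type where its partner is evaluated;
    ``de_in_any_type=True`` relaxes this to DE in any cell type.
    """
    thr = thr or CCCThresholds()
    frac = _fraction_lookup(profile)
    de_pass = _de_pass_lookup(de, thr)
    de_genes_any = {g for _, g in de_pass}
    cell_types = sorted(profile["cell_type"].unique().tolist())

    def gate(genes, cell_type):
        if de_in_any_type:
            return [g for g in genes if g in de_genes_any]
        return [g for g in genes if (cell_type, g) in de_pass]

    out: list[RelevantInteraction] = []
    for inter in db.interactions:
        orientations = [(inter.partner_a, inter.partner_b)]
        if inter.directionality == "undirected":
            orientations.append((inter.partner_b, inter.partner_a))
        for pa_id, pb_id in orientations:
            pa, pb = db.partners[pa_id], db.partners[pb_id]
            for sender in cell_types:
                if not partner_expressed(frac, pa, sender, thr.min_fraction):
                    continue
                for receiver in cell_types:
                    if not partner_expressed(frac, pb, receiver, thr.min_fraction):
                        continue
                    de_a = gate(pa.member_genes, sender)
                    de_b = gate(pb.member_genes, receiver)
                    if not de_a and not de_b:
                        continue
                    de_partner = "both" if de_a and de_b else ("a" if de_a else "b")
                    out.append(RelevantInteraction(
                        interaction_id=inter.interaction_id,
                        sender_type=sender,
                        receiver_type=receiver,
                        de_partner=de_partner,
                        de_genes=sorted(set(de_a + de_b)),
                    ))
    out.sort(key=lambda r: (r.interaction_id, r.sender_type, r.receiver_type))
    return out


def filter_by_microenvironment(interactions: list[RelevantInteraction],
                               env: MicroenvironmentTable
                               ) -> list[RelevantInteraction]:
    """Keep interactions whose sender and receiver types share a zone.

    Every sender/receiver type must appear in the table; a missing type
    is an error rather than a silent pass-through.
    """
    kept = []
    for r in interactions:
        shared = env.zones(r.sender_type) & env.zones(r.receiver_type)
        if shared:
            r.shared_zones = shared
            kept.append(r)
    return kept


def annotate_cellsign(interactions: list[RelevantInteraction],
                      cellsign: CellSignTable,
                      active_tfs: dict[str, set],
                      db: InteractionDB | None = None
                      ) -> list[RelevantInteraction]:
    """Attach downstream TFs to each interaction's receptor and flag support.

    ``active_tfs`` maps cell type -> set of TFs deemed active there
    (normally the prioritized TFs from the TF analysis).  The receptor
    partner is partner_b of the interaction as retrieved; an interaction
    is supported iff at least one downstream TF is active in the
    receiver type.  Receptors without a CellSign entry get an empty TF
    list and supported = False.
    """
    receptor_of = {}
    if db is not None:
        receptor_of = {i.interaction_id: i.partner_b for i in db.interactions}
    for r in interactions:
        receptor = receptor_of.get(r.interaction_id, r.interaction_id)
        tfs = cellsign.tfs_for(receptor)
        active_here = active_tfs.get(r.receiver_type, set())
        r.cellsign_tfs = [
            {"tf_gene": tf, "active_in_receiver": tf in active_here} for tf in tfs
        ]
        r.supported = any(d["active_in_receiver"] for d in r.cellsign_tfs)
    return interactions


def relevant_to_frame(interactions: list[RelevantInteraction]) -> pd.DataFrame:
    cols = ["interaction_id", "sender_type", "receiver_type", "de_partner",
            "de_genes", "shared_zones", "cellsign_tfs", "supported"]
    return pd.DataFrame([r.to_record() for r in interactions], columns=cols)
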