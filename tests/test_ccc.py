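"""Interaction retrieval gates: expression fraction, DE rule, spatial
zones and receptor-to-TF support."""

import warnings

import numpy as np
import pandas as pd
import pytest

from celltalk import (
    CCCThresholds,
    CellSignTable,
    Interaction,
    InteractionDB,
    MicroenvironmentTable,
    Partner,
    annotate_cellsign,
    filter_by_microenvironment,
    partner_expressed,
    retrieve_relevant,
)
from celltalk.ccc import RelevantInteraction, relevant_to_frame
from celltalk.datatypes import ValidationError


def make_profile(fracs):
    """fracs: {(cell_type, gene): fraction} -> profile DataFrame."""
    return pd.DataFrame([
        {"cell_type": ct, "gene": g, "mean_norm_expression": 1.0,
         "fraction_expressing": f, "n_cells": 100}
        for (ct, g), f in fracs.items()
    ])


def make_de(rows):
    """rows: (gene, cell_type, log2fc, p_adj) tuples."""
    return pd.DataFrame([
        {"feature": g, "group": ct, "log2fc": l, "p_raw": p / 2, "p_adj": p,
         "frac_in": 0.5, "frac_out": 0.1, "n_in": 100, "n_out": 500}
        for g, ct, l, p in rows
    ])


def simple_db():
    partners = {
        "L": Partner("L", "gene", ["L"]),
        "R": Partner("R", "gene", ["R"]),
    }
    return InteractionDB(partners=partners, interactions=[
        Interaction("ix", "L", "R", "ligand_receptor"),
    ])


class TestPartnerExpressed:
    def test_complex_requires_every_member(self):
        cplx = Partner("cplx", "complex", ["A", "B"])
        prof = {("T", "A"): 0.12, ("T", "B"): 0.09}
        assert partner_expressed(prof, cplx, "T", 0.10) is False

    def test_boundary_inclusive(self):
        cplx = Partner("cplx", "complex", ["A", "B"])
        prof = {("T", "A"): 0.10, ("T", "B"): 0.55}
        assert partner_expressed(prof, cplx, "T", 0.10) is True

    @pytest.mark.parametrize("frac,expected", [(0.09, False), (0.10, True),
                                               (0.11, True), (0.0, False)])
    def test_single_gene_fraction_gate(self, frac, expected):
        g = Partner("G", "gene", ["G"])
        assert partner_expressed({("T", "G"): frac}, g, "T", 0.10) is expected

    def test_missing_gene_counts_as_zero_with_warning(self):
        g = Partner("G", "gene", ["G"])
        with pytest.warns(UserWarning, match="absent"):
            assert partner_expressed({}, g, "T", 0.10) is False

    def test_enzyme_proxy_uses_enzyme_gene(self):
        enz = Partner("steroid_via_CYP", "enzyme_proxy", ["CYP"])
        assert partner_expressed({("T", "CYP"): 0.5}, enz, "T", 0.10) is True


class TestRetrieveRelevant:
    def test_de_gate_boundaries(self):
        prof = make_profile({("S", "L"): 0.5, ("S", "R"): 0.5,
                             ("V", "L"): 0.5, ("V", "R"): 0.5})
        db = simple_db()
        # log2fc exactly at the threshold fails ("above 0.2" is strict)
        de = make_de([("L", "S", 0.2, 0.001)])
        assert retrieve_relevant(prof, de, db) == []
        de = make_de([("L", "S", 0.21, 0.001)])
        hits = retrieve_relevant(prof, de, db)
        assert {(h.sender_type, h.receiver_type) for h in hits} == {("S", "S"), ("S", "V")}
        # p_adj exactly at the threshold fails ("below 0.01" is strict)
        de = make_de([("L", "S", 1.0, 0.01)])
        assert retrieve_relevant(prof, de, db) == []
        de = make_de([("L", "S", 1.0, 0.0099)])
        assert len(retrieve_relevant(prof, de, db)) == 2

    def test_expressed_but_not_de_dropped(self):
        prof = make_profile({("S", "L"): 0.9, ("V", "R"): 0.9,
                             ("S", "R"): 0.9, ("V", "L"): 0.9})
        de = make_de([])
        assert retrieve_relevant(prof, de, simple_db()) == []

    def test_de_in_respective_type_only(self):
        prof = make_profile({("S", "L"): 0.5, ("S", "R"): 0.0,
                             ("V", "L"): 0.0, ("V", "R"): 0.5})
        # ligand DE only in the receiver type V: default rule rejects
        de = make_de([("L", "V", 2.0, 0.001)])
        assert retrieve_relevant(prof, de, simple_db()) == []
        relaxed = retrieve_relevant(prof, de, simple_db(), de_in_any_type=True)
        assert [(h.sender_type, h.receiver_type) for h in relaxed] == [("S", "V")]

    def test_min_fraction_monotone_shrinkage(self, default_dataset):
        from celltalk import normalize_log_cpm100, profile_cell_types, qc_filter
        from celltalk.de import de_one_vs_all
        ds = default_dataset
        filtered, _ = qc_filter(ds.counts)
        norm = normalize_log_cpm100(filtered)
        prof = profile_cell_types(norm, filtered)
        de = de_one_vs_all(norm.values.T, filtered.cell_types.to_numpy(),
                           feature_names=norm.gene_ids)
        loose = retrieve_relevant(prof, de, ds.db, CCCThresholds(min_fraction=0.10))
        tight = retrieve_relevant(prof, de, ds.db, CCCThresholds(min_fraction=0.60))
        loose_keys = {(h.interaction_id, h.sender_type, h.receiver_type)
                      for h in loose}
        tight_keys = {(h.interaction_id, h.sender_type, h.receiver_type)
                      for h in tight}
        assert tight_keys <= loose_keys

    def test_output_sorted(self):
        prof = make_profile({("S", "L"): 0.5, ("S", "R"): 0.5,
                             ("V", "L"): 0.5, ("V", "R"): 0.5})
        de = make_de([("L", "S", 1.0, 1e-4), ("L", "V", 1.0, 1e-4)])
        hits = retrieve_relevant(prof, de, simple_db())
        keys = [(h.interaction_id, h.sender_type, h.receiver_type) for h in hits]
        assert keys == sorted(keys)


class TestMicroenvironment:
    def _mk(self, **zones):
        return MicroenvironmentTable(zones_by_type={k: set(v) for k, v in zones.items()})

    def _ri(self, s, r):
        return RelevantInteraction("ix", s, r, "a", ["L"])

    def test_disjoint_zones_excluded(self):
        env = self._mk(S=["medulla"], V=["outer_cortex"])
        assert filter_by_microenvironment([self._ri("S", "V")], env) == []

    def test_shared_zone_kept_and_recorded(self):
        env = self._mk(S=["inner_cortex", "medulla"], V=["medulla"])
        kept = filter_by_microenvironment([self._ri("S", "V")], env)
        assert len(kept) == 1 and kept[0].shared_zones == {"medulla"}

    def test_missing_type_is_fatal(self):
        env = self._mk(S=["medulla"])
        with pytest.raises(ValidationError, match="V"):
            filter_by_microenvironment([self._ri("S", "V")], env)

    def test_zone_mismatch_decoys_removed_on_default_dataset(self, default_dataset):
        ds = default_dataset
        zone_decoys = [i.interaction_id for i in ds.db.interactions
                       if i.annotation == "decoy:zone_mismatch"]
        assert zone_decoys  # the default layout plants some
        # zone-mismatch decoys pair types with disjoint zones by construction;
        # any retrieval of them across such type pairs must die here
        ris = []
        types = sorted(set(ds.counts.cell_meta["cell_type"]))
        for iid in zone_decoys:
            for s in types:
                for r in types:
                    if ds.microenv.zones(s) & ds.microenv.zones(r):
                        continue
                    ris.append(RelevantInteraction(iid, s, r, "a", []))
        assert filter_by_microenvironment(ris, ds.microenv) == []


class TestCellSign:
    def test_active_downstream_tf_flags_support(self):
        table = CellSignTable(rows=[("R", "TFX", "PMID:1")])
        ri = RelevantInteraction("ix", "S", "V", "a", ["L"])
        out = annotate_cellsign([ri], table, {"V": {"TFX"}}, simple_db())
        assert out[0].supported is True
        assert out[0].cellsign_tfs == [{"tf_gene": "TFX", "active_in_receiver": True}]

    def test_inactive_tf_not_supported(self):
        table = CellSignTable(rows=[("R", "TFX", "PMID:1")])
        ri = RelevantInteraction("ix", "S", "V", "a", ["L"])
        out = annotate_cellsign([ri], table, {"V": {"OTHER"}}, simple_db())
        assert out[0].supported is False

    def test_receptor_without_entry(self):
        table = CellSignTable(rows=[])
        ri = RelevantInteraction("ix", "S", "V", "a", ["L"])
        out = annotate_cellsign([ri], table, {"V": {"TFX"}}, simple_db())
        assert out[0].supported is False and out[0].cellsign_tfs == []

    def test_frame_serialization(self):
        ri = RelevantInteraction("ix", "S", "V", "both", ["L", "R"],
                                 shared_zones={"medulla"},
                                 cellsign_tfs=[{"tf_gene": "TFX",
                                                "active_in_receiver": True}],
                                 supported=True)
        df = relevant_to_frame([ri])
        assert df.iloc[0]["cellsign_tfs"] == "TFX:active"
        assert df.iloc[0]["shared_zones"] == "medulla"
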