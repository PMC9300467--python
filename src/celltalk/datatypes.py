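"""Shared domain containers for the cell-cell communication pipeline.

The pipeline moves between a small set of validated in-memory objects:
raw counts with per-cell annotations, a normalized expression matrix, the
curated interaction database (simple genes, heteromeric complexes and
enzyme proxies for non-peptide ligands), the receptor-to-downstream-TF
table, spatial microenvironment assignments, TF regulons, and a peak-level
chromatin accessibility container.  Every container validates its own
invariants on construction so that file readers and the synthetic
generator share one source of truth about what "well-formed" means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_ZONES = ("outer_cortex", "inner_cortex", "medulla")

PARTNER_KINDS = ("gene", "complex", "enzyme_proxy")


class ValidationError(ValueError):
    """Raised when a container violates one of its declared invariants."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Sparse raw counts (cells x genes) plus per-cell metadata.

    ``cell_meta`` is indexed by cell id and carries at least ``cell_type``
    and ``sample`` columns; ``zone`` is optional and may be missing (NaN)
    for individual cells, since spatial zones are assigned per cell type.
    """

    counts: sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.cell_ids, "cell id")
        _check_unique(self.gene_ids, "gene id")
        data = self.counts.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise ValidationError("counts contain non-finite values")
            if np.any(data < 0):
                raise ValidationError("counts contain negative values")
            if np.any(data != np.round(data)):
                raise ValidationError("counts contain non-integer values")
        if "cell_type" not in self.cell_meta.columns:
            raise ValidationError("cell_meta lacks a 'cell_type' column")
        missing = set(self.cell_ids) - set(self.cell_meta.index.astype(str))
        if missing:
            raise ValidationError(
                f"cell_meta does not cover every cell; first missing: {sorted(missing)[0]!r}"
            )
        # align metadata row order with the matrix
        self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> pd.Series:
        return self.cell_meta["cell_type"]

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given boolean masks."""
        cm = np.asarray(cell_mask if cell_mask is not None else np.ones(self.n_cells, bool))
        gm = np.asarray(gene_mask if gene_mask is not None else np.ones(self.n_genes, bool))
        return CountMatrix(
            counts=self.counts[cm][:, gm],
            cell_ids=[c for c, k in zip(self.cell_ids, cm) if k],
            gene_ids=[g for g, k in zip(self.gene_ids, gm) if k],
            cell_meta=self.cell_meta.loc[cm],
        )


@dataclass
class NormalizedMatrix:
    """Natural-log normalized expression (cells x genes) with provenance."""

    values: sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.data.size and np.any(self.values.data < 0):
            raise ValidationError("normalized values must be non-negative")

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class Partner:
    partner_id: str
    kind: str  # gene | complex | enzyme_proxy
    member_genes: list[str]

    def __post_init__(self) -> None:
        if self.kind not in PARTNER_KINDS:
            raise ValidationError(
                f"partner {self.partner_id!r}: unknown kind {self.kind!r}"
            )
        if not self.member_genes:
            raise ValidationError(f"partner {self.partner_id!r}: empty member list")
        if any(not g for g in self.member_genes):
            raise ValidationError(f"partner {self.partner_id!r}: empty member gene name")


@dataclass
class Interaction:
    interaction_id: str
    partner_a: str
    partner_b: str
    directionality: str = "ligand_receptor"  # or "undirected"
    annotation: str = ""


@dataclass
class InteractionDB:
    """Curated partner and ligand-receptor interaction tables.

    Partners may be single genes, heteromeric complexes (several member
    genes, all of which must pass expression gates) or enzyme proxies:
    a non-peptide ligand such as a steroid represented by the last bona
    fide enzyme of its biosynthesis pathway.
    """

    partners: dict[str, Partner]
    interactions: list[Interaction]

    def __post_init__(self) -> None:
        _check_unique([i.interaction_id for i in self.interactions], "interaction id")
        for inter in self.interactions:
            for side in (inter.partner_a, inter.partner_b):
                if side not in self.partners:
                    raise ValidationError(
                        f"interaction {inter.interaction_id!r} references "
                        f"unknown partner {side!r}"
                    )

    def members(self, partner_id: str) -> list[str]:
        return self.partners[partner_id].member_genes


@dataclass
class CellSignTable:
    """Receptor -> high-specificity downstream transcription factor links."""

    rows: list[tuple[str, str, str]]  # (receptor_partner_id, tf_gene, evidence_ref)

    def __post_init__(self) -> None:
        _check_unique([(r, t) for r, t, _ in self.rows], "(receptor, TF) pair")

    def tfs_for(self, receptor_partner_id: str) -> list[str]:
        return [t for r, t, _ in self.rows if r == receptor_partner_id]

    def validate_against(self, db: InteractionDB) -> None:
        for r, _, _ in self.rows:
            if r not in db.partners:
                raise ValidationError(f"CellSign receptor {r!r} not in interaction DB")


@dataclass
class MicroenvironmentTable:
    """Cell type -> spatial zone assignments (a type may span several zones)."""

    zones_by_type: dict[str, set[str]]
    vocabulary: tuple[str, ...] = DEFAULT_ZONES

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        for ct, zones in self.zones_by_type.items():
            bad = set(zones) - vocab
            if bad:
                raise ValidationError(
                    f"cell type {ct!r} assigned to unknown zone(s) {sorted(bad)}"
                )

    def zones(self, cell_type: str) -> set[str]:
        if cell_type not in self.zones_by_type:
            raise ValidationError(
                f"cell type {cell_type!r} missing from microenvironment table"
            )
        return self.zones_by_type[cell_type]


@dataclass
class RegulonTarget:
    target_gene: str
    mode: int  # +1 activation, -1 repression
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in (1, -1):
            raise ValidationError(f"regulon mode must be +1/-1, got {self.mode}")
        if not (0.0 < self.weight <= 1.0):
            raise ValidationError(f"regulon weight must be in (0,1], got {self.weight}")


@dataclass
class RegulonSet:
    """TF -> target gene sets with modes of regulation."""

    regulons: dict[str, list[RegulonTarget]]
    min_targets: int = 5

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            names = [t.target_gene for t in targets]
            _check_unique([(tf, n) for n in names], "(TF, target) pair")
            if tf in names:
                raise ValidationError(f"regulon {tf!r} contains a self-target")
            if len(targets) < self.min_targets:
                raise ValidationError(
                    f"regulon {tf!r} has {len(targets)} targets "
                    f"(< floor {self.min_targets})"
                )

    @property
    def tf_names(self) -> list[str]:
        return list(self.regulons)


@dataclass
class PeakAccessibility:
    """Peaks x cells accessibility with motif annotation and GC content.

    Coordinates are 0-based half-open; a peak's width is ``end - start``.
    ``motif_annot`` is a binary peaks x motifs matrix and ``motif_tf``
    maps each motif name to the gene symbol of the TF it represents.
    """

    peaks: pd.DataFrame  # columns: peak_id, chrom, start, end
    access: sp.spmatrix  # peaks x cells
    cell_ids: list[str]
    motif_names: list[str]
    motif_annot: sp.spmatrix  # peaks x motifs, binary
    motif_tf: dict[str, str]
    gc_content: np.ndarray

    def __post_init__(self) -> None:
        self.access = sp.csr_matrix(self.access)
        self.motif_annot = sp.csr_matrix(self.motif_annot)
        self.gc_content = np.asarray(self.gc_content, dtype=float)
        _check_unique(self.peaks["peak_id"].tolist(), "peak id")
        if np.any(self.peaks["end"].to_numpy() <= self.peaks["start"].to_numpy()):
            bad = self.peaks[self.peaks["end"] <= self.peaks["start"]].iloc[0]
            raise ValidationError(
                f"peak {bad['peak_id']!r} has end <= start ({bad['end']} <= {bad['start']})"
            )
        n_peaks = len(self.peaks)
        if self.access.shape[0] != n_peaks:
            raise ValidationError("access matrix rows do not match peaks")
        if self.access.shape[1] != len(self.cell_ids):
            raise ValidationError("access matrix columns do not match cell ids")
        if self.motif_annot.shape != (n_peaks, len(self.motif_names)):
            raise ValidationError("motif annotation dimensions do not match peaks/motifs")
        if self.gc_content.shape[0] != n_peaks:
            raise ValidationError("gc_content length does not match peaks")
        if np.any((self.gc_content < 0) | (self.gc_content > 1)):
            raise ValidationError("gc_content outside [0,1]")

    @property
    def widths(self) -> np.ndarray:
        return (self.peaks["end"] - self.peaks["start"]).to_numpy()

    def subset_peaks(self, mask) -> "PeakAccessibility":
        mask = np.asarray(mask, dtype=bool)
        return PeakAccessibility(
            peaks=self.peaks.loc[mask].reset_index(drop=True),
            access=self.access[mask],
            cell_ids=self.cell_ids,
            motif_names=self.motif_names,
            motif_annot=self.motif_annot[mask],
            motif_tf=self.motif_tf,
            gc_content=self.gc_content[mask],
        )
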