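"""Readers and writers for the plain-text formats the pipeline touches.

Count and accessibility matrices travel as Matrix Market (MTX) with
companion TSVs (10x convention: genes as rows on disk, transposed to
cells x genes in memory).  Database tables, metadata and all outputs are
tab-separated text; peaks and blacklists are BED (0-based half-open).
All writers emit deterministically sorted output so identical inputs
give byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    CellSignTable,
    CountMatrix,
    InteractionDB,
    Interaction,
    MicroenvironmentTable,
    Partner,
    PeakAccessibility,
    RegulonSet,
    RegulonTarget,
    ValidationError,
    DEFAULT_ZONES,
)

MEMBER_SEP = ","


def _find(directory: Path, names: list[str]) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"none of {names} found in {directory}"
    )


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, **kw)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_counts_mtx(directory_path) -> CountMatrix:
    """Read a 10x-style MTX directory plus cell metadata into a CountMatrix.

    Expects ``matrix.mtx[.gz]``, ``features.tsv[.gz]`` (or ``genes.tsv``),
    ``barcodes.tsv[.gz]`` and ``cell_meta.tsv`` with columns
    barcode / cell_type / sample [/ zone].  The on-disk matrix is genes x
    cells (10x convention) and is transposed on read; a cells x genes
    matrix (detected via the barcode count) is accepted as-is.
    """
    d = Path(directory_path)
    mtx_path = _find(d, ["matrix.mtx", "matrix.mtx.gz"])
    feat_path = _find(d, ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"])
    bc_path = _find(d, ["barcodes.tsv", "barcodes.tsv.gz"])
    meta_path = _find(d, ["cell_meta.tsv", "cell_meta.tsv.gz"])

    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))

    def _read_lines(p: Path) -> list[str]:
        opener = gzip.open if p.suffix == ".gz" else open
        with opener(p, "rt") as fh:
            return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]

    genes = _read_lines(feat_path)
    barcodes = _read_lines(bc_path)

    if mat.shape == (len(genes), len(barcodes)):
        mat = mat.T.tocsr()  # genes-as-rows on disk -> cells x genes
        orientation = "genes_x_cells"
    elif mat.shape == (len(barcodes), len(genes)):
        orientation = "cells_x_genes"
    else:
        raise ValidationError(
            f"{mtx_path}: shape {mat.shape} matches neither "
            f"({len(genes)} genes, {len(barcodes)} barcodes) orientation"
        )

    meta = _read_tsv(meta_path)
    _require_columns(meta, ["barcode", "cell_type", "sample"], meta_path)
    if "zone" not in meta.columns:
        meta["zone"] = pd.NA
    meta = meta.set_index("barcode")
    mismatch = [b for b in barcodes if b not in meta.index]
    if mismatch:
        raise ValidationError(
            f"{meta_path}: metadata missing barcode {mismatch[0]!r} "
            f"({len(mismatch)} barcodes unmatched)"
        )

    cm = CountMatrix(counts=mat, cell_ids=barcodes, gene_ids=genes, cell_meta=meta)
    cm.cell_meta.attrs["mtx_orientation"] = orientation
    return cm


def write_counts_mtx(cm: CountMatrix, directory_path) -> None:
    """Write a CountMatrix as a 10x-style MTX directory (genes as rows)."""
    d = Path(directory_path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(cm.counts.T.astype(int)))
    (d / "features.tsv").write_text("".join(g + "\n" for g in cm.gene_ids))
    (d / "barcodes.tsv").write_text("".join(c + "\n" for c in cm.cell_ids))
    meta = cm.cell_meta.copy()
    meta.insert(0, "barcode", cm.cell_ids)
    meta.to_csv(d / "cell_meta.tsv", sep="\t", index=False)


def read_interaction_db(partners_path, interactions_path) -> InteractionDB:
    """Parse partner and interaction TSVs into a validated InteractionDB."""
    pdf = _read_tsv(Path(partners_path))
    _require_columns(pdf, ["partner_id", "kind", "member_genes"], partners_path)
    partners = {}
    for _, row in pdf.iterrows():
        raw = row["member_genes"]
        members = ([] if pd.isna(raw)
                   else [m for m in str(raw).split(MEMBER_SEP) if m])
        partners[row["partner_id"]] = Partner(
            partner_id=row["partner_id"], kind=row["kind"], member_genes=members
        )
    idf = _read_tsv(Path(interactions_path))
    _require_columns(idf, ["interaction_id", "partner_a", "partner_b"], interactions_path)
    if "directionality" not in idf.columns:
        idf["directionality"] = "ligand_receptor"
    if "annotation" not in idf.columns:
        idf["annotation"] = ""
    interactions = [
        Interaction(
            interaction_id=row["interaction_id"],
            partner_a=row["partner_a"],
            partner_b=row["partner_b"],
            directionality=row["directionality"],
            annotation=row["annotation"] if pd.notna(row["annotation"]) else "",
        )
        for _, row in idf.iterrows()
    ]
    return InteractionDB(partners=partners, interactions=interactions)


def write_interaction_db(db: InteractionDB, partners_path, interactions_path) -> None:
    prows = [
        {"partner_id": p.partner_id, "kind": p.kind,
         "member_genes": MEMBER_SEP.join(p.member_genes)}
        for p in db.partners.values()
    ]
    pd.DataFrame(sorted(prows, key=lambda r: r["partner_id"])).to_csv(
        partners_path, sep="\t", index=False
    )
    irows = [
        {"interaction_id": i.interaction_id, "partner_a": i.partner_a,
         "partner_b": i.partner_b, "directionality": i.directionality,
         "annotation": i.annotation}
        for i in db.interactions
    ]
    pd.DataFrame(sorted(irows, key=lambda r: r["interaction_id"])).to_csv(
        interactions_path, sep="\t", index=False
    )


def read_cellsign(path, db: InteractionDB | None = None) -> CellSignTable:
    df = _read_tsv(Path(path))
    _require_columns(df, ["receptor_partner_id", "tf_gene"], path)
    if "evidence_ref" not in df.columns:
        df["evidence_ref"] = ""
    table = CellSignTable(
        rows=[
            (r["receptor_partner_id"], r["tf_gene"],
             r["evidence_ref"] if pd.notna(r["evidence_ref"]) else "")
            for _, r in df.iterrows()
        ]
    )
    if db is not None:
        table.validate_against(db)
    return table


def write_cellsign(table: CellSignTable, path) -> None:
    pd.DataFrame(
        sorted(table.rows),
        columns=["receptor_partner_id", "tf_gene", "evidence_ref"],
    ).to_csv(path, sep="\t", index=False)


def read_microenvironments(path, vocabulary=DEFAULT_ZONES) -> MicroenvironmentTable:
    df = _read_tsv(Path(path))
    _require_columns(df, ["cell_type", "zone"], path)
    zones_by_type: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        zones_by_type.setdefault(row["cell_type"], set()).add(row["zone"])
    return MicroenvironmentTable(zones_by_type=zones_by_type, vocabulary=tuple(vocabulary))


def write_microenvironments(env: MicroenvironmentTable, path) -> None:
    rows = sorted(
        (ct, z) for ct, zones in env.zones_by_type.items() for z in zones
    )
    pd.DataFrame(rows, columns=["cell_type", "zone"]).to_csv(path, sep="\t", index=False)


def read_regulons(path, min_targets: int = 5) -> RegulonSet:
    df = _read_tsv(Path(path))
    _require_columns(df, ["tf", "target"], path)
    if "mode" not in df.columns:
        df["mode"] = "1"
    if "weight" not in df.columns:
        df["weight"] = "1.0"
    regulons: dict[str, list[RegulonTarget]] = {}
    for _, row in df.iterrows():
        regulons.setdefault(row["tf"], []).append(
            RegulonTarget(
                target_gene=row["target"],
                mode=int(row["mode"]),
                weight=float(row["weight"]),
            )
        )
    return RegulonSet(regulons=regulons, min_targets=min_targets)


def write_regulons(regs: RegulonSet, path) -> None:
    rows = [
        {"tf": tf, "target": t.target_gene, "mode": t.mode, "weight": t.weight}
        for tf in sorted(regs.regulons)
        for t in sorted(regs.regulons[tf], key=lambda x: x.target_gene)
    ]
    pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end [name]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: malformed interval (end {end} <= start {start})"
                )
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            rows.append({"chrom": chrom, "start": start, "end": end, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df.sort_values(["chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False, header=False, columns=cols
    )


def read_peaks(bed_path, mtx_path, motif_path, barcodes_path=None,
               gc_path=None) -> PeakAccessibility:
    """Assemble a PeakAccessibility from BED + MTX + motif annotation TSV.

    The MTX is peaks x cells (rows in BED order).  The motif TSV has
    columns peak_id / motif / tf, one row per (peak, motif) annotation;
    GC content comes from an optional two-column TSV (peak_id, gc),
    defaulting to 0.5 when absent.
    """
    bed = read_bed(bed_path)
    bed = bed.rename(columns={"name": "peak_id"})
    access = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    if access.shape[0] != len(bed):
        raise ValidationError(
            f"{mtx_path}: {access.shape[0]} rows but {len(bed)} peaks in {bed_path}"
        )
    if barcodes_path is not None:
        with open(barcodes_path) as fh:
            cell_ids = [line.strip() for line in fh if line.strip()]
    else:
        cell_ids = [f"cell_{i}" for i in range(access.shape[1])]

    mdf = _read_tsv(Path(motif_path))
    _require_columns(mdf, ["peak_id", "motif", "tf"], motif_path)
    motif_names = sorted(mdf["motif"].unique())
    motif_idx = {m: j for j, m in enumerate(motif_names)}
    peak_idx = {p: i for i, p in enumerate(bed["peak_id"])}
    annot = sp.lil_matrix((len(bed), len(motif_names)), dtype=np.int8)
    motif_tf = {}
    for _, row in mdf.iterrows():
        if row["peak_id"] not in peak_idx:
            raise ValidationError(f"{motif_path}: unknown peak id {row['peak_id']!r}")
        annot[peak_idx[row["peak_id"]], motif_idx[row["motif"]]] = 1
        motif_tf[row["motif"]] = row["tf"]

    if gc_path is not None:
        gdf = _read_tsv(Path(gc_path))
        _require_columns(gdf, ["peak_id", "gc"], gc_path)
        gc_map = dict(zip(gdf["peak_id"], gdf["gc"].astype(float)))
        gc = np.array([gc_map.get(p, 0.5) for p in bed["peak_id"]])
    else:
        gc = np.full(len(bed), 0.5)

    return PeakAccessibility(
        peaks=bed[["peak_id", "chrom", "start", "end"]],
        access=access,
        cell_ids=cell_ids,
        motif_names=motif_names,
        motif_annot=annot.tocsr(),
        motif_tf=motif_tf,
        gc_content=gc,
    )


def write_peaks(pa: PeakAccessibility, out_dir) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    bed = pa.peaks.rename(columns={"peak_id": "name"})[["chrom", "start", "end", "name"]]
    bed.to_csv(d / "peaks.bed", sep="\t", index=False, header=False)
    scipy.io.mmwrite(str(d / "accessibility.mtx"), sp.coo_matrix(pa.access.astype(int)))
    (d / "atac_barcodes.tsv").write_text("".join(c + "\n" for c in pa.cell_ids))
    annot = pa.motif_annot.tocoo()
    rows = [
        {"peak_id": pa.peaks["peak_id"].iloc[i], "motif": pa.motif_names[j],
         "tf": pa.motif_tf[pa.motif_names[j]]}
        for i, j in zip(annot.row, annot.col)
    ]
    pd.DataFrame(sorted(rows, key=lambda r: (r["peak_id"], r["motif"])),
                 columns=["peak_id", "motif", "tf"]).to_csv(
        d / "peak_motifs.tsv", sep="\t", index=False
    )
    pd.DataFrame({"peak_id": pa.peaks["peak_id"], "gc": pa.gc_content}).to_csv(
        d / "peak_gc.tsv", sep="\t", index=False
    )


def write_table(records, path, sort_by=None) -> None:
    """Write records (DataFrame or list of dicts) as deterministic TSV.

    Rows are sorted by ``sort_by`` (default: all columns, left to right)
    so repeated runs produce byte-identical files.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if len(df):
        by = sort_by if sort_by is not None else list(df.columns)
        df = df.sort_values(by=by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
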