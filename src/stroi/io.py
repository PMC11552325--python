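"""Readers and writers for the spatial bundle, gene sets and result tables.

Supports the Space Ranger on-disk layout: an MTX triple
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) or a 10x HDF5
feature-barcode matrix, a ``tissue_positions`` CSV in either dialect
(headerless pre-2.0 or headered 2.0+), a ``scalefactors_json.json`` record
and an RGB tissue image.  Also GMT gene-set libraries, spot-by-cell-type
fraction CSVs, an NPZ mask archive, and CSV/JSON result output.
"""

from __future__ import annotations

import json
import os
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd
from PIL import Image
from scipy.io import mmread

from .model import (
    CellTypeProportions,
    DEGTable,
    GeneSetLibrary,
    MaskSet,
    ORATable,
    ScaleFactors,
    SegmentMask,
    SegmentationMode,
    SpatialDataset,
)

PathLike = Union[str, os.PathLike]

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _make_unique(names: Sequence[str]) -> List[str]:
    """Deduplicate symbols by appending a numeric suffix (G, G_2, G_3...)."""
    seen: Dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}_{seen[name]}")
        else:
            seen[name] = 1
            out.append(name)
    return out


def read_image(path: PathLike) -> np.ndarray:
    """Read PNG/TIFF/JPEG as an (H, W, 3) uint8 RGB array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - surface as a domain error
        raise ValueError(f"unreadable image {path}: {exc}") from exc


def read_positions(path: PathLike) -> pd.DataFrame:
    """Read a tissue_positions CSV, auto-detecting the header dialect."""
    with open(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != len(POSITION_COLUMNS):
        raise ValueError(
            f"positions file {path} has {df.shape[1]} columns, "
            f"expected {len(POSITION_COLUMNS)}"
        )
    df.columns = POSITION_COLUMNS
    return df


def _read_matrix_mtx(matrix_path: Path) -> Tuple[np.ndarray, List[str], List[str]]:
    """Read MTX + sibling features/barcodes TSVs; returns (spots x genes)."""
    mdir = matrix_path.parent

    def _sibling(stem: str) -> Path:
        for name in (f"{stem}.tsv", f"{stem}.tsv.gz", "genes.tsv" if stem == "features" else None):
            if name and (mdir / name).exists():
                return mdir / name
        raise FileNotFoundError(f"no {stem}.tsv next to {matrix_path}")

    mat = mmread(matrix_path)  # genes x barcodes per 10x convention
    features = pd.read_csv(_sibling("features"), sep="\t", header=None)
    barcodes = pd.read_csv(_sibling("barcodes"), sep="\t", header=None)
    symbols = features.iloc[:, 1 if features.shape[1] > 1 else 0].astype(str).tolist()
    counts = np.asarray(mat.todense()).T  # -> spots x genes
    return counts, symbols, barcodes.iloc[:, 0].astype(str).tolist()


def _read_matrix_h5(path: Path) -> Tuple[np.ndarray, List[str], List[str]]:
    """Read a 10x HDF5 feature-barcode matrix (CSC: genes x barcodes)."""
    from scipy.sparse import csc_matrix

    with h5py.File(path, "r") as f:
        group = f["matrix"] if "matrix" in f else f[list(f.keys())[0]]
        data = group["data"][:]
        indices = group["indices"][:]
        indptr = group["indptr"][:]
        shape = tuple(group["shape"][:])
        mat = csc_matrix((data, indices, indptr), shape=shape)
        if "features" in group:
            symbols = [s.decode() for s in group["features"]["name"][:]]
        else:  # legacy layout
            symbols = [s.decode() for s in group["gene_names"][:]]
        barcodes = [b.decode() for b in group["barcodes"][:]]
    return np.asarray(mat.todense()).T, symbols, barcodes


def read_scalefactors(path: PathLike) -> ScaleFactors:
    with open(path) as fh:
        d = json.load(fh)
    return ScaleFactors(
        hires_scalef=float(d["tissue_hires_scalef"]),
        spot_diameter_fullres=float(d["spot_diameter_fullres"]),
    )


def read_visium_bundle(
    matrix_path: PathLike,
    positions_path: PathLike,
    scalefactors_path: PathLike,
    image_path: PathLike,
) -> SpatialDataset:
    """Assemble a :class:`SpatialDataset` from a Space Ranger-style layout.

    Barcodes in the positions table are aligned 1:1 with matrix rows; a
    positions barcode absent from the matrix (or vice versa among
    positions-listed barcodes) is a hard error.  Duplicate gene symbols are
    made unique with a numeric suffix.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix in {".h5", ".hdf5"}:
        counts, symbols, mat_barcodes = _read_matrix_h5(matrix_path)
    else:
        counts, symbols, mat_barcodes = _read_matrix_mtx(matrix_path)

    positions = read_positions(positions_path)
    pos_barcodes = positions["barcode"].astype(str).tolist()
    mat_index = {b: i for i, b in enumerate(mat_barcodes)}
    missing = [b for b in pos_barcodes if b not in mat_index]
    if missing:
        raise ValueError(
            f"{len(missing)} positions barcode(s) absent from matrix "
            f"({len(mat_barcodes)} matrix barcodes, {len(pos_barcodes)} "
            f"positions rows); first missing: {missing[0]}"
        )
    order = [mat_index[b] for b in pos_barcodes]
    counts = counts[order]

    spot_table = pd.DataFrame(
        {
            "barcode": pos_barcodes,
            "in_tissue": positions["in_tissue"].astype(int).astype(bool),
            "fullres_x": positions["pxl_col_in_fullres"].astype(float),
            "fullres_y": positions["pxl_row_in_fullres"].astype(float),
        }
    )
    return SpatialDataset(
        counts=np.asarray(np.rint(counts), dtype=np.int64),
        gene_ids=_make_unique([str(s) for s in symbols]),
        spot_table=spot_table,
        scale=read_scalefactors(scalefactors_path),
        image=read_image(image_path),
    )


def read_gmt(path: PathLike, name: Optional[str] = None) -> GeneSetLibrary:
    """Read a GMT gene-set library.

    Lines with fewer than three fields are skipped with a warning; empty
    gene lists are dropped; duplicate term names get a ``_2``/``_3`` suffix.
    """
    terms: Dict[str, set] = {}
    name_counts: Dict[str, int] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(
                    f"{path}:{lineno}: fewer than 3 fields, skipping", stacklevel=2
                )
                continue
            term, _desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                warnings.warn(
                    f"{path}:{lineno}: term {term!r} has no genes, dropping",
                    stacklevel=2,
                )
                continue
            if term in name_counts:
                name_counts[term] += 1
                term = f"{term}_{name_counts[term]}"
            else:
                name_counts[term] = 1
            terms[term] = set(genes)
    if n_lines == 0:
        raise ValueError(f"empty GMT file: {path}")
    return GeneSetLibrary(name=name or Path(path).stem, terms=terms)


def read_fractions(path: PathLike) -> pd.DataFrame:
    """Read a spot x cell-type fraction CSV (index = barcode)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


# Mask archive --------------------------------------------------------------

def save_maskset(maskset: MaskSet, path: PathLike) -> None:
    """Save masks to a compressed NPZ archive."""
    rasters = (
        np.stack([m.raster for m in maskset.masks])
        if len(maskset)
        else np.zeros((0, *maskset.image_shape), dtype=bool)
    )
    np.savez_compressed(
        path,
        rasters=rasters,
        scores=np.array([m.score for m in maskset.masks], dtype=float),
        mode=np.array(maskset.mode.value),
        image_shape=np.array(maskset.image_shape, dtype=int),
        threshold_used=np.array(maskset.threshold_used, dtype=float),
    )


def load_maskset(path: PathLike) -> MaskSet:
    with np.load(path, allow_pickle=False) as z:
        rasters = z["rasters"]
        scores = z["scores"]
        mode = str(z["mode"])
        image_shape = tuple(int(v) for v in z["image_shape"])
        threshold = float(z["threshold_used"])
    masks = [
        SegmentMask(mask_id=i + 1, raster=rasters[i], score=float(scores[i]))
        for i in range(rasters.shape[0])
    ]
    return MaskSet(
        masks=masks,
        mode=SegmentationMode(mode),
        image_shape=image_shape,
        threshold_used=threshold,
    )


# Result output -------------------------------------------------------------

def write_results(
    degs: Optional[DEGTable],
    ora_tables: Sequence[ORATable],
    props: Optional[CellTypeProportions],
    outdir: PathLike,
    manifest: Optional[dict] = None,
) -> Dict[str, Path]:
    """Write CSV result tables plus a JSON run manifest.

    Returns a name -> path map of everything written.  Column order is
    stable so runs diff cleanly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    if degs is not None:
        p = outdir / "degs.csv"
        degs.table.to_csv(p, index=False)
        written["degs"] = p
    for ora in ora_tables:
        label = ora.library_name or "library"
        p = outdir / f"ora_{label}.csv"
        ora.table.to_csv(p, index=False)
        written[f"ora_{label}"] = p
    if props is not None:
        p = outdir / "proportions.csv"
        props.roi_means.to_csv(p)
        written["proportions"] = p

    manifest = dict(manifest or {})
    from . import __version__

    manifest.setdefault("software", {"name": "stroi", "version": __version__})
    p = outdir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    written["manifest"] = p
    return written


def read_deg_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


# Optional h5ad container ---------------------------------------------------

def to_anndata(ds: SpatialDataset):
    """Export to an AnnData with image and scale factors under ``uns``."""
    import anndata as ad

    obs = ds.spot_table.set_index("barcode", drop=False)
    obs.index.name = None
    adata = ad.AnnData(X=ds.counts.astype(np.float64), obs=obs)
    adata.var_names = ds.gene_ids
    adata.uns["scale"] = {
        "hires_scalef": ds.scale.hires_scalef,
        "spot_diameter_fullres": ds.scale.spot_diameter_fullres,
    }
    adata.uns["image"] = ds.image
    if ds.normalized is not None:
        adata.layers["lognorm"] = ds.normalized
    return adata


def from_anndata(adata) -> SpatialDataset:
    X = adata.X
    counts = np.asarray(X.todense() if hasattr(X, "todense") else X)
    return SpatialDataset(
        counts=np.asarray(np.rint(counts), dtype=np.int64),
        gene_ids=list(adata.var_names),
        spot_table=adata.obs.reset_index(drop=True)[
            ["barcode", "in_tissue", "fullres_x", "fullres_y"]
        ],
        scale=ScaleFactors(**{k: float(v) for k, v in adata.uns["scale"].items()}),
        image=np.asarray(adata.uns["image"], dtype=np.uint8),
        normalized=np.asarray(adata.layers["lognorm"])
        if "lognorm" in adata.layers
        else None,
    )


def save_h5ad(ds: SpatialDataset, path: PathLike) -> None:
    to_anndata(ds).write_h5ad(Path(path))


def load_h5ad(path: PathLike) -> SpatialDataset:
    import anndata as ad

    return from_anndata(ad.read_h5ad(Path(path)))
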