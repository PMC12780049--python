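"""Read and write Visium bundles in the Space Ranger output layout.

A Visium "bundle" is the de facto interchange format for 10x Genomics
spatial transcriptomics: an HDF5 feature-barcode matrix
(``filtered_feature_bc_matrix.h5``) next to a ``spatial/`` folder holding
the per-spot tissue positions table, the scale-factors JSON and the H&E
tissue images.  This module reads such bundles into :class:`VisiumDataset`,
applies the standard gene/spot quality filters, and writes aligned MSI
"count" data back out in the same layout so any downstream Visium tool can
load both modalities in a shared coordinate frame.

Conventions
-----------
* On disk the matrix is features x barcodes in compressed-sparse-column
  layout (each column one barcode), the 10x convention.  In memory
  ``VisiumDataset.counts`` keeps the same features x barcodes orientation.
* Spot centres live in full-resolution image pixels; ``hires``/``lowres``
  rasters relate to that frame through the scale factors.
* Both tissue-positions dialects are accepted: the Space Ranger v1
  headerless ``tissue_positions_list.csv`` and the v2 headered
  ``tissue_positions.csv``.  The writer emits the headered v2 form.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import FilterError, FormatError

logger = logging.getLogger(__name__)

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]

REQUIRED_SCALEFACTORS = (
    "spot_diameter_fullres",
    "tissue_hires_scalef",
    "tissue_lowres_scalef",
)


@dataclass
class VisiumDataset:
    """In-memory Visium sample: counts, spot geometry, images, scale factors.

    Attributes
    ----------
    barcodes
        Spot identifiers, in matrix column order.
    features
        DataFrame with columns ``id``, ``name``, ``feature_type``.
    counts
        Sparse features x barcodes matrix of non-negative values.
    positions
        One row per barcode (same order as ``barcodes``) with columns
        ``in_tissue``, ``array_row``, ``array_col``,
        ``pxl_row_in_fullres``, ``pxl_col_in_fullres``; indexed by barcode.
    scalefactors
        At least ``spot_diameter_fullres``, ``tissue_hires_scalef``,
        ``tissue_lowres_scalef``.
    images
        Optional rasters keyed ``hires`` / ``lowres`` (row-major, origin
        top-left, uint8).
    """

    barcodes: list[str]
    features: pd.DataFrame
    counts: sparse.spmatrix
    positions: pd.DataFrame
    scalefactors: dict
    images: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    def spot_centres_fullres(self) -> np.ndarray:
        """Spot centres as (x, y) = (pxl_col, pxl_row) in fullres pixels."""
        return self.positions[
            ["pxl_col_in_fullres", "pxl_row_in_fullres"]
        ].to_numpy(dtype=float)

    def validate(self) -> "VisiumDataset":
        if self.counts.shape != (len(self.features), len(self.barcodes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.barcodes)} barcodes"
            )
        if not set(self.barcodes) <= set(self.positions.index):
            missing = set(self.barcodes) - set(self.positions.index)
            raise FormatError(f"{len(missing)} barcodes lack position records")
        if self.counts.nnz and self.counts.min() < 0:
            raise FormatError("counts matrix contains negative entries")
        sf = self.scalefactors
        for key in REQUIRED_SCALEFACTORS:
            if key not in sf:
                raise FormatError(f"scalefactors missing key {key!r}")
        if not (0 < sf["tissue_hires_scalef"] <= 1):
            raise FormatError("tissue_hires_scalef must lie in (0, 1]")
        if sf["spot_diameter_fullres"] <= 0:
            raise FormatError("spot_diameter_fullres must be positive")
        if (self.positions[["array_row", "array_col"]].to_numpy() < 0).any():
            raise FormatError("array_row/array_col must be non-negative")
        return self


def _read_10x_h5(path: Path) -> tuple[list[str], pd.DataFrame, sparse.csc_matrix]:
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError(f"{path.name}: no 'matrix' group (not a 10x HDF5 file)")
        g = f["matrix"]
        shape = tuple(int(v) for v in g["shape"][:])
        mat = sparse.csc_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]), shape=shape
        )
        barcodes = [b.decode() for b in g["barcodes"][:]]
        feats = g["features"]
        features = pd.DataFrame(
            {
                "id": [v.decode() for v in feats["id"][:]],
                "name": [v.decode() for v in feats["name"][:]],
                "feature_type": [v.decode() for v in feats["feature_type"][:]],
            }
        )
    return barcodes, features, mat


def _read_positions(spatial_dir: Path) -> pd.DataFrame:
    """Read tissue positions in either the v1 (headerless) or v2 dialect."""
    v2 = spatial_dir / "tissue_positions.csv"
    v1 = spatial_dir / "tissue_positions_list.csv"
    if v2.exists():
        df = pd.read_csv(v2, float_precision="round_trip")
        missing = set(POSITION_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(
                f"{v2.name} lacks required columns: {sorted(missing)}"
            )
        df = df[POSITION_COLUMNS]
    elif v1.exists():
        df = pd.read_csv(
            v1, header=None, names=POSITION_COLUMNS, float_precision="round_trip"
        )
    else:
        raise FormatError(
            f"missing tissue positions table in {spatial_dir} "
            "(tissue_positions.csv or tissue_positions_list.csv)"
        )
    return df.set_index("barcode", drop=False)


def read_spaceranger(path: str | Path) -> VisiumDataset:
    """Load a Space Ranger-style bundle from ``path``.

    The directory must contain the HDF5 feature-barcode matrix, a tissue
    positions table and ``scalefactors_json.json`` (the latter two either
    directly or under a ``spatial/`` subfolder); PNG images are optional.

    Positions are joined to matrix barcodes; position records without a
    matrix column are dropped (count logged).  A barcode overlap below 50%
    between matrix and positions is treated as a wrong-bundle signal and is
    fatal.
    """
    path = Path(path)
    h5_candidates = sorted(path.glob("*filtered_feature_bc_matrix.h5")) or sorted(
        path.glob("*.h5")
    )
    if not h5_candidates:
        raise FormatError(
            f"missing HDF5 matrix in {path} (expected filtered_feature_bc_matrix.h5)"
        )
    spatial_dir = path / "spatial" if (path / "spatial").is_dir() else path
    sf_path = spatial_dir / "scalefactors_json.json"
    if not sf_path.exists():
        raise FormatError(f"missing scalefactors_json.json in {spatial_dir}")

    barcodes, features, mat = _read_10x_h5(h5_candidates[0])
    positions = _read_positions(spatial_dir)
    try:
        scalefactors = json.loads(sf_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed JSON in {sf_path.name}: {e}") from e

    overlap = len(set(barcodes) & set(positions.index))
    if barcodes and overlap < 0.5 * len(barcodes):
        raise FormatError(
            f"only {overlap}/{len(barcodes)} matrix barcodes found in the "
            "positions table; this looks like a mismatched bundle"
        )
    missing = set(barcodes) - set(positions.index)
    if missing:
        raise FormatError(
            f"{len(missing)} matrix barcodes lack position records"
        )
    dropped = len(positions) - overlap
    if dropped:
        logger.info("dropped %d position records absent from the matrix", dropped)
    positions = positions.loc[barcodes]

    images: dict[str, np.ndarray] = {}
    from PIL import Image

    for key, fname in (
        ("hires", "tissue_hires_image.png"),
        ("lowres", "tissue_lowres_image.png"),
    ):
        img_path = spatial_dir / fname
        if img_path.exists():
            images[key] = np.asarray(Image.open(img_path))

    ds = VisiumDataset(
        barcodes=barcodes,
        features=features,
        counts=mat,
        positions=positions,
        scalefactors=scalefactors,
        images=images,
    )
    return ds.validate()


def _filter_pass(
    ds: VisiumDataset,
    min_counts_per_spot: int,
    max_fraction_patterns: list[tuple[str, float]],
    min_spots_per_gene: int,
    drop_gene_patterns: list[str],
) -> VisiumDataset:
    counts = sparse.csc_matrix(ds.counts)
    names = ds.features["name"].to_numpy(dtype=object)

    # gene drop by name pattern
    gene_keep = np.ones(len(names), dtype=bool)
    for pat in drop_gene_patterns:
        rx = re.compile(pat)
        gene_keep &= np.array([rx.search(str(n)) is None for n in names])
    if not gene_keep.any():
        raise FilterError("gene-pattern filter removed all genes")
    counts = counts[gene_keep]
    features = ds.features.loc[gene_keep].reset_index(drop=True)

    # gene prevalence: keep genes detected in > min_spots_per_gene spots
    detected_in = np.asarray((counts > 0).sum(axis=1)).ravel()
    prev_keep = detected_in > min_spots_per_gene
    if not prev_keep.any():
        raise FilterError("gene-prevalence filter removed all genes")
    counts = counts[prev_keep]
    features = features.loc[prev_keep].reset_index(drop=True)

    # spot filters: totals strictly above threshold survive
    totals = np.asarray(counts.sum(axis=0)).ravel()
    spot_keep = totals > min_counts_per_spot
    for pat, frac in max_fraction_patterns:
        rx = re.compile(pat)
        in_pat = np.array(
            [rx.search(str(n)) is not None for n in features["name"]]
        )
        pat_sum = np.asarray(counts[in_pat].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pat_frac = np.where(totals > 0, pat_sum / totals, 0.0)
        spot_keep &= pat_frac < frac  # removed at fraction >= threshold
    if not spot_keep.any():
        raise FilterError("spot filters removed all spots")

    barcodes = [b for b, k in zip(ds.barcodes, spot_keep) if k]
    return VisiumDataset(
        barcodes=barcodes,
        features=features,
        counts=counts[:, spot_keep],
        positions=ds.positions.loc[barcodes],
        scalefactors=ds.scalefactors,
        images=ds.images,
    )


def filter_visium(
    ds: VisiumDataset,
    min_counts_per_spot: int = 0,
    max_fraction_patterns: list[tuple[str, float]] | None = None,
    min_spots_per_gene: int = 0,
    drop_gene_patterns: list[str] | None = None,
) -> VisiumDataset:
    """Quality-filter genes then spots, iterated to a fixed point.

    Stage order within each pass: genes matching any ``drop_gene_patterns``
    regex are removed; genes detected in <= ``min_spots_per_gene`` spots are
    removed; spots with total counts <= ``min_counts_per_spot`` are removed;
    spots whose summed counts over genes matching a
    ``(pattern, fraction)`` entry reach that fraction of their total are
    removed.  Passes repeat until the matrix stops shrinking, so the result
    is stable under re-application.
    """
    max_fraction_patterns = list(max_fraction_patterns or [])
    drop_gene_patterns = list(drop_gene_patterns or [])
    if min_counts_per_spot < 0 or min_spots_per_gene < 0:
        raise ValueError("thresholds must be >= 0")
    for _, frac in max_fraction_patterns:
        if not (0 <= frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")

    out = ds
    while True:
        new = _filter_pass(
            out,
            min_counts_per_spot,
            max_fraction_patterns,
            min_spots_per_gene,
            drop_gene_patterns,
        )
        if new.counts.shape == out.counts.shape:
            return new
        out = new


def write_spaceranger_style(
    matrix: sparse.spmatrix | np.ndarray,
    positions: pd.DataFrame,
    scalefactors: dict,
    path: str | Path,
    feature_names: list[str] | None = None,
    feature_ids: list[str] | None = None,
    feature_type: str | list[str] = "Gene Expression",
    barcodes: list[str] | None = None,
    images: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write a features x barcodes matrix as a Space Ranger-style bundle.

    Emits ``filtered_feature_bc_matrix.h5`` (10x HDF5 feature-barcode
    schema) plus a ``spatial/`` folder with the headered tissue positions
    table, ``scalefactors_json.json`` and any provided PNG images.  Float
    matrices are written as float64 (aggregated MSI intensities are
    continuous and are not rounded); integer matrices as int32.

    Returns the bundle directory.  The bundle round-trips through
    :func:`read_spaceranger` and loads in community Visium readers.
    """
    path = Path(path)
    mat = sparse.csc_matrix(matrix)
    if not np.all(np.isfinite(mat.data)):
        raise FormatError("matrix contains non-finite values")
    n_feat, n_bc = mat.shape
    if barcodes is None:
        barcodes = list(positions.index.astype(str))
    if n_bc != len(positions):
        raise FormatError(
            f"matrix has {n_bc} columns but {len(positions)} position records"
        )
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(n_feat)]
    if feature_ids is None:
        feature_ids = list(feature_names)

    path.mkdir(parents=True, exist_ok=True)
    spatial = path / "spatial"
    spatial.mkdir(exist_ok=True)

    dtype = np.int32 if np.issubdtype(mat.dtype, np.integer) else np.float64
    with h5py.File(path / "filtered_feature_bc_matrix.h5", "w") as f:
        # root attributes expected by 10x-format readers
        f.attrs["library_ids"] = np.asarray([path.name.encode() or b"sample"])
        f.attrs["filetype"] = "matrix"
        f.attrs["version"] = 2
        g = f.create_group("matrix")
        g.create_dataset("data", data=mat.data.astype(dtype), track_times=False)
        g.create_dataset("indices", data=mat.indices.astype(np.int64), track_times=False)
        g.create_dataset("indptr", data=mat.indptr.astype(np.int64), track_times=False)
        g.create_dataset("shape", data=np.asarray(mat.shape, dtype=np.int32), track_times=False)
        g.create_dataset("barcodes", data=np.asarray(barcodes, dtype="S"),
                         track_times=False)
        feats = g.create_group("features")
        feats.create_dataset("id", data=np.asarray(feature_ids, dtype="S"),
                             track_times=False)
        feats.create_dataset("name", data=np.asarray(feature_names, dtype="S"),
                             track_times=False)
        ftypes = (
            [feature_type] * n_feat
            if isinstance(feature_type, str)
            else list(feature_type)
        )
        feats.create_dataset("feature_type", data=np.asarray(ftypes, dtype="S"),
                             track_times=False)
        feats.create_dataset("genome", data=np.asarray(["custom"] * n_feat, dtype="S"),
                             track_times=False)
        feats.create_dataset("_all_tag_keys", data=np.asarray(["genome"], dtype="S"),
                             track_times=False)

    pos = positions.copy()
    if "barcode" not in pos.columns:
        pos.insert(0, "barcode", barcodes)
    pos = pos[POSITION_COLUMNS]
    pos.to_csv(spatial / "tissue_positions.csv", index=False)

    (spatial / "scalefactors_json.json").write_text(
        json.dumps(scalefactors, indent=1, sort_keys=True)
    )

    from PIL import Image

    for key, img in (images or {}).items():
        arr = np.asarray(img)
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(spatial / f"tissue_{key}_image.png")

    return path


def write_visium_dataset(ds: VisiumDataset, path: str | Path) -> Path:
    """Serialize a :class:`VisiumDataset` as a Space Ranger-style bundle."""
    return write_spaceranger_style(
        ds.counts,
        ds.positions,
        ds.scalefactors,
        path,
        feature_names=list(ds.features["name"]),
        feature_ids=list(ds.features["id"]),
        feature_type=list(ds.features["feature_type"].astype(str)),
        barcodes=ds.barcodes,
        images=ds.images,
    )
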