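"""Assign transformed MSI pixels to Visium spots and aggregate to 1:1.

After co-registration every MSI pixel has coordinates in the Visium
full-resolution frame.  To obtain matched observations across modalities,
pixels are gathered per spot within a radius and reduced to one value per
spot and peak.  Three radius conventions are supported:

* ``expanded`` — half the minimum centre-to-centre spot distance, the
  largest radius at which expanded spots cannot intersect; every pixel
  belongs to at most one spot (its nearest).
* ``visium`` — the physical capture-spot radius (55 um diameter), for MSI
  rasters much finer than the spot array.
* ``msi`` — the MSI pixel footprint: each pixel acts as a disc of half
  the pixel pitch (converted to fullres px via the 55 um spot diameter)
  and may contribute to several spots, for MSI coarser than Visium.

Reductions: sum, mean, or a distance-weighted average with weights
w_i = 1 / (d_i + eps), eps = 1e-6 x radius (bounded at d = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import MappingError
from .msi_io import MSIDataset
from .visium_io import VisiumDataset

logger = logging.getLogger(__name__)

VISIUM_SPOT_DIAMETER_UM = 55.0  # physical Visium capture-spot diameter
RADIUS_MODES = ("expanded", "visium", "msi")
AGG_FNS = ("sum", "mean", "weighted_average")
WEIGHT_EPS_FACTOR = 1e-6  # eps = factor * radius in the inverse-distance weight


@dataclass
class SpotPixelMapping:
    """Pixel-to-spot assignment table.

    Parallel arrays: ``pixel_index`` (row into the MSI dataset),
    ``barcode_index`` (row into ``barcodes``), ``distance`` in fullres px.
    In expanded/visium modes a pixel appears at most once; in msi mode a
    pixel may serve several spots.
    """

    barcodes: list[str]
    pixel_index: np.ndarray
    barcode_index: np.ndarray
    distance: np.ndarray
    radius_mode: str
    radius_fullres_px: float
    unassigned_pixels: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_assigned(self) -> int:
        return len(self.pixel_index)

    def weights(self) -> np.ndarray:
        eps = WEIGHT_EPS_FACTOR * self.radius_fullres_px
        return 1.0 / (self.distance + eps)

    def to_frame(self, pixel_ids: np.ndarray | None = None) -> pd.DataFrame:
        pid = (
            self.pixel_index
            if pixel_ids is None
            else np.asarray(pixel_ids)[self.pixel_index]
        )
        return pd.DataFrame(
            {
                "barcode": np.asarray(self.barcodes, dtype=object)[
                    self.barcode_index
                ],
                "pixel_id": pid,
                "distance": self.distance,
                "weight": self.weights(),
            }
        )


@dataclass
class MultiModalMatrix:
    """Spot x peak matrix with Visium barcodes as observations."""

    barcodes: list[str]
    mz: np.ndarray
    values: np.ndarray  # (n_barcodes, n_peaks)
    provenance: dict
    empty_spots: np.ndarray  # bool per barcode: no pixel contributed

    def total(self) -> float:
        return float(self.values.sum())


def compute_radius(
    visium: VisiumDataset,
    msi: MSIDataset | None = None,
    mode: str = "expanded",
) -> float:
    """Aggregation radius in fullres pixels for the chosen mode.

    ``expanded``: half the minimum nearest-neighbour distance between spot
    centres (k-NN search, not all-pairs).  ``visium``:
    spot_diameter_fullres / 2.  ``msi``: (pixel_pitch / 55 um) x
    spot_diameter_fullres / 2, using the spot diameter as the um-to-px
    bridge.
    """
    if mode not in RADIUS_MODES:
        raise ValueError(f"unknown radius mode {mode!r}; choose {RADIUS_MODES}")
    if mode == "expanded":
        centres = visium.spot_centres_fullres()
        if len(centres) < 2:
            raise MappingError("expanded mode needs at least 2 spots")
        tree = cKDTree(centres)
        d, _ = tree.query(centres, k=2)
        return float(d[:, 1].min()) / 2.0
    spot_d = float(visium.scalefactors["spot_diameter_fullres"])
    if mode == "visium":
        return spot_d / 2.0
    if msi is None or msi.pixel_pitch is None:
        raise MappingError("msi radius mode requires a known MSI pixel_pitch")
    return (msi.pixel_pitch / VISIUM_SPOT_DIAMETER_UM) * spot_d / 2.0


def map_pixels_to_spots(
    visium: VisiumDataset,
    msi_coords_fullres: np.ndarray,
    radius: float,
    mode: str = "expanded",
) -> SpotPixelMapping:
    """Assign MSI pixels (already in the fullres frame) to spot barcodes.

    expanded/visium: a pixel joins the nearest spot centre if within
    ``radius`` (equidistant ties go to the lexicographically smallest
    barcode); one spot per pixel.  msi: each pixel is a disc of
    ``radius`` and joins every spot centre it covers.  Pixels matching no
    spot are recorded as unassigned; an entirely empty mapping is fatal.
    """
    if mode not in RADIUS_MODES:
        raise ValueError(f"unknown radius mode {mode!r}; choose {RADIUS_MODES}")
    coords = np.atleast_2d(np.asarray(msi_coords_fullres, dtype=float))
    centres = visium.spot_centres_fullres()
    barcodes = list(visium.barcodes)
    tree = cKDTree(centres)

    if mode in ("expanded", "visium"):
        k = min(4, len(centres))
        d, idx = tree.query(coords, k=k)
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        best_d = d[:, 0]
        choice = idx[:, 0].copy()
        # break exact-distance ties by the smaller barcode string
        tied = np.flatnonzero(
            (d[:, 1:] <= best_d[:, None] * (1 + 1e-12) + 1e-12).any(axis=1)
            if k > 1
            else np.zeros(len(coords), bool)
        )
        for i in tied:
            cands = idx[i][np.isclose(d[i], best_d[i], rtol=1e-9, atol=1e-9)]
            choice[i] = min(cands, key=lambda j: barcodes[j])
        within = best_d <= radius
        pixel_index = np.flatnonzero(within)
        barcode_index = choice[within]
        distance = best_d[within]
        unassigned = np.flatnonzero(~within)
    else:  # msi mode: one pixel may cover several spot centres
        hits = tree.query_ball_point(coords, r=radius)
        pix, bc = [], []
        for i, spots in enumerate(hits):
            for j in spots:
                pix.append(i)
                bc.append(j)
        pixel_index = np.asarray(pix, dtype=int)
        barcode_index = np.asarray(bc, dtype=int)
        distance = (
            np.linalg.norm(coords[pixel_index] - centres[barcode_index], axis=1)
            if len(pixel_index)
            else np.array([])
        )
        assigned = np.unique(pixel_index)
        unassigned = np.setdiff1d(np.arange(len(coords)), assigned)

    if len(pixel_index) == 0:
        raise MappingError(
            "no MSI pixel lies within any spot radius — the registration "
            "likely failed or coordinates are in the wrong frame"
        )
    logger.info(
        "assigned %d/%d pixels to %d spots (mode=%s, radius=%.2f px)",
        len(np.unique(pixel_index)),
        len(coords),
        len(np.unique(barcode_index)),
        mode,
        radius,
    )
    return SpotPixelMapping(
        barcodes=barcodes,
        pixel_index=pixel_index,
        barcode_index=barcode_index,
        distance=np.asarray(distance, dtype=float),
        radius_mode=mode,
        radius_fullres_px=float(radius),
        unassigned_pixels=unassigned,
    )


def aggregate(
    mapping: SpotPixelMapping, msi: MSIDataset, fn: str = "mean"
) -> MultiModalMatrix:
    """Reduce assigned pixels to one observation per spot barcode.

    Spots with no assigned pixel get an all-zero row and are flagged in
    ``empty_spots`` so the barcode set stays 1:1 with the Visium object.
    """
    if fn not in AGG_FNS:
        raise ValueError(f"unknown aggregation fn {fn!r}; choose {AGG_FNS}")
    n_spots = len(mapping.barcodes)
    n_peaks = msi.n_peaks
    values = np.zeros((n_spots, n_peaks))
    I = msi.intensities[mapping.pixel_index]

    if fn == "sum":
        np.add.at(values, mapping.barcode_index, I)
    elif fn == "mean":
        np.add.at(values, mapping.barcode_index, I)
        counts = np.bincount(mapping.barcode_index, minlength=n_spots)
        nz = counts > 0
        values[nz] /= counts[nz, None]
    else:  # weighted_average
        w = mapping.weights()
        np.add.at(values, mapping.barcode_index, I * w[:, None])
        wsum = np.bincount(
            mapping.barcode_index, weights=w, minlength=n_spots
        )
        nz = wsum > 0
        values[nz] /= wsum[nz, None]

    occupied = np.zeros(n_spots, dtype=bool)
    occupied[np.unique(mapping.barcode_index)] = True
    return MultiModalMatrix(
        barcodes=list(mapping.barcodes),
        mz=np.asarray(msi.mz, dtype=float),
        values=values,
        provenance={
            "aggregation": fn,
            "radius_mode": mapping.radius_mode,
            "radius_fullres_px": mapping.radius_fullres_px,
            "weight_eps_factor": WEIGHT_EPS_FACTOR,
        },
        empty_spots=~occupied,
    )
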