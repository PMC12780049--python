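"""Synthetic paired Visium + MSI scenarios with known ground truth.

The generator emulates the geometry of consecutive tissue sections: a
hexagonal Visium spot lattice with a tissue region (an ellipse with two
interior holes — boundary features of the kind that make landmarks easy to
place), and an MSI pixel raster related to the Visium full-resolution
frame by a known invertible warp.  Peak intensities follow the tissue
mask: a "structural" peak (lactate-like, m/z 89.02435) elevated across
the tissue, a "compound" peak (drug-like, m/z 550.15724) present only in
deposition hotspots, plus unstructured noise peaks.  Because the warp,
mask and landmark pool are exact, every pipeline stage can be validated
against ground truth without external data.

Intensities are truncated-Gaussian draws rounded to integers, so
sum-aggregation bookkeeping can be checked for exact conservation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import SpotfuseError
from .msi_io import MSIDataset, write_peak_table
from .registration import AffineTransform2D, LandmarkSet, write_landmarks
from .visium_io import VisiumDataset, write_visium_dataset

STRUCTURAL_MZ = 89.02435  # tissue-wide metabolite peak (lactate-like)
COMPOUND_MZ = 550.15724  # hotspot-only compound peak (drug-like)
NB_DISPERSION = 0.5  # gene-count over-dispersion: var = mu + disp * mu^2


@dataclass
class EllipseMask:
    """Elliptical tissue region with circular holes, in fullres pixels."""

    centre: tuple[float, float]
    semi_axes: tuple[float, float]
    holes: list[tuple[float, float, float]] = field(default_factory=list)
    # each hole: (cx, cy, radius)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(xy, dtype=float))
        dx = (p[:, 0] - self.centre[0]) / self.semi_axes[0]
        dy = (p[:, 1] - self.centre[1]) / self.semi_axes[1]
        inside = dx**2 + dy**2 <= 1.0
        for cx, cy, r in self.holes:
            inside &= (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 > r**2
        return inside

    def to_dict(self) -> dict:
        return {
            "centre": list(self.centre),
            "semi_axes": list(self.semi_axes),
            "holes": [list(h) for h in self.holes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseMask":
        return cls(
            tuple(d["centre"]),
            tuple(d["semi_axes"]),
            [tuple(h) for h in d["holes"]],
        )


@dataclass
class PeakModel:
    """Spatial intensity model for one synthetic peak."""

    mz: float
    baseline: float
    tissue_effect: float
    noise_sd: float
    hotspots: list[tuple[float, float, float]] | None = None
    # hotspots (fullres frame): peak appears only inside these discs

    def to_dict(self) -> dict:
        return {
            "mz": self.mz,
            "baseline": self.baseline,
            "tissue_effect": self.tissue_effect,
            "noise_sd": self.noise_sd,
            "hotspots": None
            if self.hotspots is None
            else [list(h) for h in self.hotspots],
        }


@dataclass
class SyntheticTruth:
    """Everything the generator knows and the pipeline must recover."""

    warp: AffineTransform2D  # MSI native -> Visium fullres
    tissue_mask: EllipseMask  # in the Visium fullres frame
    rng_seed: int
    intensity_model: list[PeakModel]
    msi_bbox: tuple[float, float, float, float] | None = None
    # (xmin, ymin, xmax, ymax) of the MSI native domain, set by make_msi_fixture

    def to_dict(self) -> dict:
        return {
            "warp": self.warp.to_dict(),
            "tissue_mask": self.tissue_mask.to_dict(),
            "rng_seed": self.rng_seed,
            "intensity_model": [p.to_dict() for p in self.intensity_model],
            "msi_bbox": None if self.msi_bbox is None else list(self.msi_bbox),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        from .registration import transform_from_dict

        return cls(
            warp=transform_from_dict(d["warp"]),
            tissue_mask=EllipseMask.from_dict(d["tissue_mask"]),
            rng_seed=int(d["rng_seed"]),
            intensity_model=[
                PeakModel(
                    mz=p["mz"],
                    baseline=p["baseline"],
                    tissue_effect=p["tissue_effect"],
                    noise_sd=p["noise_sd"],
                    hotspots=None
                    if p.get("hotspots") is None
                    else [tuple(h) for h in p["hotspots"]],
                )
                for p in d["intensity_model"]
            ],
            msi_bbox=None if d.get("msi_bbox") is None else tuple(d["msi_bbox"]),
        )


def load_truth(path: str | Path) -> SyntheticTruth:
    """Read a ground-truth JSON written by :func:`write_scenario`."""
    return SyntheticTruth.from_dict(json.loads(Path(path).read_text()))


def default_warp(seed: int = 0, displacement: tuple[float, float] = (260.0, -180.0),
                 rotation_deg: float = 7.0, scale: float = 1.05) -> AffineTransform2D:
    """A representative section-to-section misalignment.

    Rotation of a few degrees, a small scale change, and a translation of
    a couple of spot spacings — the magnitude of offset seen between
    consecutive cryosections mounted on different slides.
    """
    rng = np.random.default_rng(seed)
    th = np.deg2rad(rotation_deg + rng.normal(0, 0.5))
    s = scale * (1 + rng.normal(0, 0.01))
    M = np.eye(3)
    M[:2, :2] = s * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    M[:2, 2] = displacement
    return AffineTransform2D(M, domain_frame="msi_native", codomain_frame="fullres")


def default_truth(
    seed: int = 0,
    extent: tuple[float, float] = (1400.0, 1250.0),
    warp: AffineTransform2D | None = None,
) -> SyntheticTruth:
    """Standard scenario: elliptical tissue with two holes and two
    informative peaks plus three noise peaks."""
    W, H = extent
    mask = EllipseMask(
        centre=(0.52 * W, 0.5 * H),
        semi_axes=(0.38 * W, 0.33 * H),
        holes=[
            (0.40 * W, 0.38 * H, 0.06 * W),
            (0.63 * W, 0.62 * H, 0.045 * W),
        ],
    )
    hotspots = [
        (0.55 * W, 0.42 * H, 0.05 * W),
        (0.42 * W, 0.60 * H, 0.04 * W),
    ]
    model = [
        PeakModel(STRUCTURAL_MZ, baseline=20, tissue_effect=80, noise_sd=6),
        PeakModel(COMPOUND_MZ, baseline=0, tissue_effect=60, noise_sd=4,
                  hotspots=hotspots),
        PeakModel(180.06339, baseline=35, tissue_effect=45, noise_sd=8),
        PeakModel(255.23295, baseline=25, tissue_effect=-12, noise_sd=5),
        PeakModel(400.25, baseline=15, tissue_effect=0, noise_sd=5),
    ]
    return SyntheticTruth(
        warp=warp if warp is not None else default_warp(seed),
        tissue_mask=mask,
        rng_seed=seed,
        intensity_model=model,
    )


def make_visium_fixture(
    n_rows: int = 14,
    n_cols: int = 12,
    spacing_px: float = 100.0,
    truth: SyntheticTruth | None = None,
    n_genes: int = 30,
) -> VisiumDataset:
    """Hexagonal Visium-like lattice with mask-driven tissue flags.

    Odd array rows are offset by half a spacing and the row pitch is
    spacing x sqrt(3)/2, so the minimum centre-to-centre distance equals
    ``spacing_px`` exactly.  Gene counts are negative-binomial with the
    mean elevated inside the tissue mask (dispersion 0.5).
    ``spot_diameter_fullres`` is 0.55 x spacing, mirroring the 55 um spot
    on a 100 um pitch array.
    """
    if n_rows < 2 or n_cols < 2:
        raise SpotfuseError("lattice needs at least 2 rows and 2 columns")
    if spacing_px <= 0:
        raise SpotfuseError("spacing must be positive")
    truth = truth if truth is not None else default_truth()
    rng = np.random.default_rng(np.random.SeedSequence([truth.rng_seed, 11]))

    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    x = cols * spacing_px + (rows % 2) * spacing_px / 2.0 + spacing_px / 2.0
    y = rows * spacing_px * np.sqrt(3) / 2.0 + spacing_px / 2.0
    barcodes = [f"SPOT-{r:03d}-{c:03d}" for r, c in zip(rows, cols)]
    in_tissue = truth.tissue_mask.contains(np.column_stack([x, y])).astype(int)

    positions = pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": in_tissue,
            "array_row": rows,
            "array_col": cols,
            "pxl_row_in_fullres": y,
            "pxl_col_in_fullres": x,
        }
    ).set_index("barcode", drop=False)

    # over-dispersed counts: NB with var = mu + disp * mu^2
    base_mu = rng.uniform(0.5, 8.0, size=n_genes)
    tissue_fold = rng.uniform(1.5, 6.0, size=n_genes)
    mu = base_mu[:, None] * np.where(in_tissue[None, :] == 1, tissue_fold[:, None], 1.0)
    r = 1.0 / NB_DISPERSION
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    genes = [f"Gene{i:03d}" for i in range(n_genes)]

    W = float(x.max() + spacing_px / 2.0)
    H = float(y.max() + spacing_px / 2.0)
    hires_scale = 600.0 / max(W, H)
    lowres_scale = 200.0 / max(W, H)
    scalefactors = {
        "spot_diameter_fullres": 0.55 * spacing_px,
        "tissue_hires_scalef": hires_scale,
        "tissue_lowres_scalef": lowres_scale,
        "fiducial_diameter_fullres": 0.85 * spacing_px,
    }
    images = {
        "hires": _render_mask_image(truth.tissue_mask, W, H, hires_scale),
        "lowres": _render_mask_image(truth.tissue_mask, W, H, lowres_scale),
    }
    return VisiumDataset(
        barcodes=barcodes,
        features=pd.DataFrame(
            {"id": genes, "name": genes, "feature_type": "Gene Expression"}
        ),
        counts=sparse.csc_matrix(counts),
        positions=positions,
        scalefactors=scalefactors,
        images=images,
    ).validate()


def _render_mask_image(
    mask: EllipseMask, W: float, H: float, scale: float
) -> np.ndarray:
    """Grayscale-as-RGB rendering of the tissue mask (a stand-in H&E)."""
    w, h = int(np.ceil(W * scale)), int(np.ceil(H * scale))
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([cols.ravel() / scale, rows.ravel() / scale])
    inside = mask.contains(pts).reshape(h, w)
    img = np.full((h, w), 235, dtype=np.uint8)
    img[inside] = 150
    return np.repeat(img[:, :, None], 3, axis=2)


def make_msi_fixture(
    resolution_factor: float = 8.0,
    truth: SyntheticTruth | None = None,
    visium: VisiumDataset | None = None,
    spacing_px: float = 100.0,
    pixel_pitch_um: float = 65.0,
) -> MSIDataset:
    """Rectilinear MSI raster covering the warped-back Visium extent.

    ``resolution_factor`` is MSI pixels per Visium spot spacing.  Each
    pixel's intensity is baseline + tissue_effect x [warp(pixel) in mask]
    + Gaussian noise, truncated at zero and rounded to an integer;
    hotspot-restricted peaks are zero outside their discs.  Pixel
    coordinates are in MSI native units (one unit per raster step);
    ``pixel_pitch`` records the nominal um spacing.
    """
    if resolution_factor <= 0:
        raise SpotfuseError("resolution_factor must be positive")
    truth = truth if truth is not None else default_truth()
    if visium is None:
        visium = make_visium_fixture(truth=truth, spacing_px=spacing_px)
    rng = np.random.default_rng(np.random.SeedSequence([truth.rng_seed, 23]))

    centres = visium.spot_centres_fullres()
    margin = spacing_px
    corners = np.array(
        [
            [centres[:, 0].min() - margin, centres[:, 1].min() - margin],
            [centres[:, 0].max() + margin, centres[:, 1].min() - margin],
            [centres[:, 0].min() - margin, centres[:, 1].max() + margin],
            [centres[:, 0].max() + margin, centres[:, 1].max() + margin],
        ]
    )
    back = truth.warp.inverse().apply(corners)
    xmin, ymin = back.min(axis=0)
    xmax, ymax = back.max(axis=0)
    step = spacing_px / resolution_factor
    xs = np.arange(xmin, xmax + step, step)
    ys = np.arange(ymin, ymax + step, step)
    gx, gy = np.meshgrid(xs, ys)
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    truth.msi_bbox = (float(xmin), float(ymin), float(xmax), float(ymax))

    fullres = truth.warp.apply(coords)
    in_mask = truth.tissue_mask.contains(fullres)

    peaks = sorted(truth.intensity_model, key=lambda p: p.mz)
    intensities = np.zeros((len(coords), len(peaks)))
    for j, pk in enumerate(peaks):
        mu = pk.baseline + pk.tissue_effect * in_mask.astype(float)
        v = mu + rng.normal(0.0, pk.noise_sd, size=len(coords)) if pk.noise_sd > 0 else mu
        if pk.hotspots is not None:
            in_hot = np.zeros(len(coords), dtype=bool)
            for cx, cy, r in pk.hotspots:
                in_hot |= (fullres[:, 0] - cx) ** 2 + (fullres[:, 1] - cy) ** 2 <= r**2
            v = np.where(in_hot, v, 0.0)
        intensities[:, j] = np.round(np.maximum(v, 0.0))

    return MSIDataset(
        pixel_ids=np.arange(len(coords)),
        coords=coords,
        mz=np.array([p.mz for p in peaks]),
        intensities=intensities,
        pixel_meta=pd.DataFrame({"roi": np.where(in_mask, "tissue", "background")}),
        pixel_pitch=pixel_pitch_um,
    ).validate()


def export_landmarks(
    truth: SyntheticTruth,
    n: int = 20,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> LandmarkSet:
    """Exact (or jittered) landmark pairs under the generating warp.

    Source points are sampled in the MSI native frame such that their
    warped images fall in the tissue-boundary band (where a human would
    place landmarks); targets are warp(source) plus optional Gaussian
    jitter in fullres px.  With jitter 0 the pool satisfies the warp
    exactly, enabling transform-recovery tests.
    """
    if n < 3:
        raise SpotfuseError("at least 3 landmarks are required")
    if truth.msi_bbox is None:
        raise SpotfuseError("truth.msi_bbox unset; generate the MSI fixture first")
    rng = np.random.default_rng(np.random.SeedSequence([seed, truth.rng_seed, 37]))
    xmin, ymin, xmax, ymax = truth.msi_bbox
    mask = truth.tissue_mask

    picked: list[np.ndarray] = []
    attempts = 0
    while len(picked) < n and attempts < 20000:
        attempts += 1
        p = rng.uniform([xmin, ymin], [xmax, ymax])
        f = truth.warp.apply(p[None, :])[0]
        # boundary band: inside a slightly inflated ellipse, near the edge
        # of the mask or one of its holes
        dx = (f[0] - mask.centre[0]) / mask.semi_axes[0]
        dy = (f[1] - mask.centre[1]) / mask.semi_axes[1]
        rho = np.hypot(dx, dy)
        near_edge = 0.8 <= rho <= 1.1
        near_hole = any(
            0.6 * r <= np.hypot(f[0] - cx, f[1] - cy) <= 1.6 * r
            for cx, cy, r in mask.holes
        )
        if near_edge or near_hole:
            picked.append(p)
    if len(picked) < n:
        raise SpotfuseError("could not place the requested number of landmarks")
    source = np.vstack(picked)
    target = truth.warp.apply(source)
    if jitter_sd > 0:
        target = target + rng.normal(0.0, jitter_sd, size=target.shape)
    return LandmarkSet(source, target, stage="msi_data->visium")


def write_scenario(
    out_dir: str | Path,
    seed: int = 0,
    n_rows: int = 14,
    n_cols: int = 12,
    spacing_px: float = 100.0,
    resolution_factor: float = 8.0,
    n_landmarks: int = 20,
    jitter_sd: float = 0.0,
) -> Path:
    """Write a complete on-disk scenario: Visium bundle, MSI peak table,
    landmark CSV and ground-truth JSON.  Byte-reproducible per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = default_truth(seed=seed)
    visium = make_visium_fixture(
        n_rows=n_rows, n_cols=n_cols, spacing_px=spacing_px, truth=truth
    )
    msi = make_msi_fixture(
        resolution_factor=resolution_factor,
        truth=truth,
        visium=visium,
        spacing_px=spacing_px,
    )
    landmarks = export_landmarks(truth, n=n_landmarks, jitter_sd=jitter_sd, seed=seed)

    write_visium_dataset(visium, out_dir / "visium")
    write_peak_table(msi, out_dir / "msi_peaks.csv")
    write_landmarks(landmarks, out_dir / "landmarks.csv")
    (out_dir / "truth.json").write_text(
        json.dumps(truth.to_dict(), indent=1, sort_keys=True)
    )
    return out_dir
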