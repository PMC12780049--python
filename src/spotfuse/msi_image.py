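"""Data-generated MSI images and tissue/background labelling.

MSI acquisitions have no camera image of their own, so landmarks must be
picked on an image generated from the data itself: each pixel is coloured
either by 1-3 principal components of its peak intensities (RGB channels)
or by a single spatially informative peak.  The same first principal
component, thresholded (fixed value or Otsu), yields per-pixel
tissue/background labels used later to score the co-registration.

The raster follows the image convention: row index grows with MSI y
(downward), column index with MSI x.  An :class:`MSIImage` carries the
affine frame mapping raster cells back to MSI native coordinates so that
landmark picks on the image convert to data coordinates exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError
from .msi_io import MSIDataset

logger = logging.getLogger(__name__)


@dataclass
class MSIImage:
    """Raster derived from MSI pixel data plus its coordinate frame.

    ``frame`` holds ``x_offset``, ``y_offset``, ``x_step``, ``y_step``:
    raster cell (row, col) sits at native
    ``(x_offset + col * x_step, y_offset + row * y_step)``.
    ``occupied`` flags cells backed by a real MSI pixel; the rest are
    background fill (value 0).
    """

    raster: np.ndarray  # H x W (grayscale) or H x W x 3, values in [0, 255]
    frame: dict
    occupied: np.ndarray
    channel_sources: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape[:2]

    def raster_to_native(self, points_colrow: np.ndarray) -> np.ndarray:
        """Map (col, row) raster points to MSI native (x, y)."""
        p = np.atleast_2d(np.asarray(points_colrow, dtype=float))
        x = self.frame["x_offset"] + p[:, 0] * self.frame["x_step"]
        y = self.frame["y_offset"] + p[:, 1] * self.frame["y_step"]
        return np.column_stack([x, y])

    def native_to_raster(self, points_xy: np.ndarray) -> np.ndarray:
        """Map MSI native (x, y) to fractional raster (col, row)."""
        p = np.atleast_2d(np.asarray(points_xy, dtype=float))
        col = (p[:, 0] - self.frame["x_offset"]) / self.frame["x_step"]
        row = (p[:, 1] - self.frame["y_offset"]) / self.frame["y_step"]
        return np.column_stack([col, row])

    def save(self, path: str | Path) -> Path:
        """Write the raster as PNG plus a sidecar JSON with the frame."""
        from PIL import Image

        path = Path(path)
        arr = np.clip(np.round(self.raster), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)
        sidecar = {
            "frame": self.frame,
            "channel_sources": self.channel_sources,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )
        return path


def _infer_step(values: np.ndarray) -> float:
    uniq = np.unique(values)
    if len(uniq) < 2:
        return 1.0  # single row/column: any positive step rasterizes it
    diffs = np.diff(uniq)
    diffs = diffs[diffs > 0]
    step = float(np.median(diffs))
    if step <= 0:
        raise FormatError("degenerate coordinates: inferred grid step <= 0")
    return step


def rasterize(ds: MSIDataset, values: np.ndarray) -> MSIImage:
    """Place per-pixel values onto the inferred rectilinear raster.

    The grid step per axis is the median positive difference of sorted
    unique coordinates; every MSI pixel must land in its own cell.
    ``values`` is (n_pixels,) or (n_pixels, channels), already in [0, 255].
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    x, y = ds.coords[:, 0], ds.coords[:, 1]
    x_step, y_step = _infer_step(x), _infer_step(y)
    x0, y0 = float(x.min()), float(y.min())
    col = np.round((x - x0) / x_step).astype(int)
    row = np.round((y - y0) / y_step).astype(int)
    H, W = int(row.max()) + 1, int(col.max()) + 1
    flat = row * W + col
    if len(np.unique(flat)) != len(flat):
        raise FormatError("two MSI pixels map to the same raster cell")

    n_ch = values.shape[1]
    raster = np.zeros((H, W, n_ch))
    occupied = np.zeros((H, W), dtype=bool)
    raster[row, col] = values
    occupied[row, col] = True
    if n_ch == 1:
        raster = raster[:, :, 0]
    return MSIImage(
        raster=raster,
        frame={
            "x_offset": x0,
            "y_offset": y0,
            "x_step": x_step,
            "y_step": y_step,
        },
        occupied=occupied,
        channel_sources=[f"channel_{i}" for i in range(n_ch)],
    )


def pca_scores(
    ds: MSIDataset, n_components: int, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of the pixel x peak matrix.

    Peaks are mean-centred; unit-variance scaling is off by default so the
    high-intensity structural peaks that delineate tissue dominate the
    components.  The sign of each component is fixed by forcing its
    largest-magnitude loading positive, making results deterministic and
    independent of pixel order.

    Returns (scores: n_pixels x k, loadings: n_peaks x k).
    """
    if ds.n_pixels < 2:
        raise FormatError("PCA needs at least 2 pixels")
    if ds.n_peaks < n_components:
        raise FormatError(
            f"requested {n_components} components but only {ds.n_peaks} peaks"
        )
    X = ds.intensities - ds.intensities.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    if not np.any(X):
        raise FormatError("no variance across pixels: PCA undefined")
    # SVD of the centred matrix; deterministic up to sign, fixed below
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt[:n_components].T  # loadings
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(n_components)])
    signs[signs == 0] = 1.0
    V = V * signs
    scores = X @ V
    return scores, V


def pca_rgb_image(
    ds: MSIDataset,
    n_components: int = 3,
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
    scale: bool = False,
) -> MSIImage:
    """Colour each pixel by 1-3 principal components as RGB channels.

    Each component is clipped at the given percentiles and min-max scaled
    to [0, 255]; components fill R, G, B in order and unused channels stay
    zero.
    """
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1, 2 or 3")
    scores, _ = pca_scores(ds, n_components, scale=scale)
    lo, hi = clip_percentiles
    channels = np.zeros((ds.n_pixels, 3))
    for k in range(n_components):
        s = scores[:, k]
        a, b = np.percentile(s, [lo, hi])
        s = np.clip(s, a, b)
        rng = b - a
        channels[:, k] = 0.0 if rng == 0 else (s - a) / rng * 255.0
    img = rasterize(ds, channels)
    img.channel_sources = [
        f"PC{k + 1}" if k < n_components else "unused" for k in range(3)
    ]
    return img


def single_peak_image(
    ds: MSIDataset, mz: float, cap_percentile: float = 99.0
) -> MSIImage:
    """Grayscale raster of one peak, capped at a percentile then scaled.

    Capping at (by default) the 99th percentile stops isolated hot pixels
    from compressing the dynamic range of the tissue signal.
    """
    j = ds.peak_index(mz)
    v = ds.intensities[:, j].astype(float)
    cap = np.percentile(v, cap_percentile)
    v = np.minimum(v, cap)
    vmax = v.max()
    v = v / vmax * 255.0 if vmax > 0 else v
    img = rasterize(ds, v)
    img.channel_sources = [f"mz={ds.mz[j]!r}"]
    return img


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold on a quantized histogram of ``values``.

    The value range is quantized into ``n_bins`` levels and the cut
    maximizing between-class variance is returned (as a value on the
    original scale, at a bin edge).  Ties go to the lowest such cut.
    """
    v = np.asarray(values, dtype=float)
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return vmin
    hist, edges = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    p = hist / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(n_bins))
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b[:-1]))  # last bin cannot be a cut
    return float(edges[k + 1])


def tissue_labels_from_pc1(
    ds: MSIDataset, threshold: float | str = "otsu", scale: bool = False
) -> np.ndarray:
    """Per-pixel tissue(True)/background(False) labels from PC1.

    PC1 is computed as for :func:`pca_rgb_image`; pixels above the
    threshold (a number on the PC1 scale, or ``"otsu"``) form one class.
    The orientation is data-driven: the class with the higher mean total
    intensity is called tissue, regardless of the component's sign.
    """
    scores, _ = pca_scores(ds, 1, scale=scale)
    s = scores[:, 0]
    thr = otsu_threshold(s) if threshold == "otsu" else float(threshold)
    above = s > thr
    if above.all() or (~above).all():
        warnings.warn(
            "PC1 threshold puts every pixel in one class; "
            "labels are uninformative",
            stacklevel=2,
        )
        return np.ones(ds.n_pixels, dtype=bool) if above.all() else np.zeros(
            ds.n_pixels, dtype=bool
        )
    totals = ds.total_intensity_per_pixel()
    if totals[above].mean() >= totals[~above].mean():
        return above
    return ~above
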