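"""Read, normalize, deduplicate and quality-filter MSI peak-by-pixel tables.

Mass spectrometry imaging software (e.g. SCiLS Lab, Cardinal) exports a
pixel-by-peak table: one row per raster pixel with its (x, y) position and
one numeric column per spectral peak, headed by the peak's m/z value.
That table — typically already TIC-normalized upstream — is the MSI entry
point for the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FilterError, FormatError

logger = logging.getLogger(__name__)

MZ_MATCH_TOL = 1e-6  # Da; exact-identity matching of peak masses


@dataclass
class MSIDataset:
    """MSI pixels with peak intensities.

    Attributes
    ----------
    pixel_ids
        One identifier per pixel (row order of ``intensities``).
    coords
        (n_pixels, 2) array of (x, y) positions in MSI native units.
    mz
        Peak masses in Da, one per intensity column.
    intensities
        (n_pixels, n_peaks) non-negative matrix.
    pixel_meta
        Optional per-pixel metadata (e.g. a tissue/background ROI label).
    pixel_pitch
        Spacing between adjacent pixel centres in micrometres, if known
        (65 um is a typical DESI raster pitch).
    """

    pixel_ids: np.ndarray
    coords: np.ndarray
    mz: np.ndarray
    intensities: np.ndarray
    pixel_meta: pd.DataFrame | None = None
    pixel_pitch: float | None = None

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[1]

    def validate(self) -> "MSIDataset":
        if self.intensities.shape != (len(self.pixel_ids), len(self.mz)):
            raise FormatError("intensity matrix shape mismatch")
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("intensities contain non-finite values")
        if (self.intensities < 0).any():
            i, j = np.argwhere(self.intensities < 0)[0]
            raise FormatError(
                f"negative intensity at pixel {self.pixel_ids[i]!r}, "
                f"m/z {self.mz[j]}"
            )
        if np.any(np.asarray(self.mz) <= 0):
            raise FormatError("m/z values must be strictly positive")
        uniq = np.unique(self.coords, axis=0)
        if len(uniq) != len(self.coords):
            raise FormatError("duplicate pixel coordinates")
        return self

    def total_intensity_per_pixel(self) -> np.ndarray:
        return self.intensities.sum(axis=1)

    def peak_index(self, mz: float) -> int:
        """Index of the peak matching ``mz`` within 1e-6 Da, else fatal."""
        d = np.abs(np.asarray(self.mz, dtype=float) - mz)
        i = int(np.argmin(d))
        if d[i] > MZ_MATCH_TOL:
            raise FormatError(
                f"no peak at m/z {mz}; nearest is {self.mz[i]} ({d[i]:.3g} Da away)"
            )
        return i


def read_peak_table(
    path: str | Path, x_col: str = "x", y_col: str = "y"
) -> MSIDataset:
    """Read a delimited pixel-by-peak table into an :class:`MSIDataset`.

    Columns whose header parses as a number are peaks (the header is the
    m/z value); remaining columns become per-pixel metadata.  Delimiter is
    sniffed (comma or tab).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in (x_col, y_col):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing coordinate column {col!r}")

    peak_cols: list[str] = []
    mz: list[float] = []
    for col in df.columns:
        if col in (x_col, y_col):
            continue
        try:
            mz.append(float(col))
            peak_cols.append(col)
        except ValueError:
            continue
    if not peak_cols:
        raise FormatError(f"{path.name}: no numeric m/z peak columns found")

    meta_cols = [c for c in df.columns if c not in peak_cols + [x_col, y_col]]
    order = np.argsort(mz, kind="stable")
    ds = MSIDataset(
        pixel_ids=np.arange(len(df)),
        coords=df[[x_col, y_col]].to_numpy(dtype=float),
        mz=np.asarray(mz, dtype=float)[order],
        intensities=df[peak_cols].to_numpy(dtype=float)[:, order],
        pixel_meta=df[meta_cols].copy() if meta_cols else None,
    )
    return ds.validate()


def write_peak_table(
    ds: MSIDataset, path: str | Path, x_col: str = "x", y_col: str = "y"
) -> Path:
    """Write an :class:`MSIDataset` back as a CSV peak-by-pixel table."""
    path = Path(path)
    df = pd.DataFrame(
        {x_col: ds.coords[:, 0], y_col: ds.coords[:, 1]}
    )
    if ds.pixel_meta is not None:
        for c in ds.pixel_meta.columns:
            df[c] = np.asarray(ds.pixel_meta[c])
    for j, m in enumerate(ds.mz):
        df[repr(float(m))] = ds.intensities[:, j]
    df.to_csv(path, index=False)
    return path


def _take_pixels(ds: MSIDataset, keep: np.ndarray) -> MSIDataset:
    return replace(
        ds,
        pixel_ids=ds.pixel_ids[keep],
        coords=ds.coords[keep],
        intensities=ds.intensities[keep],
        pixel_meta=None
        if ds.pixel_meta is None
        else ds.pixel_meta.iloc[np.flatnonzero(keep)
                                if keep.dtype == bool else keep].reset_index(drop=True),
    )


def _take_peaks(ds: MSIDataset, keep: np.ndarray) -> MSIDataset:
    return replace(ds, mz=ds.mz[keep], intensities=ds.intensities[:, keep])


def tic_normalize(ds: MSIDataset, target: float | str = "median") -> MSIDataset:
    """Total-ion-count normalization with a common per-pixel target total.

    Each pixel's intensities are divided by that pixel's total, then scaled
    so every pixel sums to the same constant: the median pre-normalization
    pixel total by default (keeps magnitudes comparable to the raw scale),
    or 1.0 with ``target="unit"``, or any positive number.  Pixels whose
    total is zero are dropped (count logged); all-zero input is fatal.
    """
    totals = ds.total_intensity_per_pixel()
    nonzero = totals > 0
    if not nonzero.any():
        raise FilterError("all pixels have zero total intensity")
    if not nonzero.all():
        logger.info("dropping %d zero-total pixels", int((~nonzero).sum()))
        ds = _take_pixels(ds, nonzero)
        totals = totals[nonzero]
    if target == "median":
        scale = float(np.median(totals))
    elif target == "unit":
        scale = 1.0
    else:
        scale = float(target)
        if scale <= 0:
            raise ValueError("normalization target must be positive")
    out = ds.intensities / totals[:, None] * scale
    return replace(ds, intensities=out)


def deduplicate_peaks(
    datasets: MSIDataset | list[MSIDataset], decimals: int = 2
) -> MSIDataset | list[MSIDataset]:
    """Collapse peaks that share a mass after rounding to ``decimals``.

    Within each rounded-mass group only the peak with the largest total
    intensity — summed over all pixels of all provided samples — is kept;
    ties go to the lower exact mass.  Pass a list to deduplicate several
    samples jointly on the shared peak list ("across all samples");
    a single dataset is handled alone and returned alone.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    single = isinstance(datasets, MSIDataset)
    group = [datasets] if single else list(datasets)
    mz = np.asarray(group[0].mz, dtype=float)
    for ds in group[1:]:
        if not np.array_equal(np.asarray(ds.mz, dtype=float), mz):
            raise FormatError("joint deduplication requires identical peak lists")

    totals = np.zeros(len(mz))
    for ds in group:
        totals += ds.intensities.sum(axis=0)

    key = np.round(mz, decimals)
    keep: list[int] = []
    for k in np.unique(key):
        members = np.flatnonzero(key == k)
        # best total; ties broken by lower exact mass (members sorted by mz)
        order = members[np.argsort(mz[members], kind="stable")]
        keep.append(int(order[np.argmax(totals[order])]))
    keep_arr = np.array(sorted(keep, key=lambda i: mz[i]))

    out = [_take_peaks(ds, keep_arr) for ds in group]
    return out[0] if single else out


def filter_msi(
    ds: MSIDataset,
    min_peaks_per_pixel: int = 0,
    min_total_intensity: float = 0.0,
    keep_mz: list[float] | None = None,
) -> MSIDataset:
    """Pixel and peak quality filter.

    A pixel survives iff it has strictly more than ``min_peaks_per_pixel``
    detected peaks (strictly positive intensities) AND a total intensity
    strictly above ``min_total_intensity`` — both thresholds mirror the
    "keep pixels with more than N peaks and total intensity > T" style of
    upstream QC, so they are strict inequalities.  If ``keep_mz`` is given
    the peak set is restricted to masses matching within 1e-6 Da.
    No surviving value is altered: the output is a submatrix of the input.
    """
    if min_peaks_per_pixel < 0 or min_total_intensity < 0:
        raise ValueError("thresholds must be >= 0")
    out = ds
    if keep_mz is not None:
        cols = sorted({out.peak_index(m) for m in keep_mz})
        out = _take_peaks(out, np.asarray(cols, dtype=int))

    n_detected = (out.intensities > 0).sum(axis=1)
    totals = out.intensities.sum(axis=1)
    by_peaks = n_detected > min_peaks_per_pixel
    by_total = totals > min_total_intensity
    keep = by_peaks & by_total
    if not keep.any():
        raise FilterError(
            f"all {out.n_pixels} pixels removed "
            f"({int((~by_peaks).sum())} failed the detected-peak threshold, "
            f"{int((~by_total).sum())} failed the total-intensity threshold)"
        )
    return _take_pixels(out, keep)
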