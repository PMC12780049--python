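"""Landmark-based 2-D transforms: affine and thin-plate spline (TPS).

Corresponding point pairs picked on two images define a geometric map
between their frames.  Two families are supported:

* **Affine** — 6 parameters (linear part + translation), fitted by least
  squares over all pairs.  Appropriate when the two sections differ only
  by rotation, scaling, shear and shift.
* **Thin-plate spline** — the interpolating warp minimizing bending
  energy, exact at the control points (regularization 0 by default), with
  radial kernel U(r) = r^2 log r^2.  Captures local tissue distortions
  such as stretching and tears.

All points are (x, y) with x the column index and y the row index, origin
top-left.  Transforms carry domain/codomain frame names, compose, apply to
point sets and to images (backward warping with bilinear interpolation),
and serialize to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import TransformError

LANDMARK_COLUMNS = ["stage", "source_x", "source_y", "target_x", "target_y"]


# ---------------------------------------------------------------------------
# landmarks


@dataclass
class LandmarkSet:
    """Paired (source, target) 2-D points between two frames."""

    source: np.ndarray  # (n, 2)
    target: np.ndarray  # (n, 2)
    stage: str = "msi_data->visium"
    source_frame: str = "msi_native"
    target_frame: str = "fullres"

    def __post_init__(self):
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise TransformError("landmark source/target must both be (n, 2)")
        if len(self.source) < 3:
            raise TransformError(
                f"at least 3 landmark pairs are required, got {len(self.source)}"
            )
        if not (np.isfinite(self.source).all() and np.isfinite(self.target).all()):
            raise TransformError("landmark coordinates must be finite")
        if len(np.unique(self.source, axis=0)) != len(self.source):
            raise TransformError("duplicated source landmark")

    def __len__(self) -> int:
        return len(self.source)

    def subset(self, idx: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(
            self.source[idx],
            self.target[idx],
            stage=self.stage,
            source_frame=self.source_frame,
            target_frame=self.target_frame,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stage,
                "source_x": self.source[:, 0],
                "source_y": self.source[:, 1],
                "target_x": self.target[:, 0],
                "target_y": self.target[:, 1],
            }
        )


def read_landmarks(path: str | Path, stage: str | None = None) -> LandmarkSet:
    """Read a landmark CSV (columns stage,source_x,source_y,target_x,target_y)."""
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise TransformError(f"landmark table lacks columns {sorted(missing)}")
    if stage is not None:
        df = df[df["stage"] == stage]
        if df.empty:
            raise TransformError(f"no landmarks with stage {stage!r}")
    stages = df["stage"].unique()
    if len(stages) > 1:
        raise TransformError(
            f"landmark table mixes stages {list(stages)}; pass stage="
        )
    return LandmarkSet(
        df[["source_x", "source_y"]].to_numpy(),
        df[["target_x", "target_y"]].to_numpy(),
        stage=str(stages[0]),
    )


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    landmarks.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# transforms


class SpatialTransform:
    """Common interface: 2-D point map with named domain/codomain frames."""

    kind: str = ""
    domain_frame: str = ""
    codomain_frame: str = ""

    def apply(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points)

    def to_dict(self) -> dict:
        raise NotImplementedError

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


class AffineTransform2D(SpatialTransform):
    """Homogeneous 3x3 affine; bottom row (0, 0, 1); must be invertible."""

    kind = "affine"

    def __init__(
        self,
        matrix: np.ndarray,
        domain_frame: str = "msi_native",
        codomain_frame: str = "fullres",
    ):
        M = np.asarray(matrix, dtype=float)
        if M.shape != (3, 3) or not np.allclose(M[2], [0, 0, 1]):
            raise TransformError("affine matrix must be 3x3 with bottom row (0,0,1)")
        if abs(np.linalg.det(M[:2, :2])) < 1e-12:
            raise TransformError("affine matrix is singular")
        self.matrix = M
        self.domain_frame = domain_frame
        self.codomain_frame = codomain_frame

    @classmethod
    def identity(cls, frame: str = "fullres") -> "AffineTransform2D":
        return cls(np.eye(3), domain_frame=frame, codomain_frame=frame)

    @classmethod
    def from_scale(
        cls, s: float, domain_frame: str, codomain_frame: str
    ) -> "AffineTransform2D":
        return cls(np.diag([s, s, 1.0]), domain_frame, codomain_frame)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.column_stack([p, np.ones(len(p))])
        return (h @ self.matrix.T)[:, :2]

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(
            np.linalg.inv(self.matrix),
            domain_frame=self.codomain_frame,
            codomain_frame=self.domain_frame,
        )

    def to_dict(self) -> dict:
        return {
            "kind": "affine",
            "matrix": self.matrix.tolist(),
            "domain_frame": self.domain_frame,
            "codomain_frame": self.codomain_frame,
        }


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0 by continuity
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    out[r2 == 0] = 0.0
    return out


class TPSTransform(SpatialTransform):
    """Thin-plate spline warp through control points.

    With zero regularization (the default) the spline interpolates every
    control point exactly; a positive ``regularization`` relaxes this for
    noisy landmarks by adding lambda to the kernel diagonal.
    """

    kind = "tps"

    def __init__(
        self,
        control_points: np.ndarray,
        coefficients: np.ndarray,
        target_points: np.ndarray | None = None,
        regularization: float = 0.0,
        domain_frame: str = "msi_native",
        codomain_frame: str = "fullres",
    ):
        self.control_points = np.asarray(control_points, dtype=float)
        self.coefficients = np.asarray(coefficients, dtype=float)  # (n+3, 2)
        self.target_points = (
            None if target_points is None else np.asarray(target_points, dtype=float)
        )
        self.regularization = float(regularization)
        self.domain_frame = domain_frame
        self.codomain_frame = codomain_frame

    @classmethod
    def fit(
        cls,
        source: np.ndarray,
        target: np.ndarray,
        regularization: float = 0.0,
        domain_frame: str = "msi_native",
        codomain_frame: str = "fullres",
    ) -> "TPSTransform":
        src = np.asarray(source, dtype=float)
        tgt = np.asarray(target, dtype=float)
        n = len(src)
        if n < 4:
            raise TransformError(
                f"TPS needs at least 4 landmark pairs, got {n}"
            )
        if np.linalg.matrix_rank(src - src.mean(axis=0)) < 2:
            raise TransformError("TPS landmarks are collinear")
        d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
        K = _tps_kernel(d2) + regularization * np.eye(n)
        P = np.column_stack([np.ones(n), src])
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        rhs = np.zeros((n + 3, 2))
        rhs[:n] = tgt
        try:
            coef = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as e:
            raise TransformError(f"degenerate TPS system: {e}") from e
        return cls(
            src,
            coef,
            target_points=tgt,
            regularization=regularization,
            domain_frame=domain_frame,
            codomain_frame=codomain_frame,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(self.control_points)
        d2 = np.sum((p[:, None, :] - self.control_points[None, :, :]) ** 2, axis=-1)
        U = _tps_kernel(d2)
        w, a = self.coefficients[:n], self.coefficients[n:]
        return U @ w + a[0] + p @ a[1:]

    def inverse_approx(self) -> "TPSTransform":
        """TPS fitted on the swapped landmark pairs.

        An approximation to the true inverse (adequate for mild warps);
        used for backward image warping.
        """
        if self.target_points is None:
            raise TransformError("inverse requires stored target points")
        return TPSTransform.fit(
            self.target_points,
            self.control_points,
            regularization=self.regularization,
            domain_frame=self.codomain_frame,
            codomain_frame=self.domain_frame,
        )

    def to_dict(self) -> dict:
        return {
            "kind": "tps",
            "control_points": self.control_points.tolist(),
            "coefficients": self.coefficients.tolist(),
            "target_points": None
            if self.target_points is None
            else self.target_points.tolist(),
            "regularization": self.regularization,
            "domain_frame": self.domain_frame,
            "codomain_frame": self.codomain_frame,
        }


class ChainedTransform(SpatialTransform):
    """Sequential application of transforms (innermost first)."""

    kind = "chained"

    def __init__(self, steps: list[SpatialTransform]):
        if not steps:
            raise TransformError("empty transform chain")
        for inner, outer in zip(steps, steps[1:]):
            if inner.codomain_frame != outer.domain_frame:
                raise TransformError(
                    f"chain frame mismatch: {inner.codomain_frame!r} feeds "
                    f"{outer.domain_frame!r}"
                )
        self.steps = list(steps)
        self.domain_frame = steps[0].domain_frame
        self.codomain_frame = steps[-1].codomain_frame

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        for t in self.steps:
            p = t.apply(p)
        return p

    def inverse_approx(self) -> "ChainedTransform":
        inv = []
        for t in reversed(self.steps):
            inv.append(
                t.inverse() if isinstance(t, AffineTransform2D) else t.inverse_approx()
            )
        return ChainedTransform(inv)

    def to_dict(self) -> dict:
        return {"kind": "chained", "steps": [t.to_dict() for t in self.steps]}


def transform_from_dict(d: dict) -> SpatialTransform:
    kind = d.get("kind")
    if kind == "affine":
        return AffineTransform2D(
            np.asarray(d["matrix"]), d["domain_frame"], d["codomain_frame"]
        )
    if kind == "tps":
        return TPSTransform(
            np.asarray(d["control_points"]),
            np.asarray(d["coefficients"]),
            target_points=None
            if d.get("target_points") is None
            else np.asarray(d["target_points"]),
            regularization=d.get("regularization", 0.0),
            domain_frame=d["domain_frame"],
            codomain_frame=d["codomain_frame"],
        )
    if kind == "chained":
        return ChainedTransform([transform_from_dict(s) for s in d["steps"]])
    raise TransformError(f"unknown transform kind {kind!r}")


def load_transform(path: str | Path) -> SpatialTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# estimation / composition / application


def estimate_transform(
    landmarks: LandmarkSet, kind: str = "affine", regularization: float = 0.0
) -> SpatialTransform:
    """Fit an affine (least squares) or TPS (interpolating) transform.

    Affine needs >= 3 non-collinear pairs; TPS needs >= 4 not-all-collinear
    pairs.  Deterministic for fixed input.
    """
    src, tgt = landmarks.source, landmarks.target
    if kind == "affine":
        if np.linalg.matrix_rank(src - src.mean(axis=0)) < 2:
            raise TransformError("affine landmarks are collinear")
        X = np.column_stack([src, np.ones(len(src))])
        params, *_ = np.linalg.lstsq(X, tgt, rcond=None)
        M = np.eye(3)
        M[:2, :2] = params[:2].T
        M[:2, 2] = params[2]
        return AffineTransform2D(
            M,
            domain_frame=landmarks.source_frame,
            codomain_frame=landmarks.target_frame,
        )
    if kind == "tps":
        return TPSTransform.fit(
            src,
            tgt,
            regularization=regularization,
            domain_frame=landmarks.source_frame,
            codomain_frame=landmarks.target_frame,
        )
    raise TransformError(f"unknown transform kind {kind!r}")


def apply_transform(t: SpatialTransform, points: np.ndarray) -> np.ndarray:
    """Map (n, 2) points through ``t``; element-wise, order-preserving."""
    return t.apply(points)


def compose(outer: SpatialTransform, inner: SpatialTransform) -> SpatialTransform:
    """outer after inner.  Affine pairs collapse to one affine matrix;
    anything involving a TPS becomes a chained applicator."""
    if inner.codomain_frame != outer.domain_frame:
        raise TransformError(
            f"cannot compose: inner codomain {inner.codomain_frame!r} != "
            f"outer domain {outer.domain_frame!r}"
        )
    if isinstance(outer, AffineTransform2D) and isinstance(inner, AffineTransform2D):
        return AffineTransform2D(
            outer.matrix @ inner.matrix,
            domain_frame=inner.domain_frame,
            codomain_frame=outer.codomain_frame,
        )
    inner_steps = inner.steps if isinstance(inner, ChainedTransform) else [inner]
    outer_steps = outer.steps if isinstance(outer, ChainedTransform) else [outer]
    return ChainedTransform(inner_steps + outer_steps)


def _invert(t: SpatialTransform) -> SpatialTransform:
    if isinstance(t, AffineTransform2D):
        return t.inverse()
    return t.inverse_approx()


def transform_image(
    img: np.ndarray,
    t: SpatialTransform,
    target_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Warp ``img`` into the target frame by backward mapping.

    For every target cell the inverse of ``t`` gives the source location,
    sampled with bilinear interpolation; cells falling outside the source
    raster are filled with 0 and flagged False in the returned mask.

    Returns (warped raster of ``target_shape`` (+channels), valid mask).
    """
    img = np.asarray(img, dtype=float)
    H, W = target_shape
    inv = _invert(t)
    cols, rows = np.meshgrid(np.arange(W), np.arange(H))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    src = inv.apply(pts)  # (x, y) in source frame
    sx, sy = src[:, 0], src[:, 1]
    valid = (
        (sx >= 0) & (sx <= img.shape[1] - 1) & (sy >= 0) & (sy <= img.shape[0] - 1)
    ).reshape(H, W)
    coords = np.stack([sy, sx])  # map_coordinates wants (row, col)
    if img.ndim == 2:
        out = ndimage.map_coordinates(img, coords, order=1, cval=0.0).reshape(H, W)
    else:
        out = np.stack(
            [
                ndimage.map_coordinates(img[..., c], coords, order=1, cval=0.0).reshape(
                    H, W
                )
                for c in range(img.shape[-1])
            ],
            axis=-1,
        )
    out[~valid] = 0.0
    return out, valid
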