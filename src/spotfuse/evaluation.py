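"""Score co-registration quality and benchmark landmark requirements.

The alignment score is spot-level label agreement: each modality labels
every Visium barcode tissue or background (Visium from its own
tissue-detection flag, MSI by majority vote of the transformed pixels
assigned to the spot), and

    accuracy = (# spots tissue in both + # spots background in both) / # spots.

The benchmark re-fits the transform on random landmark subsets of sizes
k (e.g. 4..20, 5 repeats each), for affine/TPS and direct/two-stage
registration, recording the accuracy per cell — quantifying how many
landmarks are enough and when the non-linear warp pays off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import SpotPixelMapping
from .errors import SpotfuseError, TransformError
from .registration import LandmarkSet, SpatialTransform, compose, estimate_transform

logger = logging.getLogger(__name__)

MIN_LANDMARKS = {"affine": 3, "tps": 4}


@dataclass
class AlignmentReport:
    """Tissue/background overlap between modalities at spot level."""

    accuracy: float
    n_spots: int
    counts: dict  # tissue_tissue, background_background, tissue_background, background_tissue
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_spots": self.n_spots,
            "counts": self.counts,
            "settings": self.settings,
        }


def _as_bool_labels(labels) -> pd.Series:
    s = pd.Series(labels)
    if s.dtype == object:
        bad = set(s.unique()) - {"tissue", "background"}
        if bad:
            raise SpotfuseError(f"unknown labels {sorted(bad)}")
        s = s == "tissue"
    return s.astype(bool)


def alignment_accuracy(
    visium_labels, msi_spot_labels, settings: dict | None = None
) -> AlignmentReport:
    """Label-agreement score over a shared barcode set.

    Both arguments map barcode -> label, as dict/Series of booleans
    (True = tissue) or of the strings "tissue"/"background".  Barcode sets
    must match exactly.
    """
    v = _as_bool_labels(visium_labels)
    m = _as_bool_labels(msi_spot_labels)
    if set(v.index) != set(m.index):
        raise SpotfuseError("barcode sets differ between the two label vectors")
    m = m.loc[v.index]
    tt = int((v & m).sum())
    bb = int((~v & ~m).sum())
    tb = int((v & ~m).sum())
    bt = int((~v & m).sum())
    n = len(v)
    return AlignmentReport(
        accuracy=(tt + bb) / n,
        n_spots=n,
        counts={
            "tissue_tissue": tt,
            "background_background": bb,
            "tissue_background": tb,
            "background_tissue": bt,
        },
        settings=settings or {},
    )


def msi_labels_per_spot(
    mapping: SpotPixelMapping, pixel_is_tissue: np.ndarray
) -> pd.Series:
    """Majority-vote spot labels from assigned pixel labels.

    Ties count as tissue; spots with no assigned pixels are background.
    Returns a boolean Series indexed by barcode (True = tissue).
    """
    pixel_is_tissue = np.asarray(pixel_is_tissue, dtype=bool)
    n_spots = len(mapping.barcodes)
    votes_tissue = np.bincount(
        mapping.barcode_index,
        weights=pixel_is_tissue[mapping.pixel_index].astype(float),
        minlength=n_spots,
    )
    votes_total = np.bincount(mapping.barcode_index, minlength=n_spots)
    labels = np.zeros(n_spots, dtype=bool)
    has = votes_total > 0
    labels[has] = votes_tissue[has] >= votes_total[has] / 2.0
    return pd.Series(labels, index=pd.Index(mapping.barcodes, name="barcode"))


def _cell_rng(seed: int, k: int, repeat: int) -> np.random.Generator:
    # independent, reproducible stream per benchmark cell
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(k), int(repeat)]))


def _fit_stage(
    pool, kind: str, rng: np.random.Generator, k: int
) -> SpatialTransform:
    if isinstance(pool, LandmarkSet):
        idx = rng.choice(len(pool), size=k, replace=False)
        return estimate_transform(pool.subset(idx), kind)
    # two-stage: pair of pools (source->intermediate, intermediate->target)
    first, second = pool
    t1 = _fit_stage(first, kind, rng, k)
    t2 = _fit_stage(second, kind, rng, k)
    return compose(t2, t1)


def landmark_benchmark(
    pool,
    k_range,
    repeats: int,
    seed: int,
    kinds=("affine", "tps"),
    stages=("direct",),
    scorer=None,
    sample: str = "sample",
) -> pd.DataFrame:
    """Full-factorial landmark-subsampling study.

    Parameters
    ----------
    pool
        A :class:`LandmarkSet` (used for every stage named "direct"), or a
        mapping stage name -> pool, where a two-stage entry
        ("intermediate") is a pair of LandmarkSets for the two hops.
    k_range
        Landmark counts to test, e.g. ``range(4, 21)``.
    repeats
        Random subsets per k.
    seed
        Base seed; each (k, repeat) cell gets its own derived stream, so
        cells are individually reproducible and the table is bit-identical
        across runs.
    scorer
        Callable ``scorer(transform) -> AlignmentReport`` closing over the
        datasets (register, aggregate, label, score).
    kinds, stages
        Transform families and registration routes to cross.

    Returns a tidy DataFrame with one row per
    (kind, stage, k, repeat): accuracy, the four label-agreement counts,
    and ``failed`` for cells where k is below the transform's minimum.
    """
    if scorer is None:
        raise ValueError("scorer callable is required")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    pools = pool if isinstance(pool, dict) else {"direct": pool}
    for stage in stages:
        if stage not in pools:
            raise ValueError(f"no landmark pool for stage {stage!r}")

    def pool_size(p):
        return len(p) if isinstance(p, LandmarkSet) else min(len(q) for q in p)

    rows = []
    for kind in kinds:
        for stage in stages:
            p = pools[stage]
            n_pool = pool_size(p)
            for k in k_range:
                if k > n_pool:
                    raise ValueError(
                        f"k={k} exceeds the landmark pool size {n_pool}"
                    )
                for rep in range(repeats):
                    rng = _cell_rng(seed, k, rep)
                    base = {
                        "sample": sample,
                        "kind": kind,
                        "stage": stage,
                        "k": k,
                        "repeat": rep,
                    }
                    if k < MIN_LANDMARKS[kind]:
                        rows.append(
                            {**base, "accuracy": np.nan, "failed": True}
                        )
                        continue
                    try:
                        t = _fit_stage(p, kind, rng, k)
                        report = scorer(t)
                    except TransformError as e:
                        logger.warning("cell %s failed: %s", base, e)
                        rows.append({**base, "accuracy": np.nan, "failed": True})
                        continue
                    c = report.counts
                    rows.append(
                        {
                            **base,
                            "accuracy": report.accuracy,
                            "tt": c["tissue_tissue"],
                            "bb": c["background_background"],
                            "tb": c["tissue_background"],
                            "bt": c["background_tissue"],
                            "failed": False,
                        }
                    )
    df = pd.DataFrame(rows)
    df["failed"] = df["failed"].astype(bool)
    return df


def best_accuracy_per_sample(table: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, kind, stage) maximum accuracy over all k and repeats."""
    ok = table[~table["failed"]]
    return (
        ok.groupby(["sample", "kind", "stage"], as_index=False)["accuracy"]
        .max()
        .rename(columns={"accuracy": "best_accuracy"})
    )


def plot_accuracy_vs_k(table: pd.DataFrame, path=None):
    """Mean accuracy vs number of landmarks (error bars = standard error)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ok = table[~table["failed"]]
    for (kind, stage), grp in ok.groupby(["kind", "stage"]):
        stats = grp.groupby("k")["accuracy"].agg(["mean", "sem"])
        ax.errorbar(
            stats.index,
            stats["mean"],
            yerr=stats["sem"],
            marker="o",
            capsize=2,
            label=f"{kind} / {stage}",
        )
    ax.set_xlabel("number of landmarks")
    ax.set_ylabel("alignment accuracy")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
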