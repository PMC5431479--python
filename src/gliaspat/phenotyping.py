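"""Phenotype clustering of microglia by soma area and roundness.

All cells are pooled across retinas, each feature is 90%-winsorized
(values outside the 5th–95th percentile clipped to those quantiles) and
z-scored, and the pooled population is split into two clusters by
Hartigan–Wong k-means. The cluster whose cells have the larger mean soma
area is labelled "high" activity — enlarged, less round somata are the
classic morphological signature of microglial reactivity — and the other
"low"; labels never depend on cluster index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import MARK_HIGH, MARK_LOW

FEATURES = ("area_um2", "roundness")


def winsorize_90(values, lower_pct: float = 5.0, upper_pct: float = 95.0):
    """Clip values below the 5th percentile up to it and above the 95th
    down to it, retaining the central 90% unchanged; order is preserved.

    Quantiles use linear interpolation (numpy default, R type 7).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    lo, hi = np.percentile(arr, [lower_pct, upper_pct])
    return np.clip(arr, lo, hi)


def _hartigan_wong_two(
    X: np.ndarray, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Hartigan–Wong run with k=2 from a random two-row start.

    Lloyd passes to a stable partition, then the HW transfer stage: move a
    single point between clusters whenever the size-corrected cost
    n₁/(n₁−1)·d₁² > n₂/(n₂+1)·d₂² — the exact SSE change for a single-point
    transfer — until no move improves. Returns (labels, centres, sse).
    """
    n = len(X)
    idx = rng.choice(n, size=2, replace=False)
    centres = X[idx].copy()
    if np.allclose(centres[0], centres[1]):  # retry distinct rows
        uniq = np.unique(X, axis=0)
        centres = uniq[rng.choice(len(uniq), size=2, replace=False)].copy()

    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):  # Lloyd
        d = ((X[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
        new = d.argmin(1)
        if (new == labels).all() and _ > 0:
            break
        labels = new
        for c in (0, 1):
            if (labels == c).any():
                centres[c] = X[labels == c].mean(0)

    # Hartigan–Wong transfer stage
    counts = np.bincount(labels, minlength=2).astype(float)
    sums = np.vstack([X[labels == c].sum(0) for c in (0, 1)])
    for _ in range(max_iter):
        moved = False
        for i in range(n):
            src = labels[i]
            dst = 1 - src
            if counts[src] <= 1:
                continue
            c_src = sums[src] / counts[src]
            gain = (counts[src] / (counts[src] - 1)) * ((X[i] - c_src) ** 2).sum()
            if counts[dst] == 0:
                cost = 0.0
            else:
                c_dst = sums[dst] / counts[dst]
                cost = (counts[dst] / (counts[dst] + 1)) * ((X[i] - c_dst) ** 2).sum()
            if cost < gain - 1e-12:
                sums[src] -= X[i]
                sums[dst] += X[i]
                counts[src] -= 1
                counts[dst] += 1
                labels[i] = dst
                moved = True
        if not moved:
            break
    centres = sums / counts[:, None]
    d = ((X - centres[labels]) ** 2).sum()
    return labels, centres, float(d)


@dataclass
class ClusterModel:
    """Fitted two-cluster phenotype model.

    ``labels`` holds "low"/"high" per cell (input row order preserved);
    ``centres_norm`` are the two cluster centres in the normalized
    (winsorized, z-scored) feature space, row 0 = low, row 1 = high.
    """

    labels: np.ndarray
    centres_norm: np.ndarray
    sse: float
    feature_names: tuple[str, ...] = FEATURES
    normalization: str = "zscore"
    mapping_rule: str = "larger mean soma area -> high"
    scaler: dict = field(default_factory=dict)

    @property
    def n_high(self) -> int:
        return int((self.labels == MARK_HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == MARK_LOW).sum())


def normalize_features(
    features: pd.DataFrame, normalization: str = "zscore"
) -> tuple[np.ndarray, dict]:
    """Winsorize each pooled feature to its central 90% and normalize
    (z-score by default; "minmax" alternative). Returns the normalized
    matrix and the scaler record."""
    X = np.column_stack([winsorize_90(features[c].to_numpy()) for c in FEATURES])
    if normalization == "zscore":
        mu, sd = X.mean(0), X.std(0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("a feature is constant after winsorizing")
        Xn = (X - mu) / sd
        scaler = {"kind": "zscore", "mean": mu.tolist(), "sd": sd.tolist()}
    elif normalization == "minmax":
        lo, hi = X.min(0), X.max(0)
        if np.any(hi == lo):
            raise ValueError("a feature is constant after winsorizing")
        Xn = (X - lo) / (hi - lo)
        scaler = {"kind": "minmax", "min": lo.tolist(), "max": hi.tolist()}
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return Xn, scaler


def kmeans_two(
    features: pd.DataFrame,
    seed: int = 0,
    n_starts: int = 10,
    normalization: str = "zscore",
) -> ClusterModel:
    """Split pooled cells into 'low'/'high' activity by k=2 Hartigan–Wong
    k-means on winsorized, normalized (soma area, roundness).

    ``features`` needs columns ``area_um2`` and ``roundness``; rows are
    cells pooled across all retinas. The best of ``n_starts`` seeded runs
    (by within-cluster SSE) is kept.
    """
    for c in FEATURES:
        if c not in features:
            raise ValueError(f"missing feature column {c!r}")
    if features[list(FEATURES)].isna().any().any():
        raise ValueError("features contain missing values")
    Xn, scaler = normalize_features(features, normalization)
    if len(np.unique(Xn, axis=0)) < 2:
        raise ValueError("all rows identical after normalization")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        labels, centres, sse = _hartigan_wong_two(Xn, rng)
        if best is None or sse < best[2]:
            best = (labels, centres, sse)
    labels_idx, centres, sse = best

    # map cluster index -> activity label by mean soma area (normalized
    # winsorized scale keeps the ordering of the raw areas)
    area_col = FEATURES.index("area_um2")
    mean_area = [Xn[labels_idx == c, area_col].mean() for c in (0, 1)]
    high_cluster = int(np.argmax(mean_area))
    labels = np.where(labels_idx == high_cluster, MARK_HIGH, MARK_LOW).astype(object)
    ordered_centres = centres[[1 - high_cluster, high_cluster]]
    return ClusterModel(
        labels=labels,
        centres_norm=ordered_centres,
        sse=sse,
        normalization=normalization,
        scaler=scaler,
    )


def cluster_densities(
    labels: np.ndarray,
    retina_ids: np.ndarray,
    retina_areas_mm2: dict[str, float],
) -> pd.DataFrame:
    """Per-retina counts, densities (cells/mm²) and percentage split of the
    two activity phenotypes.

    Every retina in ``retina_areas_mm2`` gets a row; a retina with no cells
    yields a zero row with a warning. Percentages sum to 100 per retina.
    """
    labels = np.asarray(labels, dtype=object)
    retina_ids = np.asarray(retina_ids, dtype=object)
    if len(labels) != len(retina_ids):
        raise ValueError("labels and retina_ids must align")
    rows = []
    for rid, area in retina_areas_mm2.items():
        if area <= 0:
            raise ValueError(f"retina {rid!r} has non-positive area")
        sel = retina_ids == rid
        n_low = int((labels[sel] == MARK_LOW).sum())
        n_high = int((labels[sel] == MARK_HIGH).sum())
        total = n_low + n_high
        if total == 0:
            warnings.warn(f"retina {rid!r} has zero cells", stacklevel=2)
            pct_low = pct_high = 0.0
        else:
            pct_low = 100.0 * n_low / total
            pct_high = 100.0 * n_high / total
        rows.append(
            {
                "retina_id": rid,
                "n_low": n_low,
                "n_high": n_high,
                "density_low_per_mm2": n_low / area,
                "density_high_per_mm2": n_high / area,
                "pct_low": pct_low,
                "pct_high": pct_high,
            }
        )
    return pd.DataFrame(rows)


def activity_colour_map(pattern, ax=None, point_size: float = 8.0):
    """Centroid scatter inside the retinal boundary, black for 'low'
    activity cells and red for 'high' activity cells."""
    import matplotlib.pyplot as plt

    if pattern.marks is None:
        raise ValueError("pattern has no activity labels")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    colour = {MARK_LOW: "black", MARK_HIGH: "red"}
    for mark in (MARK_LOW, MARK_HIGH):
        sel = pattern.marks == mark
        ax.scatter(pattern.points[sel, 0], pattern.points[sel, 1],
                   c=colour[mark], s=point_size, linewidths=0, label=mark)
    bx, by = pattern.window.exterior.xy
    ax.plot(bx, by, color="k", lw=0.8)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.legend(frameon=False)
    ax.set_title(f"activity map — {pattern.retina_id}")
    return ax
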