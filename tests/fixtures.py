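"""Programmatic test fixtures shared between unit and acceptance tests."""

import numpy as np

from gliaspat.patterns import PointPattern, rectangle_window
from gliaspat.synthgen import (
    SomaSpec,
    SynthImageParams,
    SynthPatternParams,
    render_image,
    simulate_pattern,
)


def rendered_fixture(n=50, seed=0, noise_sd=5.0, n_fragments=0,
                     pixel_size=1.24, semi_major_px=(12.0, 18.0)):
    """A rendered image of exactly ``n`` well-separated elliptical somata
    with known centroids/areas/roundness.

    Placement uses a hard-core pattern whose radius exceeds twice the
    largest soma radius, so components never merge and the ground-truth
    count is recoverable; somata are drawn at semi-major 12–18 px, the
    regime where the discretized second-moment ellipse fit resolves
    roundness to better than 0.05. Segmenting this fixture should use a
    particle gate scaled accordingly (~30 px, mirroring the published
    10 px gate at the published ~40 px soma scale).
    """
    canvas_px = 900
    side_um = canvas_px * pixel_size
    margin = (semi_major_px[1] + 2) * pixel_size
    win = rectangle_window(side_um, side_um)
    hard_r = 2 * semi_major_px[1] * pixel_size + 5 * pixel_size
    sat = 1.0 / (np.pi * (hard_r / 1000.0) ** 2)  # per mm²
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pat = simulate_pattern(
            SynthPatternParams(window=win, process="hardcore",
                               intensity=3 * sat, hardcore_radius=hard_r,
                               seed=seed))
    inner = np.all((pat.points > margin) & (pat.points < side_um - margin),
                   axis=1)
    pts = pat.points[inner]
    if len(pts) < n:
        raise RuntimeError("fixture could not place enough somata")
    pat = PointPattern(pts[:n], win)

    rng = np.random.default_rng(seed + 1)
    a = rng.uniform(*semi_major_px, n)
    b = a * rng.uniform(0.55, 1.0, n)
    theta = rng.uniform(0, np.pi, n)
    specs = [SomaSpec(a[i], b[i], theta[i], int(rng.integers(170, 240)))
             for i in range(n)]
    img, truth = render_image(
        pat,
        SynthImageParams(shape_px=(canvas_px, canvas_px),
                         pixel_size_um=pixel_size, noise_sd=noise_sd,
                         n_process_fragments=n_fragments, seed=seed),
        soma_specs=specs,
    )
    return img, truth, pat


def gaussian_mixture_features(n_per_cluster=2000, seed=0):
    """Two-phenotype soma-feature mixture at the reported group scales:
    'low' areas ~N(53.1, 8²) μm² with roundness ~N(0.181, 0.03²), 'high'
    areas ~N(74.3, 10²) with roundness ~N(0.160, 0.03²)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = n_per_cluster
    frame = pd.DataFrame(
        {
            "area_um2": np.r_[rng.normal(53.1, 8, n), rng.normal(74.3, 10, n)],
            "roundness": np.r_[rng.normal(0.181, 0.03, n),
                               rng.normal(0.160, 0.03, n)],
        }
    )
    truth = np.r_[np.full(n, "low"), np.full(n, "high")].astype(object)
    return frame, truth
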