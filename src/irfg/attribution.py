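"""Shapley-style spectral attribution for individual predictions.

For one class of one spectrum, the grid is partitioned into contiguous
segments (default 50 cm^-1 wide) and each segment's Shapley value with
respect to the model's class probability is estimated by permutation
sampling: segments are revealed in random order on top of an all-zero
baseline spectrum (the post-normalization "no absorbance" state) and the
marginal change in the class output is credited to the revealed segment.
Positive values push the model toward predicting presence, negative toward
absence.

By construction each sampled permutation's marginals telescope to
``f(x) - f(baseline)``, so the estimator satisfies the completeness
(efficiency) property up to floating-point error; the residual is recorded
on the map. Segment values are spread uniformly over the grid points of the
segment to give a per-wavenumber importance curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Spectrum
from .split_net import SplitNet

__all__ = ["AttributionMap", "attribute", "segment_bounds", "positive_mass_in_window"]


@dataclass
class AttributionMap:
    """Per-wavenumber importance for one class of one spectrum."""

    class_index: int
    importance: np.ndarray  # per grid point; sums (over points) to the segment values
    segment_values: np.ndarray  # Shapley value per segment
    segment_edges: np.ndarray  # wavenumber edges, length n_segments + 1
    baseline_value: float  # model output on the all-zero spectrum
    prediction: float  # model output on the full spectrum
    n_permutations: int
    segment_width: float
    residual: float  # |sum(segment_values) - (prediction - baseline_value)|
    degenerate: bool = False  # model output insensitive to the input


def segment_bounds(grid: np.ndarray, segment_width: float) -> np.ndarray:
    """Index boundaries of contiguous ``segment_width``-wide grid chunks."""
    if segment_width <= 0:
        raise ValueError("segment width must be positive")
    edges = np.arange(grid[0], grid[-1] + segment_width, segment_width)
    edges[-1] = max(edges[-1], grid[-1] + 1e-9)
    idx = np.searchsorted(grid, edges)
    idx[-1] = grid.size
    return np.unique(idx)


def attribute(
    net: SplitNet,
    spectrum: Spectrum,
    class_index: int,
    segment_width: float = 50.0,
    n_permutations: int = 200,
    seed: int = 0,
) -> AttributionMap:
    """Sampling-based Shapley attribution of one class probability.

    Deterministic given ``seed`` and ``n_permutations``. A model whose
    output barely responds to the spectrum (e.g. untrained) yields a map
    flagged ``degenerate`` rather than an error.
    """
    if not (0 <= class_index < net.config.n_outputs):
        raise ValueError(f"class index {class_index} out of range")
    grid = spectrum.grid
    if grid.size != net.grid.size:
        raise ValueError("spectrum grid does not match the model grid")
    x = spectrum.intensities.astype(np.float32)
    bounds = segment_bounds(grid, segment_width)
    starts, stops = bounds[:-1], bounds[1:]
    n_seg = starts.size

    baseline = float(net.forward(np.zeros_like(x))[class_index])
    full = float(net.forward(x)[class_index])

    rng = np.random.default_rng(seed)
    totals = np.zeros(n_seg)
    batch = np.zeros((n_seg + 1, x.size), dtype=np.float32)
    for _ in range(n_permutations):
        order = rng.permutation(n_seg)
        batch[:] = 0.0
        for step, seg in enumerate(order):
            batch[step + 1] = batch[step]
            batch[step + 1, starts[seg] : stops[seg]] = x[starts[seg] : stops[seg]]
        f = net.forward(batch)[:, class_index]
        totals[order] += np.diff(f)
    phi = totals / n_permutations

    importance = np.zeros(grid.size)
    for seg in range(n_seg):
        width = stops[seg] - starts[seg]
        importance[starts[seg] : stops[seg]] = phi[seg] / width
    residual = abs(phi.sum() - (full - baseline))
    return AttributionMap(
        class_index=class_index,
        importance=importance,
        segment_values=phi,
        segment_edges=grid[np.minimum(bounds, grid.size - 1)],
        baseline_value=baseline,
        prediction=full,
        n_permutations=n_permutations,
        segment_width=segment_width,
        residual=float(residual),
        degenerate=abs(full - baseline) < 1e-6,
    )


def positive_mass_in_window(
    amap: AttributionMap, grid: np.ndarray, lo: float, hi: float
) -> float:
    """Fraction of total positive segment mass in segments overlapping [lo, hi]."""
    pos = np.clip(amap.segment_values, 0.0, None)
    if pos.sum() == 0:
        return 0.0
    edges = amap.segment_edges
    seg_lo, seg_hi = edges[:-1], edges[1:]
    overlap = (seg_hi >= lo) & (seg_lo <= hi)
    return float(pos[overlap].sum() / pos.sum())


def plot_attribution(amap: AttributionMap, spectrum: Spectrum, path=None, ax=None):
    """Render the spectrum colored by attribution sign (red toward presence,
    blue toward absence). Matplotlib is imported lazily."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    g = spectrum.grid
    ax.plot(g, spectrum.intensities, color="0.4", lw=0.7)
    ax.fill_between(
        g, 0, spectrum.intensities, where=amap.importance > 0,
        color="red", alpha=0.4, label="toward presence",
    )
    ax.fill_between(
        g, 0, spectrum.intensities, where=amap.importance < 0,
        color="blue", alpha=0.4, label="toward absence",
    )
    ax.set_xlabel("wavenumber / cm$^{-1}$")
    ax.set_ylabel("normalized absorbance")
    ax.invert_xaxis()
    ax.legend(loc="upper left", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
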