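"""Pair correlation functions g(r) for 3D nuclear point patterns.

g(r) is the observed density of point pairs at separation r divided by the
density expected under a homogeneous Poisson process of the same intensity;
g = 1 indicates complete spatial randomness, g < 1 depletion (e.g. a
hard core), g > 1 clustering.  The study region is the convex hull of the
points and edge effects are handled by minus-sampling: only reference
points further than r from the hull boundary contribute to the count at
radius r.  An auto mode (pairs within one set) and a cross mode (reference
set A against counted set B) are provided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

logger = logging.getLogger(__name__)


@dataclass
class PairCorrelation:
    """Binned pair correlation estimate."""

    bin_edges: np.ndarray  # µm, length n_bins + 1
    g: np.ndarray  # dimensionless, per bin
    pair_counts: np.ndarray  # integer pair counts per bin
    reference_counts: np.ndarray  # eroded reference-set size per bin
    intensity: float  # counted-set intensity, points/µm^3
    region_volume: float  # convex hull volume, µm^3

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _hull_depth(points, hull: ConvexHull) -> np.ndarray:
    """Distance of interior points to the hull boundary (min over facets)."""
    eq = hull.equations  # n . x + b <= 0 inside
    return -(points @ eq[:, :3].T + eq[:, 3]).max(axis=1)


def pair_correlation(points_a, points_b=None, r_max: float = 50.0,
                     dr: float = 2.0, edge_correction: str = "minus",
                     min_points: int = 100) -> PairCorrelation:
    """Estimate g(r) with contiguous bins (0, dr], (dr, 2dr], … up to r_max.

    Auto mode (``points_b`` omitted): pairs within ``points_a``, self pairs
    excluded.  Cross mode: reference points from A, counted points from B.
    ``edge_correction`` is "minus" (default; reference points eroded by the
    bin's outer radius) or "none".
    """
    a = np.asarray(points_a, dtype=float)
    if len(a) < min_points:
        raise ValueError(f"need at least {min_points} reference points")
    auto = points_b is None
    b = a if auto else np.asarray(points_b, dtype=float)
    if r_max <= 0 or dr <= 0:
        raise ValueError("r_max and dr must be positive")

    hull_a = ConvexHull(a)
    span = a.max(axis=0) - a.min(axis=0)
    if r_max >= np.linalg.norm(span) / 2.0:
        raise ValueError(
            f"r_max={r_max} too large for the study region; choose below "
            f"{np.linalg.norm(span) / 2.0:.1f} µm")
    hull_b = hull_a if auto else ConvexHull(b)
    intensity = len(b) / hull_b.volume

    edges = np.arange(0.0, r_max + dr / 2.0, dr)
    if edges[-1] < r_max:
        edges = np.append(edges, r_max)
    n_bins = len(edges) - 1

    depth = _hull_depth(a, hull_a)
    tree_b = cKDTree(b)
    g = np.empty(n_bins)
    counts = np.empty(n_bins, dtype=np.int64)
    ref_counts = np.empty(n_bins, dtype=np.int64)
    for k in range(n_bins):
        r_lo, r_hi = edges[k], edges[k + 1]
        refs = a[depth >= r_hi] if edge_correction == "minus" else a
        if len(refs) == 0:
            raise ValueError(
                f"no reference points remain after eroding by {r_hi} µm; "
                f"reduce r_max below {np.quantile(depth, 0.99):.1f} µm")
        ref_tree = cKDTree(refs)
        c_hi = ref_tree.count_neighbors(tree_b, r_hi)
        c_lo = ref_tree.count_neighbors(tree_b, r_lo)
        # bins are (r_lo, r_hi]; in auto mode the self pairs sit at distance
        # zero and are already contained in both cumulative counts
        pairs = c_hi - c_lo
        shell = 4.0 / 3.0 * np.pi * (r_hi ** 3 - r_lo ** 3)
        g[k] = pairs / (len(refs) * intensity * shell)
        counts[k] = pairs
        ref_counts[k] = len(refs)
    return PairCorrelation(
        bin_edges=edges, g=g, pair_counts=counts,
        reference_counts=ref_counts, intensity=float(intensity),
        region_volume=float(hull_a.volume))
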