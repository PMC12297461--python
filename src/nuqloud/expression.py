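"""Per-nucleus fluorescence quantification and expressing/non-expressing calls.

Two extraction strategies mirror common signal types: nuclear signals are
averaged in a dilated spherical region around each centroid; cytosolic or
punctate signals (e.g. HCR RNA FISH) are integrated over each nucleus'
Voronoi cell.  The resulting intensity distribution is decomposed into a
two-component Gaussian mixture; the lower-mean component is noise, the
higher-mean component signal, and a nucleus is called expressing when its
posterior probability of the signal component exceeds 0.5.  Otsu's method
(256-bin histogram) and min–max line-profile normalisation are provided for
the thresholding workflows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

from . import geometry

logger = logging.getLogger(__name__)


@dataclass
class ChannelCall:
    """Expression call for one nucleus in one channel."""

    nucleus_id: object
    raw_intensity: float
    noise_component: tuple  # (mean, sd)
    signal_component: tuple  # (mean, sd)
    posterior_signal: float
    expressing: bool


@dataclass
class SignalNoiseFit:
    """Two-Gaussian decomposition of an intensity distribution."""

    intensities: np.ndarray
    noise_mean: float
    noise_sd: float
    signal_mean: float
    signal_sd: float
    noise_weight: float
    signal_weight: float
    posterior_signal: np.ndarray
    expressing: np.ndarray
    degenerate: bool = False

    def calls(self, nucleus_ids=None) -> list:
        ids = nucleus_ids if nucleus_ids is not None \
            else np.arange(len(self.intensities))
        return [
            ChannelCall(
                nucleus_id=ids[i],
                raw_intensity=float(self.intensities[i]),
                noise_component=(self.noise_mean, self.noise_sd),
                signal_component=(self.signal_mean, self.signal_sd),
                posterior_signal=float(self.posterior_signal[i]),
                expressing=bool(self.expressing[i]),
            )
            for i in range(len(self.intensities))
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "raw_intensity": self.intensities,
            "posterior_signal": self.posterior_signal,
            "expressing": self.expressing,
        })


def nuclear_intensity(volume, centroids, nuclear_radius: float,
                      dilation: float = 2.0, voxel_size: float = 1.0):
    """Mean voxel intensity in a dilated sphere around each centroid.

    The sampling region is a sphere of radius ``dilation * nuclear_radius``
    clipped to the volume bounds; centroids outside the volume yield NaN
    (flagged missing, not zero).
    """
    if nuclear_radius <= 0:
        raise ValueError("nuclear_radius must be positive")
    vol = np.asarray(volume)
    pts = np.asarray(centroids, dtype=float) / voxel_size
    r = dilation * nuclear_radius / voxel_size
    out = np.full(len(pts), np.nan)
    shape = np.array(vol.shape)
    for i, p in enumerate(pts):
        if np.any(p < 0) or np.any(p > shape - 1):
            continue
        lo = np.maximum(np.floor(p - r).astype(int), 0)
        hi = np.minimum(np.ceil(p + r).astype(int) + 1, shape)
        zz, yy, xx = np.meshgrid(*[np.arange(l, h)
                                   for l, h in zip(lo, hi)], indexing="ij")
        mask = ((zz - p[0]) ** 2 + (yy - p[1]) ** 2
                + (xx - p[2]) ** 2) <= r ** 2
        if mask.any():
            out[i] = vol[zz, yy, xx][mask].mean()
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.warning("%d centroids outside the volume (intensity NaN)",
                       n_missing)
    return out


def voronoi_intensity(volume, tessellation: geometry.Tessellation,
                      voxel_size: float = 1.0):
    """Integrated voxel intensity per Voronoi cell.

    A voxel belongs to cell i iff its centre's nearest seed (including
    auxiliary seeds) is i and it lies inside i's bounding dodecahedron, so
    every in-bounds voxel contributes to at most one cell and total
    intensity is conserved: ``sums.sum() + unassigned == volume.sum()``.

    Returns ``(per_cell_sums, unassigned_total)``.
    """
    vol = np.asarray(volume, dtype=float)
    seeds = tessellation.points
    aux = tessellation.auxiliary_points
    all_seeds = np.vstack([seeds, aux]) if len(aux) else seeds
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in vol.shape],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    coords = grid * voxel_size
    tree = cKDTree(all_seeds)
    _, owner = tree.query(coords)
    normals, support = geometry.dodecahedron_halfspaces(
        tessellation.bounding_edge_length)
    rel = coords - all_seeds[owner]
    inside = (rel @ normals.T <= support).all(axis=1)
    real = owner < len(seeds)
    ok = inside & real
    sums = np.bincount(owner[ok], weights=vol.reshape(-1)[ok],
                       minlength=len(seeds))[:len(seeds)]
    unassigned = float(vol.reshape(-1)[~ok].sum())
    return sums, unassigned


def fit_signal_noise(intensities, seed: int = 0,
                     degenerate_sep: float = 0.1) -> SignalNoiseFit:
    """Two-component 1D Gaussian mixture fit of an intensity distribution.

    EM with deterministic k-means initialisation; components are ordered by
    mean (lower = noise).  If the two means are closer than
    ``degenerate_sep`` pooled standard deviations the fit is flagged
    degenerate and every nucleus is called non-expressing.
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 intensity values")
    if not np.isfinite(x).all():
        raise ValueError("non-finite intensity values")
    if np.ptp(x) < 1e-12 * max(abs(x).max(), 1.0):
        logger.warning("constant intensity distribution; calling all "
                       "nuclei non-expressing")
        return SignalNoiseFit(
            intensities=x, noise_mean=float(x[0]), noise_sd=0.0,
            signal_mean=float(x[0]), signal_sd=0.0, noise_weight=1.0,
            signal_weight=0.0, posterior_signal=np.zeros(len(x)),
            expressing=np.zeros(len(x), dtype=bool), degenerate=True)
    xr = x.reshape(-1, 1)
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         reg_covar=1e-10 * max(x.var(), 1e-12),
                         max_iter=500, tol=1e-6, n_init=1,
                         init_params="kmeans", random_state=seed)
    gm.fit(xr)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    noise_i, signal_i = order[0], order[1]
    post = gm.predict_proba(xr)[:, signal_i]
    pooled_sd = float(np.sqrt(np.mean(sds ** 2)))
    degenerate = abs(means[signal_i] - means[noise_i]) < \
        degenerate_sep * max(pooled_sd, 1e-300)
    if degenerate:
        logger.warning("signal/noise fit degenerate (means %.3g / %.3g); "
                       "calling all nuclei non-expressing",
                       means[noise_i], means[signal_i])
        post = np.zeros(len(x))
    return SignalNoiseFit(
        intensities=x,
        noise_mean=float(means[noise_i]), noise_sd=float(sds[noise_i]),
        signal_mean=float(means[signal_i]), signal_sd=float(sds[signal_i]),
        noise_weight=float(gm.weights_[noise_i]),
        signal_weight=float(gm.weights_[signal_i]),
        posterior_signal=post,
        expressing=post > 0.5,
        degenerate=bool(degenerate),
    )


def otsu_split(values):
    """Otsu threshold on a 256-bin histogram; returns (threshold, is_high)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("Otsu split requires at least two distinct values")
    thr = float(threshold_otsu(x, nbins=256))
    return thr, x > thr


def normalise_profile(profile, background: float = 0.0):
    """Min–max normalisation of a line profile to [0, 1].

    An optional scalar background (measured outside the sample) is
    subtracted first.  Constant profiles raise a ``ValueError``.
    """
    x = np.asarray(profile, dtype=float) - background
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("constant profile cannot be normalised")
    return (x - lo) / (hi - lo)
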