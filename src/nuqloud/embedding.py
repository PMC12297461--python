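"""Staged 2D reference embedding of feature space and partial-data projection.

The reference embedding is a t-SNE with the staged protocol used for the
organisational atlas: a random pre-sample (default 25,000 cells) is
embedded with PCA initialisation, multi-scale affinities from dual
perplexities (50 and 500), cosine distance and learning rate n/12, running
250 iterations at exaggeration 12 / momentum 0.5 and 750 at exaggeration
1 / momentum 0.8.  Remaining cells are initialised at their feature-space
nearest neighbour's coordinates, and the full embedding is optimised at
perplexity 30 with 500 early-exaggeration iterations (exaggeration 4,
momentum 0.5) followed by 500 at exaggeration 3, momentum 0.8.

New (partial-imaging) data is projected by normalising with the stored
reference z-score parameters, initialising at the nearest reference
neighbour and running 500 iterations at exaggeration 3 with the reference
coordinates held fixed.

The optimiser computes exact pairwise gradients, so it is intended for the
tens-of-thousands-of-cells scale of a reference atlas, not millions.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import EmbeddingConfig
from .features import FeatureTable

logger = logging.getLogger(__name__)

MACHINE_EPS = 1e-12
_MAX_STEP = 0.25  # per-point step-norm clip during partial projection


@dataclass
class ReferenceEmbedding:
    """Fitted 2D reference embedding plus everything needed to project."""

    coordinates: np.ndarray  # (n, 2)
    features: np.ndarray  # z-scored reference feature matrix
    feature_names: tuple
    zscore_params: object  # DataFrame or None
    schedule: dict
    seed: int
    presample_indices: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# affinities


def _normalise_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    return x / np.maximum(norms, MACHINE_EPS)


def cosine_distances(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    xn = _normalise_rows(np.asarray(x, dtype=float))
    yn = xn if y is None else _normalise_rows(np.asarray(y, dtype=float))
    return np.clip(1.0 - xn @ yn.T, 0.0, 2.0)


def _conditional_p(dist: np.ndarray, perplexity: float,
                   exclude_diag: bool) -> np.ndarray:
    """Row-wise Gaussian affinities calibrated to the target perplexity."""
    n, m = dist.shape
    target = np.log(perplexity)
    beta = np.ones(n)
    lo = np.full(n, -np.inf)
    hi = np.full(n, np.inf)
    d = dist.copy()
    if exclude_diag:
        np.fill_diagonal(d, np.nan)
    d = d - np.nanmin(d, axis=1, keepdims=True)  # stabilise exponentials
    if exclude_diag:
        np.fill_diagonal(d, 0.0)  # masked below
    for _ in range(64):
        w = np.exp(-d * beta[:, None])
        if exclude_diag:
            np.fill_diagonal(w, 0.0)
        sw = w.sum(axis=1)
        h = np.log(sw) + beta * (d * w).sum(axis=1) / np.maximum(sw,
                                                                 MACHINE_EPS)
        diff = h - target
        done = np.abs(diff) < 1e-5
        if done.all():
            break
        too_high = diff > 0  # entropy too high -> narrow the kernel
        lo = np.where(too_high, beta, lo)
        hi = np.where(~too_high, beta, hi)
        up = np.where(np.isinf(hi), beta * 2.0, (beta + hi) / 2.0)
        down = np.where(np.isinf(lo), beta / 2.0, (beta + lo) / 2.0)
        beta = np.where(done, beta, np.where(too_high, up, down))
    w = np.exp(-d * beta[:, None])
    if exclude_diag:
        np.fill_diagonal(w, 0.0)
    return w / np.maximum(w.sum(axis=1, keepdims=True), MACHINE_EPS)


def joint_probabilities(x: np.ndarray, perplexities) -> np.ndarray:
    """Symmetrised multi-scale affinities (mean over perplexities)."""
    d = cosine_distances(x)
    n = len(x)
    perplexities = [min(p, (n - 1) / 3.0) for p in perplexities]
    p = np.mean([_conditional_p(d, pp, exclude_diag=True)
                 for pp in perplexities], axis=0)
    p = (p + p.T) / (2.0 * n)
    return np.maximum(p, 0.0)


# ---------------------------------------------------------------------------
# optimisation


def _tsne_optimise(p: np.ndarray, y0: np.ndarray, learning_rate: float,
                   phases) -> np.ndarray:
    """Exact-gradient t-SNE with per-parameter gains and momentum phases.

    Runs in float32: at the reference-atlas scale the gradient noise floor
    is far below the optimisation tolerances.
    """
    y = y0.astype(np.float32)
    p = p.astype(np.float32)
    update = np.zeros_like(y)
    gains = np.ones_like(y)
    for iters, exaggeration, momentum in phases:
        pe = p * np.float32(exaggeration)
        for _ in range(iters):
            d2 = _sq_dists(y)
            w = 1.0 / (1.0 + d2)
            np.fill_diagonal(w, 0.0)
            q = w / max(w.sum(), MACHINE_EPS)
            pq = (pe - q) * w
            grad = 4.0 * ((np.diag(pq.sum(axis=1)) - pq) @ y)
            same_sign = np.sign(grad) == np.sign(update)
            gains = np.where(same_sign, gains * 0.8, gains + 0.2)
            gains = np.maximum(gains, 0.01)
            update = momentum * update - learning_rate * gains * grad
            y = y + update
            y = y - y.mean(axis=0)
    return y.astype(float)


def _sq_dists(y: np.ndarray) -> np.ndarray:
    s = (y ** 2).sum(axis=1)
    d2 = s[:, None] + s[None, :] - 2.0 * (y @ y.T)
    return np.maximum(d2, 0.0)


def _pca_init(x: np.ndarray, seed: int) -> np.ndarray:
    y = PCA(n_components=2, random_state=seed).fit_transform(x)
    return y / max(y[:, 0].std(), MACHINE_EPS) * 1e-4


def _extract_features(features):
    if isinstance(features, FeatureTable):
        if not features.is_zscored:
            raise ValueError("embedding expects z-scored features")
        return (features.values, features.feature_names,
                features.zscore_params)
    x = np.asarray(features, dtype=float)
    return x, tuple(f"f{i}" for i in range(x.shape[1])), None


def fit_reference(features, seed: int = 0,
                  config: EmbeddingConfig | None = None) -> ReferenceEmbedding:
    """Fit the staged reference t-SNE; deterministic given the seed."""
    config = config or EmbeddingConfig()
    x, names, zparams = _extract_features(features)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 cells for a reference embedding")
    if np.isnan(x).any():
        raise ValueError("missing values in feature matrix")
    rng = np.random.default_rng(seed)
    t0 = time.perf_counter()

    n_pre = min(config.pre_sample, n)
    pre_idx = np.sort(rng.choice(n, n_pre, replace=False))
    x_pre = x[pre_idx]

    perps = list(config.pre_perplexities)
    if n_pre - 1 < 3 * max(perps):
        scaled = [min(p, (n_pre - 1) / 3.0) for p in perps]
        logger.warning("pre-sample too small for perplexities %s; using %s",
                       perps, scaled)
        perps = scaled
    p_pre = joint_probabilities(x_pre, perps)
    y_pre = _tsne_optimise(p_pre, _pca_init(x_pre, seed),
                           learning_rate=max(n_pre / 12.0, 1.0),
                           phases=config.pre_schedule)

    y = np.empty((n, 2))
    y[pre_idx] = y_pre
    rest = np.setdiff1d(np.arange(n), pre_idx)
    if len(rest):
        d = cosine_distances(x[rest], x_pre)
        y[rest] = y_pre[d.argmin(axis=1)]

    full_perp = min(config.full_perplexity, (n - 1) / 3.0)
    p_full = joint_probabilities(x, [full_perp])
    y = _tsne_optimise(p_full, y, learning_rate=max(n / 12.0, 1.0),
                       phases=config.full_schedule)

    schedule = {
        "pre_sample": n_pre,
        "pre_perplexities": tuple(perps),
        "pre_schedule": tuple(config.pre_schedule),
        "full_perplexity": full_perp,
        "full_schedule": tuple(config.full_schedule),
        "learning_rate_rule": "n/12",
        "metric": "cosine",
        "init": "pca",
        "momentum_note": "printed protocol value 8 interpreted as 0.8",
        "seed": seed,
    }
    logger.info("reference embedding: %d cells (%d pre-embedded) in %.1fs",
                n, n_pre, time.perf_counter() - t0)
    return ReferenceEmbedding(
        coordinates=y, features=x, feature_names=names,
        zscore_params=zparams, schedule=schedule, seed=seed,
        presample_indices=pre_idx)


def project_partial(reference: ReferenceEmbedding, new_features,
                    config: EmbeddingConfig | None = None) -> np.ndarray:
    """Project partial data into a fitted reference embedding.

    New feature vectors must be normalised with the REFERENCE's stored
    z-score parameters; passing a :class:`FeatureTable` z-scored with its
    own statistics raises.  Points start at their nearest reference
    neighbour (cosine distance) and are optimised for 500 iterations at
    exaggeration 3 with the reference coordinates frozen.
    """
    config = config or EmbeddingConfig()
    if isinstance(new_features, FeatureTable):
        if not new_features.is_zscored:
            raise ValueError("project_partial expects z-scored features")
        if tuple(new_features.feature_names) != tuple(
                reference.feature_names):
            raise ValueError("feature names do not match the reference")
        if reference.zscore_params is not None:
            a = reference.zscore_params.loc[list(reference.feature_names)]
            b = new_features.zscore_params.loc[list(reference.feature_names)]
            if not np.allclose(a.to_numpy(), b.to_numpy(), rtol=0, atol=0):
                raise ValueError(
                    "new data was z-scored with its own statistics; "
                    "normalise with the reference's stored parameters")
        x_new = new_features.values
    else:
        x_new = np.asarray(new_features, dtype=float)
    if x_new.shape[1] != reference.features.shape[1]:
        raise ValueError("feature dimensionality mismatch")

    d = cosine_distances(x_new, reference.features)
    y_ref = reference.coordinates
    y = y_ref[d.argmin(axis=1)].copy()

    perp = min(config.full_perplexity, (reference.features.shape[0]) / 3.0)
    p = _conditional_p(d, perp, exclude_diag=False)  # rows sum to 1

    m = len(x_new)
    lr = max(m / 12.0, 1.0)
    y = y.astype(np.float32)
    y_ref32 = y_ref.astype(np.float32)
    p = p.astype(np.float32)
    update = np.zeros_like(y)
    gains = np.ones_like(y)
    exaggeration = np.float32(config.projection_exaggeration)
    momentum = np.float32(config.projection_momentum)
    sy = (y_ref32 ** 2).sum(axis=1)
    for _ in range(config.projection_iters):
        d2 = np.maximum((y ** 2).sum(axis=1)[:, None] + sy[None, :]
                        - 2.0 * (y @ y_ref32.T), 0.0)
        w = 1.0 / (1.0 + d2)
        q = w / np.maximum(w.sum(axis=1, keepdims=True), MACHINE_EPS)
        c = (exaggeration * p - q) * w
        grad = 4.0 * (c.sum(axis=1)[:, None] * y - c @ y_ref32)
        same_sign = np.sign(grad) == np.sign(update)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        gains = np.maximum(gains, 0.01)
        update = momentum * update - lr * gains * grad
        # clip per-point step norms: new points move through a fixed
        # potential, so unbounded gain-scaled steps oscillate
        norms = np.linalg.norm(update, axis=1, keepdims=True)
        update = update * np.minimum(1.0, _MAX_STEP / np.maximum(
            norms, MACHINE_EPS))
        y = y + update
    return y.astype(float)
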