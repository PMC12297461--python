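"""Organisational motifs (Gaussian mixture) and archetypes (Ward HAC).

Cells are stratified in z-scored feature space by a full-covariance
Gaussian mixture (default 11 components, k-means initialised).  Component
count selection combines the silhouette elbow, BIC, and a local minimum of
the Jensen–Shannon-divergence gradient between successive mixtures.  Motifs
agglomerate into two archetypes by Ward clustering of their mean feature
profiles; the archetype with the higher mean density-class features is
called *amorphous*, the other *crystalline*.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .datatypes import ClusteringConfig
from .features import DENSITY_FEATURES, FeatureTable

logger = logging.getLogger(__name__)

_WARD_REPLICAS = 1000  # row replication resolution for the weighted Ward tree
AMORPHOUS = "amorphous"
CRYSTALLINE = "crystalline"


@dataclass
class MotifModel:
    """Fitted Gaussian-mixture motif model in z-scored feature space."""

    n_components: int
    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    labels: np.ndarray
    seed: int
    converged: bool
    feature_names: tuple
    diagnostics: pd.DataFrame | None = None
    _gm: GaussianMixture | None = field(default=None, repr=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._gm.predict(x)

    def score_samples(self, x: np.ndarray) -> np.ndarray:
        return self._gm.score_samples(x)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Deterministic mixture sampling (component draw + Gaussian)."""
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        out = np.empty((n, self.means.shape[1]))
        for k in range(self.n_components):
            m = comp == k
            if m.any():
                out[m] = rng.multivariate_normal(
                    self.means[k], self.covariances[k], size=m.sum(),
                    method="cholesky")
        return out


@dataclass
class ArchetypeMap:
    """Motif → archetype assignment with per-cell labels."""

    motif_to_archetype: dict
    archetype_profiles: pd.DataFrame  # archetype x feature mean z-scores
    linkage_tree: np.ndarray
    cell_labels: np.ndarray  # archetype name per cell


def _extract(features) -> tuple:
    if isinstance(features, FeatureTable):
        if not features.is_zscored:
            raise ValueError("motif clustering expects z-scored features")
        return features.values, features.feature_names
    x = np.asarray(features, dtype=float)
    return x, tuple(f"f{i}" for i in range(x.shape[1]))


def fit_motifs(features, K: int = 11, seed: int = 0,
               config: ClusteringConfig | None = None) -> MotifModel:
    """EM-fit a full-covariance K-component mixture, k-means initialised.

    Deterministic given the seed: the k-means partition (10 restarts) seeds
    the responsibilities, and EM runs to tol 1e-4 or 500 iterations with a
    1e-6 covariance regularisation floor.
    """
    config = config or ClusteringConfig()
    x, names = _extract(features)
    if np.isnan(x).any():
        raise ValueError("missing values in feature matrix")
    if len(x) < 10 * K:
        raise ValueError(f"need at least {10 * K} cells for K={K} "
                         f"(got {len(x)})")
    km = KMeans(n_clusters=K, n_init=config.kmeans_restarts,
                random_state=seed).fit(x)
    weights0 = np.bincount(km.labels_, minlength=K) / len(x)
    gm = GaussianMixture(
        n_components=K, covariance_type="full",
        reg_covar=config.covariance_floor, max_iter=config.em_max_iter,
        tol=config.em_tol, means_init=km.cluster_centers_,
        weights_init=weights0, random_state=seed)
    gm.fit(x)
    if not gm.converged_:
        logger.warning("EM did not converge in %d iterations; returning "
                       "best-so-far model", config.em_max_iter)
    return MotifModel(
        n_components=K, means=gm.means_, covariances=gm.covariances_,
        weights=gm.weights_, labels=gm.predict(x), seed=seed,
        converged=bool(gm.converged_), feature_names=names, _gm=gm)


def _jsd_monte_carlo(model_p: MotifModel, model_q: MotifModel,
                     n_draws: int, rng: np.random.Generator) -> float:
    """Jensen–Shannon divergence between two mixtures, Monte-Carlo estimate."""
    xp = model_p.sample(n_draws, rng)
    xq = model_q.sample(n_draws, rng)
    lp_p, lq_p = model_p.score_samples(xp), model_q.score_samples(xp)
    lp_q, lq_q = model_p.score_samples(xq), model_q.score_samples(xq)
    lm_p = logsumexp([lp_p, lq_p], axis=0) - np.log(2.0)
    lm_q = logsumexp([lp_q, lq_q], axis=0) - np.log(2.0)
    return 0.5 * float(np.mean(lp_p - lm_p)) + \
        0.5 * float(np.mean(lq_q - lm_q))


def select_motif_count(features, K_range, seed: int = 0,
                       n_draws: int = 10_000,
                       silhouette_subsample: int = 10_000):
    """Model-selection diagnostics over a range of component counts.

    For each K: mean silhouette (on a subsample), BIC, and the Monte-Carlo
    Jensen–Shannon divergence between the K and K−1 mixtures.  The JSD
    gradient is its finite difference over K; the recommended K is the
    first local minimum of that gradient (ties toward smaller K).
    """
    K_range = sorted(int(k) for k in K_range)
    if len(K_range) < 3:
        raise ValueError("K_range must contain at least 3 values")
    if min(K_range) < 2 or max(K_range) > 64:
        raise ValueError("K_range must lie within [2, 64]")
    x, _ = _extract(features)
    rng = np.random.default_rng(seed)
    sub = np.arange(len(x))
    if len(x) > silhouette_subsample:
        sub = rng.choice(len(x), silhouette_subsample, replace=False)

    models = {}
    rows = []
    fit_ks = sorted(set(K_range) | {min(K_range) - 1}) \
        if min(K_range) > 1 else K_range
    for K in fit_ks:
        models[K] = fit_motifs(x, K=K, seed=seed)
    for K in K_range:
        model = models[K]
        sil = silhouette_score(x[sub], model.labels[sub]) \
            if len(np.unique(model.labels[sub])) > 1 else np.nan
        bic = model._gm.bic(x)
        jsd = _jsd_monte_carlo(model, models[K - 1], n_draws,
                               np.random.default_rng(seed + 13 * K)) \
            if K - 1 in models else np.nan
        rows.append({"K": K, "silhouette": sil, "bic": bic, "jsd": jsd})
    diag = pd.DataFrame(rows).set_index("K")
    jsd = diag["jsd"].to_numpy()
    grad = np.full(len(jsd), np.nan)
    grad[:-1] = np.diff(jsd)
    diag["jsd_gradient"] = grad

    finite = np.isfinite(grad)
    rec = None
    for i in range(1, len(grad) - 1):
        if not (finite[i - 1] and finite[i] and finite[i + 1]):
            continue
        if grad[i] < grad[i - 1] and grad[i] <= grad[i + 1]:
            rec = K_range[i]
            break
    if rec is None and finite.any():
        rec = K_range[int(np.nanargmin(grad))]
    return diag, rec


def feature_importance(features, labels, seed: int = 0,
                       n_estimators: int = 200) -> pd.DataFrame:
    """Random-forest impurity importances of features for the motif labels.

    Importances are non-negative and sum to one; features below
    1/(10·n_features) are flagged as underutilised.
    """
    x, names = _extract(features)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two motif labels")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(x, labels)
    imp = rf.feature_importances_
    return pd.DataFrame({
        "importance": imp,
        "underutilised": imp < 1.0 / (10.0 * len(names)),
    }, index=list(names))


def cluster_archetypes(motif_model: MotifModel, features=None,
                       n_archetypes: int = 2, metric: str = "euclidean",
                       min_weight: float = 0.005) -> ArchetypeMap:
    """Ward-agglomerate motif mean profiles into archetypes.

    ``metric`` is "euclidean" (default) or "correlation" (1 − Pearson of
    the profiles).  Motifs with mixture weight below ``min_weight`` are
    near-empty components (typically a handful of extreme boundary cells);
    they are excluded from the dendrogram — where their outlying profiles
    would otherwise dominate the top split — and attached to the nearest
    archetype centroid afterwards.  With two archetypes, the one whose
    cells have the higher mean density-class features is labelled
    amorphous.
    """
    K = motif_model.n_components
    if n_archetypes > K:
        raise ValueError(f"n_archetypes={n_archetypes} exceeds K={K}")
    profiles = motif_model.means
    big = motif_model.weights >= min_weight
    if big.sum() < n_archetypes:
        big = np.ones(K, dtype=bool)
    core = profiles[big]
    # weight motifs by their cell mass (replicated rows give exactly the
    # weighted Ward objective): the top split then separates cell
    # populations instead of isolating small outlying motifs
    reps = np.maximum(np.round(
        motif_model.weights[big] * _WARD_REPLICAS).astype(int), 1)
    rows = np.repeat(np.arange(big.sum()), reps)
    expanded = core[rows]
    if metric == "euclidean":
        tree = linkage(expanded, method="ward")
    elif metric == "correlation":
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(expanded)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        dist[~np.isfinite(dist)] = 1.0  # constant profile: neutral distance
        np.fill_diagonal(dist, 0.0)
        tree = linkage(squareform(dist, checks=False), method="ward")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    expanded_groups = fcluster(tree, t=n_archetypes, criterion="maxclust")
    groups = np.empty(K, dtype=int)
    for j in range(big.sum()):
        member = expanded_groups[rows == j]
        groups[np.nonzero(big)[0][j]] = np.bincount(member).argmax()
    if (~big).any():
        cents = np.stack([profiles[big][groups[big] == g].mean(axis=0)
                          for g in range(1, n_archetypes + 1)])
        for k in np.nonzero(~big)[0]:
            groups[k] = 1 + int(np.argmin(
                np.linalg.norm(cents - profiles[k], axis=1)))

    names = list(motif_model.feature_names)
    cell_groups = groups[motif_model.labels]
    group_profiles = pd.DataFrame(
        [profiles[groups == g].mean(axis=0)
         for g in range(1, n_archetypes + 1)],
        index=range(1, n_archetypes + 1), columns=names)

    dens_cols = [c for c in names if c in DENSITY_FEATURES]
    if n_archetypes == 2 and dens_cols:
        dens = group_profiles[dens_cols].mean(axis=1)
        amorph = int(dens.idxmax())
        label_of = {amorph: AMORPHOUS,
                    (3 - amorph): CRYSTALLINE}
    else:
        label_of = {g: f"archetype_{g}" for g in range(1, n_archetypes + 1)}
    motif_to_arch = {k: label_of[groups[k]] for k in range(K)}
    cell_labels = np.array([label_of[g] for g in cell_groups], dtype=object)
    group_profiles.index = [label_of[g] for g in group_profiles.index]
    return ArchetypeMap(
        motif_to_archetype=motif_to_arch,
        archetype_profiles=group_profiles,
        linkage_tree=tree,
        cell_labels=cell_labels,
    )


def select_archetype_count(motif_model: MotifModel, features,
                           candidates=range(2, 7), seed: int = 0,
                           metric: str = "euclidean",
                           subsample: int = 10_000) -> tuple:
    """Silhouette-selected cut count over the motif dendrogram.

    Cuts the archetype dendrogram at each candidate count, scores the
    induced per-cell partition by silhouette in feature space (on a
    subsample), and returns ``(best_count, scores)``.
    """
    x, _ = _extract(features)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(x))
    if len(x) > subsample:
        idx = rng.choice(len(x), subsample, replace=False)
    scores = {}
    for c in candidates:
        if c > motif_model.n_components:
            continue
        amap = cluster_archetypes(motif_model, n_archetypes=c, metric=metric)
        labs = amap.cell_labels[idx]
        if len(np.unique(labs)) < 2:
            continue
        scores[c] = float(silhouette_score(x[idx], labs))
    best = max(scores, key=scores.get)
    return best, scores


def archetype_robustness(features, K_list=(2, 4, 8, 16, 32, 64, 128, 256),
                         seed: int = 0, n_archetypes: int = 2) -> pd.DataFrame:
    """Agreement of archetype bipartitions across initial motif counts.

    Fits motifs for each K, cuts archetypes, and returns the pairwise
    adjusted-Rand-index matrix of the per-cell archetype labels.
    """
    x, _ = _extract(features)
    K_list = [int(k) for k in K_list]
    if len(x) < 10 * max(K_list):
        raise ValueError("not enough cells for the largest K")
    labels = {}
    for K in K_list:
        model = fit_motifs(features, K=K, seed=seed)
        amap = cluster_archetypes(model, n_archetypes=n_archetypes)
        labels[K] = amap.cell_labels
    ari = pd.DataFrame(index=K_list, columns=K_list, dtype=float)
    for a in K_list:
        for b in K_list:
            la = pd.factorize(labels[a])[0]
            lb = pd.factorize(labels[b])[0]
            ari.loc[a, b] = adjusted_rand_score(la, lb)
    return ari
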