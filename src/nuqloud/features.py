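"""Per-nucleus organisational features.

Fourteen features describe each nucleus' local neighbourhood:

* three multi-scale densities — counts of other nuclei in concentric
  spherical shells (default 0–10, 10–20, 20–30 µm) divided by shell volume
  (µm⁻³);
* Voronoi density — mean inverse distance to face-sharing (Delaunay)
  neighbours (µm⁻¹);
* Voronoi cell volume (µm³), number of face neighbours, centroid offset
  (distance seed → cell centroid, µm) and polarity (centroid offset
  normalised by the cell's cube-root volume, dimensionless);
* mean and population standard deviation of volume, neighbour count and
  centroid offset over the immediate Voronoi neighbourhood (self excluded).

Features are z-scored jointly across all samples of a dataset (pooled mean
and sd), which preserves inter-sample differences; the parameters are kept
so partial datasets can be normalised onto the same scale.  Features group
into three classes — density, anisotropy, irregularity — recovered by
Ward clustering of their average per-sample Pearson correlation.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from . import geometry
from .datatypes import FeatureConfig, SampleCloud

logger = logging.getLogger(__name__)

DENSITY_FEATURES = ("density_0_10", "density_10_20", "density_20_30",
                    "voronoi_density")
ANISOTROPY_FEATURES = ("voronoi_volume", "nbh_mean_volume", "centroid_offset",
                       "nbh_mean_centroid_offset", "nbh_std_centroid_offset",
                       "polarity")
IRREGULARITY_FEATURES = ("n_neighbours", "nbh_mean_n_neighbours",
                         "nbh_std_n_neighbours", "nbh_std_volume")

FEATURE_NAMES = (
    "density_0_10", "density_10_20", "density_20_30", "voronoi_density",
    "voronoi_volume", "n_neighbours", "centroid_offset", "polarity",
    "nbh_mean_volume", "nbh_std_volume",
    "nbh_mean_n_neighbours", "nbh_std_n_neighbours",
    "nbh_mean_centroid_offset", "nbh_std_centroid_offset",
)

CANONICAL_CLASSES = {
    "density": set(DENSITY_FEATURES),
    "anisotropy": set(ANISOTROPY_FEATURES),
    "irregularity": set(IRREGULARITY_FEATURES),
}


@dataclass
class FeatureTable:
    """n_cells × n_features organisational feature matrix.

    ``data`` is indexed by (sample_id, nucleus_id); non-feature annotation
    columns (boundary flags, ground-truth labels) are carried alongside the
    feature columns.  ``zscore_params`` holds the pooled per-feature mean/sd
    once the table has been (or can be) standardised.
    """

    data: pd.DataFrame
    feature_names: tuple = FEATURE_NAMES
    zscore_params: pd.DataFrame | None = None  # columns: mean, sd
    is_zscored: bool = False
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data.index.get_level_values("sample_id").to_numpy()

    def annotation(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def to_csv(self, path) -> None:
        self.data.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# individual feature groups


def shell_densities(points, radii=(10.0, 20.0, 30.0),
                    tree: cKDTree | None = None) -> np.ndarray:
    """Multi-scale density: neighbour counts per concentric shell / volume.

    For nucleus i and shell (a, b]: number of *other* nuclei at distance
    a < d <= b divided by the shell volume (4π/3)(b³−a³).  Returns an
    (n, len(radii)) array in µm⁻³.
    """
    radii = tuple(float(r) for r in radii)
    if any(b <= a for a, b in zip((0.0,) + radii, radii)):
        raise ValueError("shell radii must be strictly increasing and > 0")
    pts = np.asarray(points, dtype=float)
    if tree is None:
        tree = cKDTree(pts)
    cum = np.stack([
        tree.query_ball_point(pts, r, return_length=True) for r in radii
    ], axis=1).astype(float)
    cum -= 1.0  # every cumulative ball contains the focal nucleus itself
    counts = np.diff(np.concatenate(
        [np.zeros((len(pts), 1)), cum], axis=1), axis=1)
    edges = (0.0,) + radii
    vols = np.array([4.0 / 3.0 * np.pi * (b ** 3 - a ** 3)
                     for a, b in zip(edges[:-1], edges[1:])])
    return counts / vols


def cell_features(tessellation: geometry.Tessellation):
    """Voronoi-derived per-cell features.

    Returns ``(frame, isolated)`` where frame has columns voronoi_volume,
    voronoi_density, n_neighbours, centroid_offset, polarity, and
    ``isolated`` flags cells without any real face neighbour (their
    voronoi_density is reported as 0).
    """
    pts = tessellation.points
    n = len(tessellation)
    nnb = np.array([len(nb) for nb in tessellation.neighbours])
    vdens = np.zeros(n)
    for i, nb in enumerate(tessellation.neighbours):
        if len(nb):
            d = np.linalg.norm(pts[nb] - pts[i], axis=1)
            vdens[i] = np.mean(1.0 / d)
    isolated = nnb == 0
    if isolated.any():
        logger.warning("%d cells have no real face neighbours; their "
                       "voronoi_density is reported as 0", isolated.sum())
    offset = np.linalg.norm(tessellation.centroids - pts, axis=1)
    volume = tessellation.volumes
    frame = pd.DataFrame({
        "voronoi_volume": volume,
        "voronoi_density": vdens,
        "n_neighbours": nnb.astype(float),
        "centroid_offset": offset,
        "polarity": offset / np.cbrt(volume),
    })
    return frame, isolated


def neighbourhood_stats(tessellation: geometry.Tessellation,
                        base: pd.DataFrame) -> pd.DataFrame:
    """Mean / population-std of volume, neighbour count and centroid offset
    over each cell's face neighbours (self excluded; std is 0 for cells with
    a single neighbour, and isolated cells get 0 throughout)."""
    cols = {"volume": base["voronoi_volume"].to_numpy(),
            "n_neighbours": base["n_neighbours"].to_numpy(),
            "centroid_offset": base["centroid_offset"].to_numpy()}
    n = len(tessellation)
    out = {f"nbh_mean_{k}": np.zeros(n) for k in cols}
    out.update({f"nbh_std_{k}": np.zeros(n) for k in cols})
    for i, nb in enumerate(tessellation.neighbours):
        if not len(nb):
            continue
        for k, v in cols.items():
            vals = v[nb]
            out[f"nbh_mean_{k}"][i] = vals.mean()
            out[f"nbh_std_{k}"][i] = vals.std()  # population form
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# pipeline


def compute_features(clouds, config: FeatureConfig | None = None,
                     edge_length: float = 100.0) -> FeatureTable:
    """Full organisational feature extraction for one or more samples.

    Tessellates each sample (adaptive restricted Voronoi), computes the 14
    features and returns a raw (non-z-scored) :class:`FeatureTable` with
    ``is_boundary`` / ``isolated`` annotation columns; ground-truth labels
    present on the clouds are carried through.
    """
    config = config or FeatureConfig()
    if isinstance(clouds, SampleCloud):
        clouds = [clouds]
    frames = []
    for cloud in clouds:
        t0 = time.perf_counter()
        if len(cloud) < 5:
            raise ValueError(
                f"sample {cloud.sample_id}: at least 5 nuclei required")
        tess = geometry.adaptive_voronoi(cloud.positions, edge_length)
        dens = shell_densities(cloud.positions, config.shell_radii)
        base, isolated = cell_features(tess)
        nbh = neighbourhood_stats(tess, base)
        df = pd.concat(
            [pd.DataFrame(dens, columns=["density_0_10", "density_10_20",
                                         "density_20_30"]),
             base, nbh], axis=1)
        df["is_boundary"] = tess.is_boundary
        df["isolated"] = isolated
        for name, values in cloud.labels.items():
            df[name] = values
        df["sample_id"] = cloud.sample_id
        df["nucleus_id"] = cloud.nucleus_ids
        frames.append(df)
        logger.info("features: sample %s, %d cells, %.2fs",
                    cloud.sample_id, len(cloud), time.perf_counter() - t0)
    data = pd.concat(frames, ignore_index=True)
    data = data.set_index(["sample_id", "nucleus_id"])
    names = FEATURE_NAMES if config.include_polarity else tuple(
        f for f in FEATURE_NAMES if f != "polarity")
    return FeatureTable(data=data, feature_names=names,
                        metadata={"shell_radii": config.shell_radii,
                                  "edge_length": edge_length})


def zscore(table: FeatureTable,
           params: pd.DataFrame | None = None) -> FeatureTable:
    """Standardise features; pooled across ALL samples unless params given.

    With ``params=None`` the pooled mean/sd over every cell of every sample
    are computed and stored for reuse on new (partial) data.  Constant
    features (sd < 1e-12) raise a ``ValueError`` naming the column.
    """
    x = table.values
    names = list(table.feature_names)
    if params is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        params = pd.DataFrame({"mean": mean, "sd": sd}, index=names)
    else:
        missing = [n for n in names if n not in params.index]
        if missing:
            raise ValueError(f"z-score params missing features {missing}")
        mean = params.loc[names, "mean"].to_numpy()
        sd = params.loc[names, "sd"].to_numpy()
    tiny = np.asarray(sd) < 1e-12
    if tiny.any():
        bad = [names[i] for i in np.nonzero(tiny)[0]]
        raise ValueError(f"constant feature column(s): {bad}")
    z = (x - mean) / sd
    data = table.data.copy()
    data[names] = z
    return FeatureTable(data=data, feature_names=table.feature_names,
                        zscore_params=params, is_zscored=True,
                        metadata=dict(table.metadata))


def inverse_zscore(table: FeatureTable) -> FeatureTable:
    if not table.is_zscored or table.zscore_params is None:
        raise ValueError("table is not z-scored")
    names = list(table.feature_names)
    mean = table.zscore_params.loc[names, "mean"].to_numpy()
    sd = table.zscore_params.loc[names, "sd"].to_numpy()
    data = table.data.copy()
    data[names] = table.values * sd + mean
    return FeatureTable(data=data, feature_names=table.feature_names,
                        zscore_params=table.zscore_params, is_zscored=False,
                        metadata=dict(table.metadata))


@dataclass
class FeatureClassMap:
    """Feature → class assignment plus the dendrogram it came from."""

    classes: dict  # feature name -> class name
    linkage_tree: np.ndarray
    mean_correlation: pd.DataFrame

    def members(self, class_name: str) -> list:
        return [f for f, c in self.classes.items() if c == class_name]


def classify_features(table: FeatureTable, n_classes: int = 3,
                      min_cells: int = 3) -> FeatureClassMap:
    """Group features by Ward clustering of their mean Pearson correlation.

    Correlation is computed per sample at single-cell level, averaged across
    samples; distance is 1 − correlation.  The resulting groups are named by
    maximal overlap with the canonical density / anisotropy / irregularity
    classes.
    """
    names = list(table.feature_names)
    if len(names) < 2:
        raise ValueError("need at least two features")
    sids = table.sample_ids
    mats = []
    for sid in pd.unique(sids):
        x = table.values[sids == sid]
        if len(x) < min_cells:
            raise ValueError(f"sample {sid}: fewer than {min_cells} cells")
        if np.any(x.std(axis=0) < 1e-12):
            bad = [names[i] for i in np.nonzero(x.std(axis=0) < 1e-12)[0]]
            raise ValueError(f"constant feature in sample {sid}: {bad}")
        mats.append(np.corrcoef(x, rowvar=False))
    corr = np.mean(mats, axis=0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="ward")
    groups = fcluster(tree, t=n_classes, criterion="maxclust")

    class_names = list(CANONICAL_CLASSES)
    if n_classes == len(class_names):
        overlap = np.zeros((n_classes, n_classes))
        for g in range(1, n_classes + 1):
            members = {names[i] for i in np.nonzero(groups == g)[0]}
            for c, cname in enumerate(class_names):
                overlap[g - 1, c] = len(members & CANONICAL_CLASSES[cname])
        rows, cols = linear_sum_assignment(-overlap)
        mapping = {g + 1: class_names[c] for g, c in zip(rows, cols)}
    else:
        mapping = {g: f"class_{g}" for g in range(1, n_classes + 1)}
    classes = {names[i]: mapping[groups[i]] for i in range(len(names))}
    return FeatureClassMap(
        classes=classes, linkage_tree=tree,
        mean_correlation=pd.DataFrame(corr, index=names, columns=names))
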