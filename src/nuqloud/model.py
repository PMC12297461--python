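"""High-level modelling interface: organisational motifs and archetypes.

`OrganisationModel` bundles the full analysis of one or more nuclear point
clouds — adaptive restricted Voronoi tessellation, the 14 organisational
features, pooled z-scoring, Gaussian-mixture motif stratification and
archetype agglomeration — behind a fit() call that returns an
`OrganisationResults` with labels, diagnostics and a summary table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, features as feats
from .datatypes import RunConfig, SampleCloud
from .features import FeatureTable

logger = logging.getLogger(__name__)


class OrganisationModel:
    """Organisational-motif model over nuclear point clouds.

    Parameters
    ----------
    data : SampleCloud, list of SampleCloud, or FeatureTable
        Input specimens; a precomputed (raw) feature table skips the
        geometry stage.
    config : RunConfig, optional
        Geometry / feature / clustering parameters.
    """

    def __init__(self, data, config: RunConfig | None = None):
        self.config = config or RunConfig()
        if isinstance(data, FeatureTable):
            self._clouds = None
            self._raw = data
        else:
            self._clouds = [data] if isinstance(data, SampleCloud) else \
                list(data)
            self._raw = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: RunConfig | None = None) -> "OrganisationModel":
        """Build from the canonical table layout
        (sample_id, nucleus_id, x_um, y_um, z_um, ...)."""
        clouds = [SampleCloud.from_frame(df[df["sample_id"] == sid],
                                         sample_id=sid)
                  for sid in df["sample_id"].unique()]
        return cls(clouds, config=config)

    def extract_features(self) -> FeatureTable:
        """Raw (non-z-scored) feature table; computed once and cached."""
        if self._raw is None:
            self._raw = feats.compute_features(
                self._clouds, self.config.features,
                edge_length=self.config.geometry.edge_length)
        return self._raw

    def fit(self, seed: int | None = None,
            n_motifs: int | None = None) -> "OrganisationResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        K = cfg.clustering.n_motifs if n_motifs is None else n_motifs
        raw = self.extract_features()
        z = feats.zscore(raw)
        motifs = clustering.fit_motifs(z, K=K, seed=seed,
                                       config=cfg.clustering)
        archetypes = clustering.cluster_archetypes(
            motifs, z, n_archetypes=cfg.clustering.n_archetypes,
            metric=cfg.clustering.archetype_metric)
        return OrganisationResults(
            model=self, raw_features=raw, zscored_features=z,
            motif_model=motifs, archetype_map=archetypes, seed=seed)


@dataclass
class OrganisationResults:
    """Fitted motif/archetype stratification of a dataset."""

    model: OrganisationModel
    raw_features: FeatureTable
    zscored_features: FeatureTable
    motif_model: clustering.MotifModel
    archetype_map: clustering.ArchetypeMap
    seed: int
    _importance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def motif_labels(self) -> np.ndarray:
        return self.motif_model.labels

    @property
    def archetype_labels(self) -> np.ndarray:
        return self.archetype_map.cell_labels

    def feature_importance(self) -> pd.DataFrame:
        if self._importance is None:
            self._importance = clustering.feature_importance(
                self.zscored_features, self.motif_labels, seed=self.seed)
        return self._importance

    def to_frame(self) -> pd.DataFrame:
        df = self.raw_features.data.copy()
        df["motif"] = self.motif_labels
        df["archetype"] = self.archetype_labels
        return df

    def summary(self) -> str:
        z = self.zscored_features
        n = len(z)
        sids = pd.unique(z.sample_ids)
        lines = [
            "Organisational motif model",
            "=" * 54,
            f"cells: {n}    samples: {len(sids)}    "
            f"features: {len(z.feature_names)}",
            f"motifs (GMM components): {self.motif_model.n_components}"
            f"    seed: {self.seed}    "
            f"converged: {self.motif_model.converged}",
            "",
            "motif  weight  cells   archetype",
        ]
        counts = np.bincount(self.motif_labels,
                             minlength=self.motif_model.n_components)
        for k in range(self.motif_model.n_components):
            lines.append(
                f"{k:>5d}  {self.motif_model.weights[k]:.3f}  "
                f"{counts[k]:>6d}   "
                f"{self.archetype_map.motif_to_archetype[k]}")
        lines.append("")
        arch_counts = pd.Series(self.archetype_labels).value_counts()
        total = arch_counts.sum()
        for name, cnt in arch_counts.items():
            lines.append(f"archetype {name:<12s} {cnt:>7d} cells "
                         f"({100.0 * cnt / total:.1f}%)")
        return "\n".join(lines)

    def plot_archetypes(self, ax=None, coords=None, s=2.0):
        """Scatter the cells coloured by archetype (xy positions or given
        2D coordinates, e.g. a reference embedding)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        if coords is None:
            raw = self.raw_features.data
            if "x_um" in raw.columns:
                coords = raw[["x_um", "y_um"]].to_numpy()
            else:
                raise ValueError("no coordinates available; pass coords")
        for name in np.unique(self.archetype_labels):
            m = self.archetype_labels == name
            ax.scatter(coords[m, 0], coords[m, 1], s=s, label=str(name))
        ax.set_aspect("equal")
        ax.legend(markerscale=5)
        return ax
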