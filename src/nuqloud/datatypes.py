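"""Core data containers: nucleus records, per-sample point clouds, run config."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

#: canonical table columns (µm coordinates)
COORD_COLUMNS = ("x_um", "y_um", "z_um")
ID_COLUMNS = ("sample_id", "nucleus_id")
CHANNEL_PREFIX = "channel_"


@dataclass
class NucleusRecord:
    """One segmented nucleus: identity, 3D position (µm), channel intensities."""

    nucleus_id: object
    sample_id: object
    position: np.ndarray
    intensities: dict = field(default_factory=dict)


@dataclass
class SampleCloud:
    """All nuclei of one specimen.

    Positions are real-valued µm in a right-handed frame; optional per-channel
    intensities are stored column-wise.  Ground-truth annotations produced by
    the synthetic generators (population labels, interior flags) live in
    ``labels``.
    """

    sample_id: object
    nucleus_ids: np.ndarray
    positions: np.ndarray  # (n, 3) µm
    intensities: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.nucleus_ids = np.asarray(self.nucleus_ids)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if len(self.nucleus_ids) != len(self.positions):
            raise ValueError("nucleus_ids and positions length mismatch")
        if not np.isfinite(self.positions).all():
            bad = np.nonzero(~np.isfinite(self.positions).all(axis=1))[0]
            raise ValueError(
                f"sample {self.sample_id}: non-finite coordinates at rows "
                f"{bad.tolist()[:10]}")
        if len(np.unique(self.nucleus_ids)) != len(self.nucleus_ids):
            raise ValueError(
                f"sample {self.sample_id}: duplicate nucleus_id values")

    def __len__(self):
        return len(self.positions)

    @property
    def records(self) -> list:
        return [
            NucleusRecord(
                nucleus_id=self.nucleus_ids[i],
                sample_id=self.sample_id,
                position=self.positions[i],
                intensities={c: v[i] for c, v in self.intensities.items()},
            )
            for i in range(len(self))
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "sample_id": self.sample_id,
            "nucleus_id": self.nucleus_ids,
            "x_um": self.positions[:, 0],
            "y_um": self.positions[:, 1],
            "z_um": self.positions[:, 2],
        })
        for ch, values in self.intensities.items():
            df[CHANNEL_PREFIX + ch] = values
        for name, values in self.labels.items():
            df[name] = values
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id=None,
                   metadata=None) -> "SampleCloud":
        if sample_id is None:
            ids = df["sample_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds multiple samples; pass sample_id")
            sample_id = ids[0]
            df = df[df["sample_id"] == sample_id]
        intensities = {
            c[len(CHANNEL_PREFIX):]: df[c].to_numpy(dtype=float)
            for c in df.columns if c.startswith(CHANNEL_PREFIX)
        }
        known = set(ID_COLUMNS) | set(COORD_COLUMNS) | {
            c for c in df.columns if c.startswith(CHANNEL_PREFIX)}
        labels = {c: df[c].to_numpy() for c in df.columns if c not in known}
        return cls(
            sample_id=sample_id,
            nucleus_ids=df["nucleus_id"].to_numpy(),
            positions=df[list(COORD_COLUMNS)].to_numpy(dtype=float),
            intensities=intensities,
            metadata=metadata or {},
            labels=labels,
        )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeometryConfig:
    edge_length: float = 100.0  # µm, bounding dodecahedron edge


@dataclass
class FeatureConfig:
    shell_radii: tuple = (10.0, 20.0, 30.0)  # µm, concentric shells
    include_polarity: bool = True
    per_sample_zscore: bool = False  # default pools across samples

    def __post_init__(self):
        r = tuple(float(x) for x in self.shell_radii)
        if any(b <= a for a, b in zip((0.0,) + r, r)):
            raise ValueError("shell radii must be strictly increasing, > 0")
        self.shell_radii = r


@dataclass
class ClusteringConfig:
    n_motifs: int = 11
    n_archetypes: int = 2
    archetype_metric: str = "euclidean"  # or "correlation"
    covariance_floor: float = 1e-6
    em_max_iter: int = 500
    em_tol: float = 1e-4
    kmeans_restarts: int = 10

    def __post_init__(self):
        if self.n_motifs < 1 or self.n_archetypes < 1:
            raise ValueError("component counts must be >= 1")


@dataclass
class PairCorrelationConfig:
    r_max: float = 50.0  # µm
    dr: float = 2.0  # µm bin width


@dataclass
class EmbeddingConfig:
    pre_perplexities: tuple = (50.0, 500.0)
    full_perplexity: float = 30.0
    pre_sample: int = 25_000
    pre_schedule: tuple = ((250, 12.0, 0.5), (750, 1.0, 0.8))
    full_schedule: tuple = ((500, 4.0, 0.5), (500, 3.0, 0.8))
    projection_iters: int = 500
    projection_exaggeration: float = 3.0
    projection_momentum: float = 0.8


@dataclass
class RunConfig:
    """Aggregated run parameters; every stochastic stage takes `seed`."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    gr: PairCorrelationConfig = field(default_factory=PairCorrelationConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        sections = {
            "geometry": GeometryConfig,
            "features": FeatureConfig,
            "clustering": ClusteringConfig,
            "gr": PairCorrelationConfig,
            "embedding": EmbeddingConfig,
        }
        for key, klass in sections.items():
            if key in d:
                sub = d[key]
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in sub.items()}
                kwargs[key] = klass(**sub)
        if "seed" in d:
            kwargs["seed"] = d["seed"]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
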