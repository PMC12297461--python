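"""Synthetic point clouds, intensity mixtures and toy volumes.

The generators emulate the two organisational archetypes seen in embryonic
tissue: an *amorphous* phenotype (dense, isotropic, irregular — modelled as
a hard-core random point process) and a *crystalline* phenotype (low
density, anisotropic, regular — modelled as an axis-scaled jittered
lattice).  Every generator is deterministic under a fixed seed and emits
ground-truth labels, so the whole analysis pipeline is testable without any
imaging data.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import SampleCloud

logger = logging.getLogger(__name__)

# default embryo composition: ellipsoidal "embryo" with an amorphous and a
# crystalline compartment separated by roughly one cell diameter
EMBRYO_DEFAULTS = dict(
    semi_axes=(150.0, 100.0, 100.0),  # µm
    amorphous_intensity=6e-3,  # nuclei / µm^3
    amorphous_hardcore=2.0,  # µm minimum nuclear separation
    lattice_spacing=9.0,  # µm
    lattice_axis_scales=(1.0, 1.0, 1.6),
    lattice_jitter_sd=0.9,  # µm
    gap=6.0,  # µm between the two compartments
    interior_margin=30.0,  # µm from the surface counting as interior
)


def _check_region(region):
    kind, params = region
    if kind not in ("box", "ball", "ellipsoid"):
        raise ValueError(f"unknown region kind {kind!r}")
    return kind, np.asarray(params, dtype=float)


def _region_volume(kind, params) -> float:
    if kind == "box":
        return float(np.prod(params))
    if kind == "ball":
        return 4.0 / 3.0 * np.pi * float(params) ** 3
    return 4.0 / 3.0 * np.pi * float(np.prod(params))  # ellipsoid


def _region_bounds(kind, params):
    if kind == "box":
        return np.zeros(3), params
    if kind == "ball":
        r = float(params)
        return -np.array([r, r, r]), np.array([r, r, r])
    return -params, params


def _region_contains(kind, params, pts):
    if kind == "box":
        return ((pts >= 0) & (pts <= params)).all(axis=1)
    if kind == "ball":
        return (pts ** 2).sum(axis=1) <= float(params) ** 2
    return ((pts / params) ** 2).sum(axis=1) <= 1.0


def make_lattice(spacing: float, dims=(5, 5, 5), jitter_sd: float = 0.0,
                 axis_scales=(1.0, 1.0, 1.0), seed: int = 0,
                 sample_id="lattice") -> SampleCloud:
    """Axis-scaled rectangular lattice with Gaussian jitter (crystalline).

    ``axis_scales`` stretches the lattice per axis, producing the anisotropy
    of the crystalline phenotype; ``jitter_sd`` (µm, must stay below
    spacing/4) adds isotropic positional noise.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter_sd >= spacing / 4.0:
        raise ValueError("jitter_sd must be below spacing/4")
    rng = np.random.default_rng(seed)
    axes = [np.arange(d) * spacing * s
            for d, s in zip(dims, np.asarray(axis_scales, dtype=float))]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = grid + rng.normal(0.0, jitter_sd, grid.shape) if jitter_sd else grid
    return SampleCloud(
        sample_id=sample_id,
        nucleus_ids=np.arange(len(pts)),
        positions=pts,
        metadata={"generator": "lattice", "seed": seed},
        labels={"population": np.full(len(pts), "crystalline", dtype=object)},
    )


def _hardcore_sample(rng, n_target, kind, params, hardcore,
                     predicate=None, max_attempts_factor=200):
    """Random sequential adsorption with an exact minimum-distance guarantee."""
    lo, hi = _region_bounds(kind, params)
    accepted = []
    grid = {}
    cell = max(hardcore, 1e-6)

    def _key(p):
        return tuple(np.floor(p / cell).astype(int))

    attempts = 0
    budget = max_attempts_factor * max(n_target, 1)
    while len(accepted) < n_target and attempts < budget:
        attempts += 1
        p = rng.uniform(lo, hi)
        if not _region_contains(kind, params, p[None])[0]:
            continue
        if predicate is not None and not predicate(p):
            continue
        if hardcore > 0:
            k = _key(p)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        for q in grid.get((k[0] + dx, k[1] + dy, k[2] + dz),
                                          ()):
                            if np.dot(p - q, p - q) < hardcore ** 2:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            grid.setdefault(k, []).append(p)
        accepted.append(p)
    if len(accepted) < n_target:
        raise RuntimeError(
            f"hard-core placement infeasible: {len(accepted)}/{n_target} "
            f"points after {attempts} attempts")
    return np.asarray(accepted)


def make_amorphous(intensity: float, region=("box", (100.0, 100.0, 100.0)),
                   hardcore: float = 0.0, seed: int = 0,
                   sample_id="amorphous") -> SampleCloud:
    """Hard-core random point cloud at a target intensity (amorphous).

    ``intensity`` is the expected density in nuclei/µm³; ``hardcore`` the
    exact minimum pairwise separation in µm.  With ``hardcore=0`` this is a
    homogeneous Poisson process.
    """
    kind, params = _check_region(region)
    # hardcore is a minimum separation, i.e. a sphere *diameter*; random
    # sequential adsorption jams near packing fraction 0.38
    packing = intensity * np.pi / 6.0 * hardcore ** 3
    if packing >= 0.3:
        raise ValueError(
            f"infeasible packing fraction {packing:.2f} (needs < 0.3)")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * _region_volume(kind, params))
    pts = _hardcore_sample(rng, n, kind, params, hardcore)
    return SampleCloud(
        sample_id=sample_id,
        nucleus_ids=np.arange(len(pts)),
        positions=pts,
        metadata={"generator": "amorphous", "seed": seed,
                  "intensity": intensity, "hardcore": hardcore},
        labels={"population": np.full(len(pts), "amorphous", dtype=object)},
    )


def make_embryo(seed: int = 0, sample_id="embryo", **overrides) -> SampleCloud:
    """Composite two-population fixture inside an ellipsoidal container.

    An amorphous compartment (hard-core cloud) fills the half-ellipsoid
    x < -gap/2 and a crystalline compartment (jittered, axis-scaled lattice)
    fills x > +gap/2.  Per-point ground truth: ``population`` label and an
    ``interior`` flag for points at least ``interior_margin`` µm from the
    container surface (estimated radially).
    """
    p = dict(EMBRYO_DEFAULTS)
    unknown = set(overrides) - set(p)
    if unknown:
        raise TypeError(f"unknown embryo parameters {sorted(unknown)}")
    p.update(overrides)
    if p["gap"] < 0:
        raise ValueError("compartments overlap (negative gap)")
    semi = np.asarray(p["semi_axes"], dtype=float)
    rng = np.random.default_rng(seed)

    # amorphous half: x <= -gap/2
    def in_amorphous(pt):
        return pt[0] <= -p["gap"] / 2.0

    # Monte-Carlo estimate of the compartment volume (deterministic by seed)
    probe = rng.uniform(-semi, semi, (20000, 3))
    inside = _region_contains("ellipsoid", semi, probe)
    frac_am = np.mean(inside & (probe[:, 0] <= -p["gap"] / 2.0))
    vol_am = frac_am * 8.0 * np.prod(semi)
    n_am = rng.poisson(p["amorphous_intensity"] * vol_am)
    pts_am = _hardcore_sample(rng, n_am, "ellipsoid", semi,
                              p["amorphous_hardcore"],
                              predicate=in_amorphous)

    # crystalline half: jittered lattice covering the x >= +gap/2 part
    spacing = p["lattice_spacing"]
    scales = np.asarray(p["lattice_axis_scales"], dtype=float)
    step = spacing * scales
    counts = np.ceil(2 * semi / step).astype(int) + 1
    axes = [np.arange(c) * s - e for c, s, e in zip(counts, step, semi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid + rng.normal(0.0, p["lattice_jitter_sd"], grid.shape)
    keep = _region_contains("ellipsoid", semi, grid) & \
        (grid[:, 0] >= p["gap"] / 2.0)
    pts_cr = grid[keep]

    pts = np.vstack([pts_am, pts_cr])
    population = np.array(["amorphous"] * len(pts_am)
                          + ["crystalline"] * len(pts_cr), dtype=object)
    # radial estimate of distance to the container surface
    rho = np.sqrt(((pts / semi) ** 2).sum(axis=1))
    r = np.linalg.norm(pts, axis=1)
    dist_surface = np.where(rho > 1e-12, (1.0 / np.maximum(rho, 1e-12) - 1.0)
                            * r, semi.min())
    interior = dist_surface >= p["interior_margin"]
    logger.info("embryo fixture: %d amorphous + %d crystalline nuclei "
                "(%d interior)", len(pts_am), len(pts_cr), interior.sum())
    return SampleCloud(
        sample_id=sample_id,
        nucleus_ids=np.arange(len(pts)),
        positions=pts,
        metadata={"generator": "embryo", "seed": seed, **p},
        labels={"population": population, "interior": interior,
                "dist_surface_um": dist_surface},
    )


def make_intensity_mixture(n: int, noise_mean: float, noise_sd: float,
                           signal_mean: float, signal_sd: float,
                           signal_fraction: float, seed: int = 0):
    """Labelled draws from a two-component Gaussian intensity mixture.

    Returns ``(values, labels)`` with labels 0 = noise, 1 = signal.
    """
    if signal_mean <= noise_mean:
        raise ValueError("signal_mean must exceed noise_mean")
    if noise_sd <= 0 or signal_sd <= 0:
        raise ValueError("standard deviations must be positive")
    if not 0.0 <= signal_fraction <= 1.0:
        raise ValueError("signal_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = (rng.uniform(size=n) < signal_fraction).astype(int)
    values = np.where(
        labels == 1,
        rng.normal(signal_mean, signal_sd, n),
        rng.normal(noise_mean, noise_sd, n),
    )
    return values, labels


def make_blob_image(points, amplitudes, blob_sd: float, shape):
    """Sum of isotropic Gaussian blobs on a zero background (3D volume)."""
    shape = tuple(int(s) for s in shape)
    pts = np.asarray(points, dtype=float)
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(pts),))
    vol = np.zeros(shape, dtype=float)
    if len(pts) == 0:
        return vol
    reach = int(np.ceil(4 * blob_sd))
    for p, a in zip(pts, amps):
        if a == 0:
            continue
        lo = np.maximum(np.floor(p - reach).astype(int), 0)
        hi = np.minimum(np.ceil(p + reach).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                 indexing="ij")
        d2 = ((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2)
        vol[zz, yy, xx] += a * np.exp(-d2 / (2 * blob_sd ** 2))
    return vol


def nearest_neighbour_distances(points) -> np.ndarray:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return d[:, 1]
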