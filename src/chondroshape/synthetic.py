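"""Synthetic inputs with known ground truth for the clone-geometry pipeline.

Emulates multicolour lineage-tracing data: clone-labelled 3D cell tables
inside a slab whose two faces serve as the opposing surface patches,
with controllable clone envelope (columnar at a planted tilt, or
spherical), orientation jitter and clone-size distribution; plus
surface-patch pairs at a known dihedral and von Mises-Fisher direction
samples with a matching concentration estimator.  Every generator is
deterministic under its seed and returns a machine-readable truth record
separate from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import uniform_direction, vonmises_fisher

from .clone_metrics import SurfacePatchPair


@dataclass
class CloneFieldSpec:
    """Recipe for a clone-labelled slab of cells.

    ``column_tilt_deg`` is the planted true alpha of columnar envelopes;
    ``orientation_noise_deg`` adds per-clone angular jitter around it.
    Clone sizes are Poisson around ``cells_per_clone_mean``, truncated at
    a minimum of 2 cells so every clone admits an axis.
    """

    geometry: Literal["flat_slab"] = "flat_slab"
    n_clones: int = 100
    cells_per_clone_mean: float = 5.0
    envelope: Literal["columnar", "spherical"] = "columnar"
    column_tilt_deg: float = 0.0
    orientation_noise_deg: float = 0.0
    cell_spacing: float = 1.0
    slab_thickness: float = 8.0
    blob_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.column_tilt_deg <= 90.0:
            raise ValueError("column tilt must lie in [0, 90] degrees")
        if self.orientation_noise_deg < 0:
            raise ValueError("orientation noise must be non-negative")
        if self.cell_spacing > self.slab_thickness:
            raise ValueError("cell spacing incompatible with slab thickness")


@dataclass
class DirectionSampleSpec:
    """Recipe for a unit-vector sample of known vMF concentration."""

    b_true: float = 0.0
    mean_dir: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        self.mean_dir = np.asarray(self.mean_dir, dtype=float)
        self.mean_dir = self.mean_dir / np.linalg.norm(self.mean_dir)


def _tilted_direction(tilt_deg: float, azimuth_rad: float) -> np.ndarray:
    t = np.radians(tilt_deg)
    return np.array(
        [np.sin(t) * np.cos(azimuth_rad), np.sin(t) * np.sin(azimuth_rad), np.cos(t)]
    )


def generate_clone_field(
    spec: CloneFieldSpec,
) -> tuple[pd.DataFrame, SurfacePatchPair, dict]:
    """Clone-labelled cell table + slab surface patches + truth record.

    Clones sit on a lateral grid inside a slab with faces at z = 0 and
    z = thickness (the surface patches, hence true beta = 0 for the flat
    slab).  Columnar envelopes stack cells one spacing apart along a
    direction at the planted tilt from the slab normal, with per-clone
    angular jitter; spherical envelopes are isotropic Gaussian blobs
    centred mid-slab.
    """
    rng = np.random.default_rng(spec.seed)
    n_side = int(np.ceil(np.sqrt(spec.n_clones)))
    pitch = max(4.0 * spec.cell_spacing, 3.0 * spec.blob_sigma)
    rows = []
    truth_clones = []
    cell_id = 0
    for k in range(spec.n_clones):
        gx = (k % n_side) * pitch
        gy = (k // n_side) * pitch
        n_cells = max(2, int(rng.poisson(spec.cells_per_clone_mean)))
        if spec.envelope == "columnar":
            azimuth = rng.uniform(0.0, 2.0 * np.pi)
            tilt = spec.column_tilt_deg
            if spec.orientation_noise_deg > 0:
                tilt = float(np.clip(
                    tilt + rng.normal(0.0, spec.orientation_noise_deg), 0.0, 90.0
                ))
            direction = _tilted_direction(tilt, azimuth)
            # keep the column inside the slab
            max_len = (n_cells - 1) * spec.cell_spacing * abs(direction[2])
            z0 = rng.uniform(0.0, max(1e-9, spec.slab_thickness - max_len))
            base = np.array([gx, gy, z0])
            pts = base + np.arange(n_cells)[:, None] * spec.cell_spacing * direction
            true_alpha = tilt
        else:
            centre = np.array([gx, gy, spec.slab_thickness / 2.0])
            pts = centre + rng.normal(0.0, spec.blob_sigma, size=(n_cells, 3))
            true_alpha = None
        for p in pts:
            rows.append((cell_id, k, p[0], p[1], p[2], spec.cell_spacing / 2.0, 0.0))
            cell_id += 1
        truth_clones.append({"clone_id": k, "n_cells": n_cells, "true_alpha_deg": true_alpha})

    cells = pd.DataFrame(
        rows, columns=["id", "clone_id", "x", "y", "z", "radius", "birth_time"]
    )
    extent = n_side * pitch
    gx, gy = np.meshgrid(np.linspace(-pitch, extent, 8), np.linspace(-pitch, extent, 8))
    bottom = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    top = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, spec.slab_thickness)])
    pair = SurfacePatchPair(patch_a=bottom, patch_b=top)
    truth = {
        "envelope": spec.envelope,
        "true_beta_deg": 0.0,
        "column_tilt_deg": spec.column_tilt_deg if spec.envelope == "columnar" else None,
        "orientation_noise_deg": spec.orientation_noise_deg,
        "clones": truth_clones,
        "seed": spec.seed,
    }
    return cells, pair, truth


def generate_surface_pair(
    dihedral_deg: float,
    n_points: int = 25,
    noise: float = 0.0,
    seed: int = 0,
    patch_size: float = 10.0,
    separation: float = 5.0,
) -> SurfacePatchPair:
    """Two planar point clouds meeting at a known dihedral angle.

    Patch A lies in the z = 0 plane; patch B is rotated about the x axis
    by the dihedral and lifted by ``separation``.  Gaussian out-of-plane
    noise is added to both patches.
    """
    if not 0.0 <= dihedral_deg <= 90.0:
        raise ValueError("dihedral must lie in [0, 90] degrees")
    if n_points < 3:
        raise ValueError("need at least 3 points per patch")
    rng = np.random.default_rng(seed)
    xy_a = rng.uniform(-patch_size / 2, patch_size / 2, size=(n_points, 2))
    xy_b = rng.uniform(-patch_size / 2, patch_size / 2, size=(n_points, 2))
    a = np.column_stack([xy_a, np.zeros(n_points)])
    t = np.radians(dihedral_deg)
    rot = np.array(
        [[1.0, 0.0, 0.0], [0.0, np.cos(t), -np.sin(t)], [0.0, np.sin(t), np.cos(t)]]
    )
    b = np.column_stack([xy_b, np.zeros(n_points)]) @ rot.T
    b[:, 2] += separation
    if noise > 0:
        a[:, 2] += rng.normal(0.0, noise, n_points)
        b += rng.normal(0.0, noise, size=(n_points, 1)) * rot[:, 2]
    return SurfacePatchPair(patch_a=a, patch_b=b)


def generate_directions(spec: DirectionSampleSpec) -> np.ndarray:
    """von Mises-Fisher unit-vector sample (uniform on the sphere at b = 0)."""
    rng = np.random.default_rng(spec.seed)
    if spec.b_true == 0:
        sample = uniform_direction.rvs(3, size=spec.n, random_state=rng)
    else:
        sample = vonmises_fisher.rvs(
            spec.mean_dir, spec.b_true, size=spec.n, random_state=rng
        )
    return np.atleast_2d(sample)


def estimate_concentration(sample: np.ndarray) -> float:
    """Maximum-likelihood vMF concentration (Banerjee et al. approximation).

    b_hat = R(p - R^2) / (1 - R^2) with p = 3 and R the resultant length;
    rotation invariant because it depends only on |mean vector|.
    """
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    r = float(np.linalg.norm(sample.mean(axis=0)))
    r = min(r, 1.0 - 1e-12)
    return r * (3.0 - r**2) / (1.0 - r**2)
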