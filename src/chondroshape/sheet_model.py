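"""Growing-polarised-tissue model of nasal-capsule shape transitions.

A flat trapezoid "canvas" of 1800 triangular finite elements carries
per-vertex growth factors (POL, MID, CHEEKS), is deformed into a
half-dome starting shape over a 12-step setup phase, and then grows from
step 13 on.  Two interconnected networks drive growth: the polarity
regulatory network (PRN) orients growth parallel to the midline through
the gradient of the POLARISER factor (POL, 1 at the proximal base, 0 at
the distal tip), and the growth-rate regulatory network (KRN) sets
specified growth rates through the promotion/inhibition primitives

    pro(n, x) = 1 + n*x        inh(n, x) = 1 / (1 + n*x)

with isotropic rate K = 0.05 * inh(100, iCHEEKS) or, in anisotropic
mode, Kpar = 0.05 * inh(100, iCHEEKS) parallel to the polarity field and
Kper = 0 perpendicular to it.  CHEEKS paints two slow-growing lateral
zones.  Because the canvas is connected, the specified growth differs
from the resultant growth: each step updates per-edge rest lengths and
then relaxes an edge-spring + dihedral-bending energy quasi-statically,
so differential growth produces lateral bends, grooves and flattening.

Variants: ``fixed_midline`` anchors the midline (MID) vertices in the
z-plane (the nasal septum as an anchoring ridge), ``free_midline`` keeps
the central groove but lets the midline deform, ``no_midline`` removes
both the groove and the anchor.  The model is fully deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from scipy.optimize import minimize

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# KRN primitives


def pro(n: float, x: float) -> float:
    """Promotion primitive of the growth-rate network: 1 + n*x."""
    return 1.0 + n * x


def inh(n, x):
    """Inhibition primitive of the growth-rate network: 1 / (1 + n*x).

    Accepts scalars or arrays; raises on the pole n*x = -1.
    """
    denom = 1.0 + np.multiply(n, x)
    if np.any(np.isclose(denom, 0.0)):
        raise ZeroDivisionError("inh(n, x) undefined at n*x = -1")
    return np.divide(1.0, denom) if np.ndim(denom) else 1.0 / denom


#: baseline specified growth rate per step where CHEEKS is absent
BASE_GROWTH_RATE = 0.05
#: inhibition strength of the CHEEKS factor in the KRN
CHEEKS_INHIBITION = 100.0


# ---------------------------------------------------------------------------
# configuration and canvas


@dataclass
class ElasticParams:
    """Edge-spring + hinge-bending elasticity of the sheet."""

    stretch_stiffness: float = 1.0
    bending_stiffness: float = 1e-3
    tolerance: float = 1e-6     # max residual force (projected gradient)
    max_iterations: int = 3000


@dataclass
class ModelConfig:
    """Full configuration of one run (all deterministic)."""

    variant: Literal["fixed_midline", "free_midline", "no_midline"] = "fixed_midline"
    growth_mode: Literal["isotropic", "anisotropic"] = "isotropic"
    cheeks_enabled: bool = True
    n_setup_steps: int = 12
    growth_start_step: int = 13
    n_growth_steps: int = 15
    elastic: ElasticParams = dc_field(default_factory=ElasticParams)
    # trapezoid canvas: base along x, midline along y
    base_width: float = 1.0
    tip_width: float = 0.6
    height: float = 1.2
    nx: int = 30               # quads across; 2*nx*ny triangles
    ny: int = 30
    # starting-shape geometry (setup-phase target)
    dome_amplitude: float = 0.25
    groove_sigma: float = 0.25
    # CHEEKS slow-zone bands
    cheeks_center_u: float = 0.6
    cheeks_sigma_u: float = 0.12
    cheeks_center_s: float = 0.5
    cheeks_sigma_s: float = 0.15
    cheeks_distal_offset: float = 0.1   # free_midline: bands offset distally
    pin_base: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("fixed_midline", "free_midline", "no_midline"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.growth_mode not in ("isotropic", "anisotropic"):
            raise ConfigurationError(f"unknown growth mode {self.growth_mode!r}")
        if self.n_growth_steps < 0:
            raise ConfigurationError("n_growth_steps must be >= 0")
        if min(self.base_width, self.tip_width, self.height) <= 0:
            raise ConfigurationError("canvas dimensions must be positive")


@dataclass
class Canvas:
    """Triangulated growing sheet with per-vertex factors and rest geometry.

    ``uv`` stores material coordinates per vertex: u in [-1, 1] laterally
    (0 on the midline) and s in [0, 1] proximo-distally (0 at the base).
    Elements are never subdivided; only vertices move and rest lengths
    grow.
    """

    vertices: np.ndarray           # (nv, 3)
    triangles: np.ndarray          # (nt, 3)
    factors: dict[str, np.ndarray]
    uv: np.ndarray                 # (nv, 2): columns (u, s)
    nx: int
    ny: int
    edges: np.ndarray              # (ne, 2)
    edge_tris: np.ndarray          # (ne, 2), -1 for boundary
    rest_lengths: np.ndarray       # (ne,)
    hinges: np.ndarray             # (nh, 4): i0, i1, opposite_a, opposite_b
    rest_dihedrals: np.ndarray     # (nh,)
    z_anchored: np.ndarray         # (nv,) bool
    base_ref: np.ndarray | None = None   # reference base-row positions for pinning

    def copy(self) -> "Canvas":
        return Canvas(
            vertices=self.vertices.copy(),
            triangles=self.triangles,
            factors={k: v.copy() for k, v in self.factors.items()},
            uv=self.uv,
            nx=self.nx,
            ny=self.ny,
            edges=self.edges,
            edge_tris=self.edge_tris,
            rest_lengths=self.rest_lengths.copy(),
            hinges=self.hinges,
            rest_dihedrals=self.rest_dihedrals.copy(),
            z_anchored=self.z_anchored.copy(),
            base_ref=None if self.base_ref is None else self.base_ref.copy(),
        )

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def row_indices(self, j: int) -> np.ndarray:
        return np.arange(j * (self.nx + 1), (j + 1) * (self.nx + 1))

    @property
    def base_row(self) -> np.ndarray:
        return self.row_indices(0)

    @property
    def tip_row(self) -> np.ndarray:
        return self.row_indices(self.ny)


@dataclass
class GrowthRates:
    """Per-triangle specified growth; isotropic K or (Kpar, Kper) + polarity."""

    mode: str
    k_iso: np.ndarray | None = None
    k_par: np.ndarray | None = None
    k_per: np.ndarray | None = None
    polarity: np.ndarray | None = None  # (nt, 3) unit vectors, NaN if unpolarized


@dataclass
class ShapeMetrics:
    """Shape descriptors of a grown canvas relative to the post-setup shape.

    lateral_bend_angle is the signed mean dihedral (degrees) across the
    cheek-zone boundary: positive when the lateral flaps fold toward the
    concave (ventral, -z) side.  groove_depth is the z-drop of the
    midline below the flank ridge line, as a change from the reference.
    longitudinal_bend is the dorsal (+z) rotation of the distal midline
    profile relative to the reference: positive = tip curls dorsally,
    negative = inverted (ventral) bend.
    """

    elongation_ratio: float
    lateral_bend_angle_deg: float
    groove_depth: float
    flatness: float
    longitudinal_bend_deg: float = 0.0
    #: mean per-cross-section z-extent over lateral extent; unlike the
    #: bounding-box flatness it is insensitive to longitudinal curling of
    #: the whole structure and measures the flattening of the roof profile
    cross_section_flatness: float = 0.0


# ---------------------------------------------------------------------------
# mesh construction


def _mesh_topology(nx: int, ny: int) -> tuple[np.ndarray, np.ndarray]:
    """Grid triangulation of an (nx x ny)-quad sheet, mirror-symmetric in x."""
    def vid(i: int, j: int) -> int:
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i, j + 1), vid(i + 1, j + 1)
            if i < nx // 2:          # diagonal a-d on the left half
                tris.append((a, b, d))
                tris.append((a, d, c))
            else:                    # mirrored diagonal b-c on the right half
                tris.append((a, b, c))
                tris.append((b, d, c))
    triangles = np.array(tris, dtype=int)
    uv = None
    return triangles, uv


def _edges_and_hinges(triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    edge_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for t, (a, b, c) in enumerate(triangles):
        for v0, v1, opp in ((a, b, c), (b, c, a), (c, a, b)):
            key = (min(v0, v1), max(v0, v1))
            edge_map.setdefault(key, []).append((t, opp))
    edges = np.array(sorted(edge_map), dtype=int)
    edge_tris = np.full((len(edges), 2), -1, dtype=int)
    hinges = []
    for e, key in enumerate(sorted(edge_map)):
        adj = edge_map[key]
        for slot, (t, _) in enumerate(adj[:2]):
            edge_tris[e, slot] = t
        if len(adj) == 2:
            hinges.append((key[0], key[1], adj[0][1], adj[1][1]))
    return edges, edge_tris, np.array(hinges, dtype=int)


def build_canvas(config: ModelConfig | None = None) -> Canvas:
    """Flat trapezoid canvas with painted factors.

    The base (proximal) edge is parallel to x, the midline to y.  POL is
    linear: 1 on the base row, 0 at the tip.  MID marks the midline
    vertex column.  CHEEKS paints two smooth slow-zone bands either side
    of the midline (offset distally in the free-midline variant),
    symmetric under x-mirror.
    """
    config = config or ModelConfig()
    nx, ny = config.nx, config.ny
    if 2 * nx * ny != 1800:
        raise ConfigurationError(
            f"mesh resolution {nx}x{ny} yields {2 * nx * ny} elements, not 1800"
        )
    if nx % 2 != 0:
        raise ConfigurationError("nx must be even so a vertex column lies on the midline")

    triangles, _ = _mesh_topology(nx, ny)
    ii, jj = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1))
    ii, jj = ii.ravel(), jj.ravel()
    u = 2.0 * ii / nx - 1.0
    s = jj / ny
    width = config.base_width + (config.tip_width - config.base_width) * s
    vertices = np.column_stack([u * width / 2.0, s * config.height, np.zeros_like(u)])
    uv = np.column_stack([u, s])

    pol = 1.0 - s
    mid = (np.abs(u) < 1e-12).astype(float)
    s_c = config.cheeks_center_s
    if config.variant == "free_midline":
        s_c = s_c + config.cheeks_distal_offset
    cheeks = (
        np.exp(-((np.abs(u) - config.cheeks_center_u) ** 2) / (2 * config.cheeks_sigma_u**2))
        * np.exp(-((s - s_c) ** 2) / (2 * config.cheeks_sigma_s**2))
    )
    cheeks[cheeks < 1e-4] = 0.0

    edges, edge_tris, hinges = _edges_and_hinges(triangles)
    rest_lengths = np.linalg.norm(vertices[edges[:, 1]] - vertices[edges[:, 0]], axis=1)
    rest_dihedrals = np.zeros(len(hinges))

    return Canvas(
        vertices=vertices,
        triangles=triangles,
        factors={"POL": pol, "MID": mid, "CHEEKS": cheeks},
        uv=uv,
        nx=nx,
        ny=ny,
        edges=edges,
        edge_tris=edge_tris,
        rest_lengths=rest_lengths,
        hinges=hinges,
        rest_dihedrals=rest_dihedrals,
        z_anchored=np.zeros(len(vertices), dtype=bool),
    )


# ---------------------------------------------------------------------------
# setup phase


def _setup_target_z(canvas: Canvas, config: ModelConfig) -> np.ndarray:
    """z of the starting shape: an arched vault over the trapezoid.

    Groove variants (fixed/free midline) subtract a central Gaussian so
    the midline sits at z = 0 between two flank ridges (dome minus groove
    of equal amplitude); the no-midline variant is a plain dome with the
    midline on top.  The cross-section is scaled with the local trapezoid
    width so the vault tapers toward the tip.
    """
    u = canvas.uv[:, 0]
    s = canvas.uv[:, 1]
    width = config.base_width + (config.tip_width - config.base_width) * s
    taper = width / config.base_width
    dome = np.cos(np.pi * u / 2.0)
    if config.variant in ("fixed_midline", "free_midline"):
        profile = dome - np.exp(-(u**2) / (2 * config.groove_sigma**2))
    else:
        profile = dome
    return config.dome_amplitude * profile * taper


def setup_phase(canvas: Canvas, config: ModelConfig) -> Canvas:
    """Deform the flat trapezoid into the starting shape over 12 steps.

    The deformation is a prescribed parametric mapping (linear in-step
    interpolation of the target z); factors are carried unchanged.  At
    the end the rest geometry is re-baselined so the starting shape is
    stress-free, the base row is stored as the rigid-body pinning
    reference, and (fixed_midline) the MID vertices become z-anchored.
    """
    canvas = canvas.copy()
    z_target = _setup_target_z(canvas, config)
    for step in range(1, config.n_setup_steps + 1):
        canvas.vertices[:, 2] = z_target * (step / config.n_setup_steps)
    # stress-free reference = starting shape
    canvas.rest_lengths = np.linalg.norm(
        canvas.vertices[canvas.edges[:, 1]] - canvas.vertices[canvas.edges[:, 0]], axis=1
    )
    canvas.rest_dihedrals = _dihedrals(canvas.vertices, canvas.hinges)
    canvas.base_ref = canvas.vertices[canvas.base_row].copy()
    if config.variant == "fixed_midline":
        canvas.z_anchored = canvas.factors["MID"] > 0.5
        canvas.vertices[canvas.z_anchored, 2] = 0.0
    return canvas


# ---------------------------------------------------------------------------
# polarity (PRN) and specified growth (KRN)


def compute_polarity(canvas: Canvas) -> np.ndarray:
    """Per-triangle unit in-plane gradient of the POLARISER factor.

    Triangles with (numerically) zero gradient are unpolarized and get
    NaN vectors.
    """
    pol = canvas.factors["POL"]
    tri = canvas.triangles
    p0, p1, p2 = (canvas.vertices[tri[:, k]] for k in range(3))
    f0, f1, f2 = (pol[tri[:, k]] for k in range(3))
    n = np.cross(p1 - p0, p2 - p0)
    nsq = np.einsum("ij,ij->i", n, n)
    # linear finite-element gradient of the interpolated field
    grad = (
        (f1 - f0)[:, None] * np.cross(n, p0 - p2)
        + (f2 - f0)[:, None] * np.cross(n, p1 - p0)
    ) / nsq[:, None]
    mag = np.linalg.norm(grad, axis=1)
    out = np.full_like(grad, np.nan)
    ok = mag > 1e-12
    out[ok] = grad[ok] / mag[ok, None]
    return out


def triangle_factor(canvas: Canvas, name: str) -> np.ndarray:
    """Per-triangle factor value: arithmetic mean of its three vertices."""
    return canvas.factors[name][canvas.triangles].mean(axis=1)


def specified_growth(
    canvas: Canvas,
    mode: str = "isotropic",
    cheeks_enabled: bool = True,
) -> GrowthRates:
    """KRN: specified per-triangle growth rates.

    Isotropic: K = 0.05 * inh(100, iCHEEKS).  Anisotropic: Kpar with the
    same law along the polarity field, Kper = 0 across it.  Disabling
    the cheek zones treats iCHEEKS as 0 everywhere.
    """
    icheeks = triangle_factor(canvas, "CHEEKS")
    if not cheeks_enabled:
        icheeks = np.zeros_like(icheeks)
    k = BASE_GROWTH_RATE * inh(CHEEKS_INHIBITION, icheeks)
    if mode == "isotropic":
        return GrowthRates(mode=mode, k_iso=k)
    if mode == "anisotropic":
        return GrowthRates(
            mode=mode, k_par=k, k_per=np.zeros_like(k), polarity=compute_polarity(canvas)
        )
    raise ConfigurationError(f"unknown growth mode {mode!r}")


# ---------------------------------------------------------------------------
# elastic energy


def _dihedrals(vertices: np.ndarray, hinges: np.ndarray) -> np.ndarray:
    if len(hinges) == 0:
        return np.zeros(0)
    x0, x1, x2, x3 = (vertices[hinges[:, k]] for k in range(4))
    e = x1 - x0
    n1 = np.cross(x1 - x0, x2 - x0)
    n2 = np.cross(x3 - x0, x1 - x0)
    ehat = e / np.linalg.norm(e, axis=1, keepdims=True)
    n1h = n1 / np.linalg.norm(n1, axis=1, keepdims=True)
    n2h = n2 / np.linalg.norm(n2, axis=1, keepdims=True)
    sin = np.einsum("ij,ij->i", np.cross(n1h, n2h), ehat)
    cos = np.einsum("ij,ij->i", n1h, n2h)
    return np.arctan2(sin, cos)


def _energy_and_grad(
    flat: np.ndarray,
    canvas: Canvas,
    ks: float,
    kb: float,
) -> tuple[float, np.ndarray]:
    """Spring + hinge-bending energy and its analytic gradient."""
    x = flat.reshape(-1, 3)
    grad = np.zeros_like(x)

    e0, e1 = canvas.edges[:, 0], canvas.edges[:, 1]
    d = x[e1] - x[e0]
    length = np.linalg.norm(d, axis=1)
    stretch = length - canvas.rest_lengths
    energy = 0.5 * ks * float(np.dot(stretch, stretch))
    f = (ks * stretch / length)[:, None] * d
    np.add.at(grad, e1, f)
    np.add.at(grad, e0, -f)

    h = canvas.hinges
    if len(h):
        x0, x1, x2, x3 = x[h[:, 0]], x[h[:, 1]], x[h[:, 2]], x[h[:, 3]]
        e = x1 - x0
        le = np.linalg.norm(e, axis=1)
        n1 = np.cross(x1 - x0, x2 - x0)
        n2 = np.cross(x3 - x0, x1 - x0)
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        n1h = n1 / np.sqrt(n1sq)[:, None]
        n2h = n2 / np.sqrt(n2sq)[:, None]
        sin = np.einsum("ij,ij->i", np.cross(n1h, n2h), e / le[:, None])
        cos = np.einsum("ij,ij->i", n1h, n2h)
        theta = np.arctan2(sin, cos)
        diff = np.arctan2(
            np.sin(theta - canvas.rest_dihedrals), np.cos(theta - canvas.rest_dihedrals)
        )
        energy += kb * float(np.dot(diff, diff))
        coef = 2.0 * kb * diff
        a1 = n1 / n1sq[:, None]
        a2 = n2 / n2sq[:, None]
        # dtheta/dx (verified against finite differences)
        g2 = -le[:, None] * a1
        g3 = -le[:, None] * a2
        dot12 = np.einsum("ij,ij->i", x1 - x2, e) / le
        dot13 = np.einsum("ij,ij->i", x1 - x3, e) / le
        dot02 = np.einsum("ij,ij->i", x0 - x2, e) / le
        dot03 = np.einsum("ij,ij->i", x0 - x3, e) / le
        g0 = dot12[:, None] * a1 + dot13[:, None] * a2
        g1 = -dot02[:, None] * a1 - dot03[:, None] * a2
        np.add.at(grad, h[:, 0], coef[:, None] * g0)
        np.add.at(grad, h[:, 1], coef[:, None] * g1)
        np.add.at(grad, h[:, 2], coef[:, None] * g2)
        np.add.at(grad, h[:, 3], coef[:, None] * g3)

    return energy, grad.ravel()


def relax(canvas: Canvas, config: ModelConfig) -> Canvas:
    """Quasi-static elastic relaxation toward the current rest geometry.

    Minimises the spring + bending energy with L-BFGS-B; z-anchored
    vertices are held at z = 0 through equal bounds.  Rigid-body modes
    are then removed by re-pinning the base row (Kabsch alignment to the
    stored post-setup base positions).  Non-convergence logs a warning
    and keeps the best iterate.
    """
    el = config.elastic
    nv = len(canvas.vertices)
    # anchored z dofs are eliminated from the optimisation variables
    free = np.ones((nv, 3), dtype=bool)
    free[canvas.z_anchored, 2] = False
    template = canvas.vertices.copy()
    template[canvas.z_anchored, 2] = 0.0

    def fun(xf: np.ndarray) -> tuple[float, np.ndarray]:
        x = template.copy()
        x[free] = xf
        e, g = _energy_and_grad(x.ravel(), canvas, el.stretch_stiffness, el.bending_stiffness)
        return e, g.reshape(-1, 3)[free]

    res = minimize(
        fun,
        template[free],
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": el.max_iterations,
            "maxfun": 50 * el.max_iterations,
            "maxcor": 20,
            "gtol": el.tolerance,
            "ftol": 1e-16,
            "maxls": 60,
        },
    )
    if not res.success and "ITERATIONS" not in str(res.message).upper():
        logger.warning("relaxation did not converge: %s", res.message)
    x = template
    x[free] = res.x
    canvas.vertices = x
    if config.pin_base and canvas.base_ref is not None:
        _pin_base(canvas)
    return canvas


def _pin_base(canvas: Canvas) -> None:
    """Remove rigid-body drift: rigidly align the base row back onto its
    reference position (rotation + translation, no scaling, so lateral
    base growth is untouched).

    When midline vertices are z-anchored the absolute z = 0 plane is
    already fixed by the constraint, so only the in-plane modes (x-y
    translation, rotation about z) are removed; a z translation would
    fight the anchor.
    """
    p = canvas.vertices[canvas.base_row]
    q = canvas.base_ref
    if np.any(canvas.z_anchored):
        pc = np.array([*p[:, :2].mean(axis=0), 0.0])
        qc = np.array([*q[:, :2].mean(axis=0), 0.0])
        h2 = (p[:, :2] - pc[:2]).T @ (q[:, :2] - qc[:2])
        u, _, vt = np.linalg.svd(h2)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r2 = vt.T @ np.diag([1.0, d]) @ u.T
        rot = np.eye(3)
        rot[:2, :2] = r2
    else:
        pc, qc = p.mean(axis=0), q.mean(axis=0)
        h = (p - pc).T @ (q - qc)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    canvas.vertices = (canvas.vertices - pc) @ rot.T + qc


# ---------------------------------------------------------------------------
# growth


def grow_step(canvas: Canvas, rates: GrowthRates, config: ModelConfig) -> Canvas:
    """One growth step: scale rest edge lengths by the specified growth,
    then relax the connected sheet (specified vs resultant growth)."""
    scale_sum = np.zeros(len(canvas.edges))
    scale_cnt = np.zeros(len(canvas.edges))
    if rates.mode == "isotropic":
        tri_scale = 1.0 + rates.k_iso
        for slot in range(2):
            t = canvas.edge_tris[:, slot]
            ok = t >= 0
            scale_sum[ok] += tri_scale[t[ok]]
            scale_cnt[ok] += 1
    else:
        d = canvas.vertices[canvas.edges[:, 1]] - canvas.vertices[canvas.edges[:, 0]]
        ehat = d / np.linalg.norm(d, axis=1, keepdims=True)
        spar = (1.0 + rates.k_par) ** 2
        sper = (1.0 + rates.k_per) ** 2
        iso_fallback = 1.0 + 0.5 * (rates.k_par + rates.k_per)
        for slot in range(2):
            t = canvas.edge_tris[:, slot]
            ok = t >= 0
            pvec = rates.polarity[t[ok]]
            c2 = np.einsum("ij,ij->i", ehat[ok], np.nan_to_num(pvec)) ** 2
            factor = np.sqrt(spar[t[ok]] * c2 + sper[t[ok]] * (1.0 - c2))
            unpol = np.isnan(pvec[:, 0])
            factor[unpol] = iso_fallback[t[ok]][unpol]
            scale_sum[ok] += factor
            scale_cnt[ok] += 1
    canvas.rest_lengths = canvas.rest_lengths * (scale_sum / scale_cnt)
    return relax(canvas, config)


def run_model(
    config: ModelConfig | None = None,
    record_every: int = 1,
) -> tuple[list[Canvas], list[ShapeMetrics]]:
    """Build, set up (steps 0-12) and grow (from step 13) the canvas.

    Returns the recorded canvas snapshots (index 0 is the post-setup
    starting shape) and the shape metrics of each recorded growth step
    relative to that starting shape.  Fully deterministic.
    """
    config = config or ModelConfig()
    canvas = build_canvas(config)
    canvas = setup_phase(canvas, config)
    reference = canvas.copy()
    snapshots = [reference]
    metrics: list[ShapeMetrics] = []
    for step in range(1, config.n_growth_steps + 1):
        rates = specified_growth(canvas, config.growth_mode, config.cheeks_enabled)
        canvas = grow_step(canvas, rates, config)
        if step % record_every == 0 or step == config.n_growth_steps and step % record_every:
            snapshots.append(canvas.copy())
            metrics.append(shape_metrics(canvas, reference))
    return snapshots, metrics


# ---------------------------------------------------------------------------
# shape metrics


def mesh_area(canvas: Canvas) -> float:
    tri = canvas.triangles
    p0, p1, p2 = (canvas.vertices[tri[:, k]] for k in range(3))
    return float(0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1).sum())


def _cross_section_angles(canvas: Canvas, config_rows: np.ndarray,
                          inner_u: float = 0.35, outer_u: float = 0.75) -> float:
    """Mean signed fold angle (degrees) across the cheek band, both sides.

    Per row and side, the z-vs-outward-lateral slope of the central
    segment is compared with that of the outer flap; positive = flap
    folded toward -z relative to the central continuation.
    """
    u_all = canvas.uv[:, 0]
    angles = []
    for j in config_rows:
        row = canvas.row_indices(j)
        u = u_all[row]
        x = canvas.vertices[row, 0]
        z = canvas.vertices[row, 2]
        for side in (+1.0, -1.0):
            w = side * u  # outward parameter
            central = (w >= 0.0) & (w <= inner_u)
            outer = w >= outer_u
            if central.sum() < 2 or outer.sum() < 2:
                continue
            def slope_angle(sel):
                sx = np.polyfit(w[sel], x[sel], 1)[0]
                sz = np.polyfit(w[sel], z[sel], 1)[0]
                return np.arctan2(sz, abs(sx))
            angles.append(slope_angle(central) - slope_angle(outer))
    return float(np.degrees(np.mean(angles))) if angles else 0.0


def _raw_bend(canvas: Canvas, s_lo: float = 0.3, s_hi: float = 0.75) -> float:
    rows = [j for j in range(canvas.ny + 1) if s_lo <= j / canvas.ny <= s_hi]
    return _cross_section_angles(canvas, np.array(rows))


def _raw_groove(canvas: Canvas, s_lo: float = 0.2, s_hi: float = 0.85) -> float:
    u_all = canvas.uv[:, 0]
    depths = []
    for j in range(canvas.ny + 1):
        if not (s_lo <= j / canvas.ny <= s_hi):
            continue
        row = canvas.row_indices(j)
        u = u_all[row]
        z = canvas.vertices[row, 2]
        mid = z[np.argmin(np.abs(u))]
        ridges = []
        for side in (+1.0, -1.0):
            sel = (side * u >= 0.15) & (side * u <= 0.9)
            if np.any(sel):
                ridges.append(z[sel].max())
        if ridges:
            depths.append(np.mean(ridges) - mid)
    return float(np.mean(depths)) if depths else 0.0


def _raw_cross_section_flatness(canvas: Canvas, s_lo: float = 0.25,
                                s_hi: float = 0.85) -> float:
    """Mean per-row (z extent / lateral extent) over the mid rows, with
    each row's z measured about its own best-fit lateral line so a rigid
    tilt of the row does not count as thickness."""
    vals = []
    for j in range(canvas.ny + 1):
        if not (s_lo <= j / canvas.ny <= s_hi):
            continue
        row = canvas.row_indices(j)
        x = canvas.vertices[row, 0]
        z = canvas.vertices[row, 2]
        z_detrended = z - np.polyval(np.polyfit(x, z, 1), x)
        vals.append(np.ptp(z_detrended) / np.ptp(x))
    return float(np.mean(vals)) if vals else 0.0


def _raw_longitudinal(canvas: Canvas, s_lo: float = 0.7) -> float:
    """Inclination (degrees) of the distal midline profile in the y-z plane."""
    mid_col = np.array([j * (canvas.nx + 1) + canvas.nx // 2 for j in range(canvas.ny + 1)])
    sel = mid_col[np.arange(canvas.ny + 1) / canvas.ny >= s_lo]
    y = canvas.vertices[sel, 1]
    z = canvas.vertices[sel, 2]
    sy = np.polyfit(np.arange(len(sel)), y, 1)[0]
    sz = np.polyfit(np.arange(len(sel)), z, 1)[0]
    return float(np.degrees(np.arctan2(sz, sy)))


def _canonicalize(canvas: Canvas, reference: Canvas) -> tuple[Canvas, Canvas]:
    """Express both meshes in the reference's intrinsic frame (base row
    along x, proximo-distal direction along y).

    The frame is derived from the reference only and applied to both
    meshes, so a rigid motion applied jointly to canvas and reference
    cancels out; the relative gauge between the two comes from the
    simulation's own base pinning and is left untouched.
    """
    canvas = canvas.copy()
    reference = reference.copy()
    # intrinsic frame of the reference
    base = reference.vertices[reference.base_row]
    c0 = base.mean(axis=0)
    ex = base[-1] - base[0]
    ex = ex / np.linalg.norm(ex)
    ey = reference.vertices[reference.row_indices(1)].mean(axis=0) - c0
    ey = ey - np.dot(ey, ex) * ex
    ey = ey / np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    frame = np.vstack([ex, ey, ez])
    canvas.vertices = (canvas.vertices - c0) @ frame.T
    reference.vertices = (reference.vertices - c0) @ frame.T
    return canvas, reference


def shape_metrics(canvas: Canvas, reference: Canvas) -> ShapeMetrics:
    """Shape descriptors relative to a reference canvas of equal topology."""
    if canvas.triangles.shape != reference.triangles.shape or not np.array_equal(
        canvas.triangles, reference.triangles
    ):
        raise ValueError("canvas and reference topology differ")
    canvas, reference = _canonicalize(canvas, reference)

    def tip_base(c: Canvas) -> float:
        return float(np.linalg.norm(
            c.vertices[c.tip_row].mean(axis=0) - c.vertices[c.base_row].mean(axis=0)
        ))

    elong = tip_base(canvas) / tip_base(reference)
    bend = _raw_bend(canvas) - _raw_bend(reference)
    groove = _raw_groove(canvas) - _raw_groove(reference)
    z_ext = float(np.ptp(canvas.vertices[:, 2]))
    x_ext = float(np.ptp(canvas.vertices[:, 0]))
    flatness = float(z_ext / x_ext) if x_ext > 0 else np.inf
    return ShapeMetrics(
        elongation_ratio=elong,
        lateral_bend_angle_deg=bend,
        groove_depth=groove,
        flatness=flatness,
        longitudinal_bend_deg=_raw_longitudinal(canvas) - _raw_longitudinal(reference),
        cross_section_flatness=_raw_cross_section_flatness(canvas),
    )
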