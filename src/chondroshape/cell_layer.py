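"""Off-lattice 3D simulation of clonal chondrocyte proliferation in a confined sheet.

A founder monolayer of sphere cells sits on a lateral grid between rigid
side walls.  Cells divide at gamma-distributed intervals; the division
direction is drawn from a von Mises-Fisher distribution whose mean is set
by a polarizing gradient (none, one-sided or two-sided across the sheet)
and whose concentration ``b`` interpolates between fully random (b -> 0)
and near-deterministic (large b) daughter placement.  Daughters are pushed
into place by damped pairwise sphere repulsion against the rigid lateral
walls, so clones grow as transverse columns when polarized and as
irregular clusters when not.

The columnar order parameter S is the mean absolute projection of the
mother->daughter displacement unit vectors on the sheet normal: S = 1 for
perfect columns, 0.5 for uniformly random directions, 0 for in-plane
divisions.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import uniform_direction, vonmises_fisher

logger = logging.getLogger(__name__)

#: sentinel returned by :func:`polarization_direction` when divisions are isotropic
ISOTROPIC = None


class ConfigurationError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class Cell:
    """A single chondrocyte, modelled as a sphere of fixed radius.

    Positions are measured in cell-diameter units, so the default radius
    is 0.5.
    """

    id: int
    clone_id: int
    position: np.ndarray
    radius: float = 0.5
    birth_time: float = 0.0
    next_division_time: float | None = None
    divisions_remaining: int = 0


@dataclass
class LayerDomain:
    """Laterally confined slab: rigid walls in x and y, unconstrained in z.

    The domain is centred on the origin; walls sit at +/- extent/2 and
    cell centres are kept at least one radius inside them.
    """

    x_extent: float
    y_extent: float
    mid_plane_z: float = 0.0

    def __post_init__(self) -> None:
        if self.x_extent <= 0 or self.y_extent <= 0:
            raise ConfigurationError("domain extents must be positive")

    def clamp_lateral(self, positions: np.ndarray, radius: float) -> np.ndarray:
        """Project cell centres back inside the rigid walls (in place)."""
        half = np.array([self.x_extent / 2.0, self.y_extent / 2.0])
        np.clip(positions[:, 0], -half[0] + radius, half[0] - radius, out=positions[:, 0])
        np.clip(positions[:, 1], -half[1] + radius, half[1] - radius, out=positions[:, 1])
        return positions


@dataclass
class PolarizationField:
    """Static geometric prescription of the polarity cue across the sheet.

    mode
        ``none``: divisions isotropic.  ``one_sided``: all cells polarized
        along +axis.  ``two_sided``: polarity points away from the founder
        mid-plane toward the nearer surface (oppositional column growth).
    determinacy_b
        Concentration of the von Mises-Fisher division-direction
        distribution; 0 means fully random directions.
    extent_L
        Maximum distance from the mid-plane within which cells remain
        proliferative when polarized (thickness control).
    """

    mode: Literal["none", "one_sided", "two_sided"] = "none"
    axis: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    determinacy_b: float = 0.0
    extent_L: float = np.inf

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ConfigurationError("polarization axis must be non-zero")
        self.axis = self.axis / n
        if self.determinacy_b < 0:
            raise ConfigurationError("determinacy_b must be non-negative")


@dataclass
class DivisionClock:
    """Gamma-distributed per-cell division waiting times.

    ``cv`` is the coefficient of variation of the waiting time; cv = 0
    degenerates to deterministic intervals of length ``tau``.  ``n_max``
    caps the number of divisions per lineage generation, bounding clone
    size at 2**n_max cells.
    """

    tau: float = 1.0
    cv: float = 0.0
    n_max: int = 4

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigurationError("mean division time tau must be positive")
        if self.cv < 0:
            raise ConfigurationError("cv must be non-negative")
        if self.n_max < 0:
            raise ConfigurationError("n_max must be non-negative")

    def draw_waiting_time(self, rng: np.random.Generator) -> float:
        if self.cv == 0:
            return self.tau
        shape = 1.0 / self.cv**2
        scale = self.tau * self.cv**2
        return float(rng.gamma(shape, scale))


@dataclass
class SimState:
    """Full mutable state of one simulation run."""

    time: float
    cells: dict[int, Cell]
    domain: LayerDomain
    field: PolarizationField
    clock: DivisionClock
    rng_seed: int
    rng: np.random.Generator
    division_log: list[tuple[np.ndarray, np.ndarray, float]] = dc_field(default_factory=list)
    _next_id: int = 0

    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.cells.values()])

    def cell_ids(self) -> list[int]:
        return list(self.cells.keys())


@dataclass
class OrderReport:
    """Columnar order parameter S over M logged division displacements."""

    S: float
    n_vectors: int
    reference_axis: np.ndarray


@dataclass
class ThicknessMap:
    """Lateral map of local slab thickness (z-extent of occupied cells)."""

    grid_spacing: float
    values: np.ndarray
    mask: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


# ---------------------------------------------------------------------------
# construction


def init_layer(
    n_x: int,
    n_y: int,
    spacing: float = 1.0,
    seed: int = 0,
    field: PolarizationField | None = None,
    clock: DivisionClock | None = None,
    radius: float = 0.5,
) -> SimState:
    """Create the laterally space-constrained founder monolayer.

    ``n_x * n_y`` cells are placed on a planar grid centred on the origin
    at the mid-plane z; each founder is its own clone.  Division times are
    drawn from the clock, so identical seeds give identical states.
    """
    if n_x < 1 or n_y < 1:
        raise ConfigurationError("grid dimensions must be >= 1")
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    field = field if field is not None else PolarizationField()
    clock = clock if clock is not None else DivisionClock()
    domain = LayerDomain(x_extent=n_x * spacing, y_extent=n_y * spacing)
    rng = np.random.default_rng(seed)

    xs = (np.arange(n_x) - (n_x - 1) / 2.0) * spacing
    ys = (np.arange(n_y) - (n_y - 1) / 2.0) * spacing
    cells: dict[int, Cell] = {}
    cid = 0
    for y in ys:
        for x in xs:
            cells[cid] = Cell(
                id=cid,
                clone_id=cid,
                position=np.array([x, y, domain.mid_plane_z]),
                radius=radius,
                birth_time=0.0,
                next_division_time=clock.draw_waiting_time(rng),
                divisions_remaining=clock.n_max,
            )
            cid += 1
    return SimState(
        time=0.0,
        cells=cells,
        domain=domain,
        field=field,
        clock=clock,
        rng_seed=seed,
        rng=rng,
        _next_id=cid,
    )


# ---------------------------------------------------------------------------
# division machinery


def polarization_direction(
    cell: Cell,
    field: PolarizationField,
    rng: np.random.Generator | None = None,
    mid_plane_z: float = 0.0,
) -> np.ndarray | None:
    """Mean division direction prescribed by the gradient, or ISOTROPIC.

    Two-sided gradients point away from the founder mid-plane toward the
    nearer surface.  A cell sitting within half a radius of the mid-plane
    (the founder monolayer itself) has no defined side; if an rng is
    supplied the sign is drawn at random, which is what seeds oppositional
    up/down column growth, otherwise +axis is used.
    """
    if field.mode == "none":
        return ISOTROPIC
    if field.mode == "one_sided":
        return field.axis.copy()
    # two_sided
    dz = float(np.dot(cell.position, field.axis)) - mid_plane_z
    if abs(dz) < cell.radius / 2.0 and rng is not None:
        sign = 1.0 if rng.random() < 0.5 else -1.0
    else:
        sign = 1.0 if dz >= 0 else -1.0
    return sign * field.axis


def is_proliferative(cell: Cell, field: PolarizationField, mid_plane_z: float = 0.0) -> bool:
    """Polarized cells farther than extent_L from the mid-plane stop dividing."""
    if field.mode == "none":
        return True
    dz = abs(float(np.dot(cell.position, field.axis)) - mid_plane_z)
    return dz <= field.extent_L


def sample_division_direction(
    mean_dir: np.ndarray | None,
    b: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a division direction from a von Mises-Fisher distribution.

    Concentration kappa equals the determinacy parameter b; b = 0 or an
    isotropic mean (None) gives a uniform draw on the sphere.
    """
    if b < 0:
        raise ValueError("concentration b must be non-negative")
    if mean_dir is None or b == 0:
        return np.asarray(uniform_direction.rvs(3, random_state=rng)).reshape(3)
    return np.asarray(
        vonmises_fisher.rvs(np.asarray(mean_dir, dtype=float), b, random_state=rng)
    ).reshape(3)


def attempt_division(state: SimState, cell_id: int) -> SimState:
    """Divide one cell: place a daughter one diameter away along the sampled
    direction, inherit the clone label, log the displacement, then relax
    overlaps.  Mutates and returns ``state``."""
    if cell_id not in state.cells:
        raise KeyError(f"unknown cell id {cell_id}")
    mother = state.cells[cell_id]
    if mother.divisions_remaining <= 0:
        raise ValueError(f"cell {cell_id} has no divisions remaining")

    mean_dir = polarization_direction(
        mother, state.field, rng=state.rng, mid_plane_z=state.domain.mid_plane_z
    )
    direction = sample_division_direction(mean_dir, state.field.determinacy_b, state.rng)
    daughter_pos = mother.position + 2.0 * mother.radius * direction

    mother.divisions_remaining -= 1
    daughter = Cell(
        id=state._next_id,
        clone_id=mother.clone_id,
        position=daughter_pos,
        radius=mother.radius,
        birth_time=state.time,
        next_division_time=state.time + state.clock.draw_waiting_time(state.rng),
        divisions_remaining=mother.divisions_remaining,
    )
    state._next_id += 1
    state.cells[daughter.id] = daughter
    mother.next_division_time = state.time + state.clock.draw_waiting_time(state.rng)
    state.division_log.append((mother.position.copy(), daughter_pos.copy(), state.time))
    resolve_overlaps(state)
    return state


def resolve_overlaps(
    state: SimState,
    tolerance: float = 0.01,
    max_sweeps: int = 500,
    damping: float = 1.0,
) -> SimState:
    """Iterative damped pairwise sphere repulsion plus rigid-wall projection.

    Sweeps projected pair corrections (each cell's net correction is the
    contact-averaged overlap resolution) until the worst pairwise overlap
    is below ``tolerance`` diameters or the sweep cap is hit (then a
    warning is logged and the best state returned).  Exactly coincident
    cells are separated along the +x axis (deterministic tie-break).
    Candidate pairs come from a periodically refreshed neighbour list.
    """
    cells = list(state.cells.values())
    n = len(cells)
    if n == 0:
        return state
    radius = cells[0].radius
    diameter = 2.0 * radius
    pos = np.array([c.position for c in cells])
    tol_abs = tolerance * diameter
    tie_break = np.array([1.0, 0.0, 0.0])
    refresh = 10  # sweeps between neighbour-list rebuilds
    skin = 0.75 * diameter  # neighbour-list margin beyond contact distance

    iu = ju = None
    state.domain.clamp_lateral(pos, radius)
    for sweep in range(max_sweeps):
        if sweep % refresh == 0:
            pairs = cKDTree(pos).query_pairs(diameter + skin, output_type="ndarray")
            if len(pairs) == 0:
                break
            iu, ju = pairs[:, 0], pairs[:, 1]
        diff = pos[iu] - pos[ju]
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        sel = dist < diameter - tol_abs
        if not sel.any():
            if sweep % refresh == 0:
                break  # fresh neighbour list and no overlap: converged
            pairs = cKDTree(pos).query_pairs(diameter + skin, output_type="ndarray")
            if len(pairs) == 0:
                break
            iu, ju = pairs[:, 0], pairs[:, 1]
            diff = pos[iu] - pos[ju]
            dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            sel = dist < diameter - tol_abs
            if not sel.any():
                break
        i, j = iu[sel], ju[sel]
        d = dist[sel]
        u = np.empty((len(d), 3))
        coincident = d < 1e-12
        u[~coincident] = diff[sel][~coincident] / d[~coincident, None]
        u[coincident] = tie_break  # deterministic tie-break along +x
        push = np.where(coincident, diameter, diameter - d)
        shift = (0.5 * damping * push)[:, None] * u
        ij = np.concatenate([i, j])
        signed = np.concatenate([shift, -shift])
        corrections = np.column_stack([
            np.bincount(ij, weights=signed[:, k], minlength=n) for k in range(3)
        ])
        counts = np.bincount(ij, minlength=n).astype(float)
        # contact-averaged correction keeps dense packings stable
        pos += corrections / np.maximum(counts, 1.0)[:, None]
        state.domain.clamp_lateral(pos, radius)
    else:
        logger.warning("overlap relaxation did not converge within %d sweeps", max_sweeps)
        warnings.warn("overlap relaxation did not converge", RuntimeWarning, stacklevel=2)

    for c, p in zip(cells, pos):
        c.position = p
    return state


# ---------------------------------------------------------------------------
# event loop


@dataclass
class SimConfig:
    """Configuration of a full event-driven run."""

    n_x: int = 4
    n_y: int = 4
    spacing: float = 1.0
    field: PolarizationField = dc_field(default_factory=PolarizationField)
    clock: DivisionClock = dc_field(default_factory=DivisionClock)
    t_end: float = np.inf
    seed: int = 0
    snapshot_interval: float | None = None

    def __post_init__(self) -> None:
        if self.t_end < 0:
            raise ConfigurationError("t_end must be non-negative")


def run_simulation(config: SimConfig) -> tuple[SimState, list[tuple[float, pd.DataFrame]]]:
    """Event-driven proliferation loop.

    Division events are processed in time order (ties broken by cell id)
    until ``t_end`` or until every lineage has exhausted its divisions.
    Returns the final state and a list of (time, cell-table) snapshots;
    the final state is always appended as the last snapshot.
    """
    state = init_layer(
        config.n_x, config.n_y, config.spacing, config.seed,
        field=config.field, clock=config.clock,
    )
    heap: list[tuple[float, int]] = [
        (c.next_division_time, c.id) for c in state.cells.values()
        if c.divisions_remaining > 0
    ]
    heapq.heapify(heap)

    trajectory: list[tuple[float, pd.DataFrame]] = []
    next_snap = config.snapshot_interval

    while heap:
        t, cid = heapq.heappop(heap)
        if t > config.t_end:
            break
        cell = state.cells.get(cid)
        if cell is None or cell.divisions_remaining <= 0:
            continue
        if cell.next_division_time != t:
            continue  # stale event
        if not is_proliferative(cell, state.field, state.domain.mid_plane_z):
            continue  # beyond polarized extent: permanently non-proliferative
        if config.snapshot_interval is not None:
            while next_snap is not None and t > next_snap:
                trajectory.append((next_snap, cells_to_table(state)))
                next_snap += config.snapshot_interval
        state.time = t
        attempt_division(state, cid)
        daughter_id = state._next_id - 1
        daughter = state.cells[daughter_id]
        if cell.divisions_remaining > 0:
            heapq.heappush(heap, (cell.next_division_time, cell.id))
        if daughter.divisions_remaining > 0:
            heapq.heappush(heap, (daughter.next_division_time, daughter.id))

    trajectory.append((state.time, cells_to_table(state)))
    return state, trajectory


def cells_to_table(state: SimState) -> pd.DataFrame:
    """Cell table with the canonical column layout."""
    rows = [
        (c.id, c.clone_id, c.position[0], c.position[1], c.position[2], c.radius, c.birth_time)
        for c in state.cells.values()
    ]
    return pd.DataFrame(rows, columns=["id", "clone_id", "x", "y", "z", "radius", "birth_time"])


# ---------------------------------------------------------------------------
# observables


def order_parameter(
    division_log: list[tuple[np.ndarray, np.ndarray, float]],
    reference_axis: np.ndarray = np.array([0.0, 0.0, 1.0]),
) -> OrderReport:
    """Columnar order S: mean |d_k . axis| over mother->daughter unit vectors."""
    if len(division_log) == 0:
        raise ValueError("division log is empty")
    axis = np.asarray(reference_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    d = np.array([daughter - mother for mother, daughter, _ in division_log])
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    S = float(np.mean(np.abs(d @ axis)))
    return OrderReport(S=S, n_vectors=len(d), reference_axis=axis)


def thickness_map(state: SimState, grid_spacing: float = 1.0) -> ThicknessMap:
    """Local slab thickness per lateral bin, viewed from above.

    Thickness in a bin is (max z + r) - (min z - r) over the cells whose
    centres fall in it; bins with no cells are masked out.
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if not state.cells:
        raise ValueError("state has no cells")
    pos = state.positions()
    radius = next(iter(state.cells.values())).radius
    hx = state.domain.x_extent / 2.0
    hy = state.domain.y_extent / 2.0
    x_edges = np.arange(-hx, hx + grid_spacing * 0.5, grid_spacing)
    y_edges = np.arange(-hy, hy + grid_spacing * 0.5, grid_spacing)
    nx_bins, ny_bins = len(x_edges) - 1, len(y_edges) - 1
    ix = np.clip(np.digitize(pos[:, 0], x_edges) - 1, 0, nx_bins - 1)
    iy = np.clip(np.digitize(pos[:, 1], y_edges) - 1, 0, ny_bins - 1)

    values = np.zeros((nx_bins, ny_bins))
    mask = np.zeros((nx_bins, ny_bins), dtype=bool)
    for b in range(nx_bins * ny_bins):
        bi, bj = b // ny_bins, b % ny_bins
        sel = (ix == bi) & (iy == bj)
        if np.any(sel):
            z = pos[sel, 2]
            values[bi, bj] = (z.max() + radius) - (z.min() - radius)
            mask[bi, bj] = True
    return ThicknessMap(grid_spacing=grid_spacing, values=values, mask=mask,
                        x_edges=x_edges, y_edges=y_edges)


def thickness_stats(tmap: ThicknessMap) -> tuple[float, float]:
    """(mean thickness, regularity) over occupied bins.

    Regularity is 1 - CV (population coefficient of variation), clipped to
    [0,1]: a perfectly uniform slab scores 1.
    """
    if not np.any(tmap.mask):
        raise ValueError("thickness map has no occupied bins")
    vals = tmap.values[tmap.mask]
    mean = float(vals.mean())
    cv = float(vals.std() / mean) if mean > 0 else 0.0
    regularity = float(np.clip(1.0 - cv, 0.0, 1.0))
    return mean, regularity
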