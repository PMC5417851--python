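"""Clone-envelope micro-geometry statistics for lineage-traced cartilage.

Quantifies how the shape and orientation of clonal envelopes relate to
the local geometry of the cartilage:

* alpha — angle between a clone's principal axis and the local surface
  normal, in [0, 90] degrees.  Small alpha means a transverse clonal
  column (perpendicular to the sheet); alpha near 90 means in-plane
  elongation.
* beta — angle between the two opposing cartilage surfaces framing a
  locality, from least-squares plane fits.  beta <= 20 degrees defines
  sheet-like geometry.
* rose histograms of axial orientation data on [0, 90] degrees.
* Spearman rank correlation of alpha against beta across localities, and
  an unpaired pooled-variance Student t-test reconstructed from printed
  summary statistics (mean, s.e.m., n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: inclusive upper bound on beta (degrees) for a locality to count as sheet-like
SHEET_BETA_MAX_DEG = 20.0

#: sentinel elongation ratio for perfectly collinear clusters
COLLINEAR = math.inf

#: sentinel returned when a rank correlation is undefined (constant input)
UNDEFINED_CORRELATION = math.nan


class DegenerateClusterError(ValueError):
    """All member positions coincide; no axis is defined."""


@dataclass
class CloneCluster:
    """All labelled cells of one clone at one locality."""

    clone_id: int
    positions: np.ndarray  # (n, 3)
    locality_id: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 2:
            raise ValueError("a clone cluster needs at least 2 cells")


@dataclass
class SurfacePatchPair:
    """Point samples of the two opposing surfaces around a locality."""

    patch_a: np.ndarray  # (>=3, 3)
    patch_b: np.ndarray

    def __post_init__(self) -> None:
        for name in ("patch_a", "patch_b"):
            pts = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if pts.shape[0] < 3:
                raise ValueError(f"{name} needs at least 3 points")
            setattr(self, name, pts)


@dataclass
class CloneGeometryRecord:
    """Per-clone alpha/beta record: one dot of the alpha-beta scatter."""

    clone_id: int
    locality_id: int | None
    n_cells: int
    alpha_deg: float
    beta_deg: float
    elongation_ratio: float

    @property
    def sheet_like(self) -> bool:
        return self.beta_deg <= SHEET_BETA_MAX_DEG


@dataclass
class RoseHistogram:
    """Axial orientation histogram over [0, 90] degrees."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int


# ---------------------------------------------------------------------------


def principal_axis(cluster: CloneCluster) -> tuple[np.ndarray, float]:
    """Leading eigenvector of the centred second-moment matrix, plus the
    elongation ratio sqrt(lambda1/lambda2).

    The axis is returned with a non-negative z component (axial data).
    Collinear clusters get the COLLINEAR (infinite) ratio sentinel;
    clusters whose points all coincide raise DegenerateClusterError.
    """
    pts = cluster.positions
    centred = pts - pts.mean(axis=0)
    if np.allclose(centred, 0.0):
        raise DegenerateClusterError(f"clone {cluster.clone_id}: all positions identical")
    cov = centred.T @ centred / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    axis = eigvecs[:, -1]
    if axis[2] < 0 or (axis[2] == 0 and (axis[0] < 0 or (axis[0] == 0 and axis[1] < 0))):
        axis = -axis
    lam1, lam2 = eigvals[-1], eigvals[-2]
    if lam2 <= lam1 * 1e-12:
        ratio = COLLINEAR
    else:
        ratio = math.sqrt(lam1 / lam2)
    return axis, ratio


def clone_alpha(cluster: CloneCluster, surface_normal: np.ndarray) -> float:
    """Angle (degrees, folded to [0, 90]) between the clone principal axis
    and the local surface normal.  0 = transverse column, 90 = in-plane."""
    axis, _ = principal_axis(cluster)
    n = np.asarray(surface_normal, dtype=float)
    n = n / np.linalg.norm(n)
    cosang = min(1.0, abs(float(np.dot(axis, n))))
    return math.degrees(math.acos(cosang))


def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through a point cloud.

    The normal is the eigenvector of the centred second-moment matrix with
    the smallest eigenvalue; collinear clouds (two vanishing eigenvalues)
    have no defined plane and raise ValueError.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[1] <= eigvals[2] * 1e-12:
        raise ValueError("patch points are collinear; plane fit is degenerate")
    return eigvecs[:, 0]


def surface_beta(pair: SurfacePatchPair) -> float:
    """Dihedral angle (degrees, folded to [0, 90]) between the least-squares
    planes of the two opposing surface patches."""
    n_a = fit_plane_normal(pair.patch_a)
    n_b = fit_plane_normal(pair.patch_b)
    cosang = min(1.0, abs(float(np.dot(n_a, n_b))))
    return math.degrees(math.acos(cosang))


def rose_histogram(angles_deg, bin_width_deg: float = 10.0) -> RoseHistogram:
    """Axial orientation histogram: right-open bins over [0, 90], last bin
    closed, so 90 lands in the top bin and boundary angles in the lower."""
    angles = np.asarray(list(angles_deg), dtype=float)
    if angles.size and (angles.min() < 0 or angles.max() > 90):
        raise ValueError("angles must lie in [0, 90] degrees")
    n_bins = 90.0 / bin_width_deg
    if bin_width_deg <= 0 or abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide 90 degrees")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    idx = np.minimum((angles // bin_width_deg).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins) if angles.size else np.zeros(n_bins, dtype=int)
    return RoseHistogram(bin_edges=edges, counts=counts, n_total=int(angles.size))


def alpha_beta_spearman(records: list[CloneGeometryRecord]) -> float:
    """Spearman rank correlation (average-rank ties) of alpha against beta
    across clone records; NaN sentinel when either variable is constant."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a rank correlation")
    alpha = np.array([r.alpha_deg for r in records])
    beta = np.array([r.beta_deg for r in records])
    if np.all(alpha == alpha[0]) or np.all(beta == beta[0]):
        return UNDEFINED_CORRELATION
    rho = stats.spearmanr(alpha, beta).statistic
    return float(rho)


def two_sample_t_from_summary(
    mean1: float, sem1: float, n1: int,
    mean2: float, sem2: float, n2: int,
) -> tuple[float, float]:
    """Unpaired pooled-variance Student t-test reconstructed from printed
    summaries (mean, s.e.m., n); SD_i = sem_i * sqrt(n_i), df = n1+n2-2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("standard errors must be non-negative")
    sd1 = sem1 * math.sqrt(n1)
    sd2 = sem2 * math.sqrt(n2)
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# table-level pipeline


def clusters_from_table(
    cells: pd.DataFrame,
    locality_id: int | None = None,
    min_cells: int = 2,
    linkage_cut: float | None = None,
) -> list[CloneCluster]:
    """Group a cell table into CloneClusters by its clone_id column.

    With ``linkage_cut`` set (in the same length units as the table),
    same-label cells are further split into spatially separate clusters by
    single-linkage clustering cut at that distance — needed for dense real
    tracing where one label marks several founders.
    """
    out: list[CloneCluster] = []
    for clone_id, grp in cells.groupby("clone_id", sort=True):
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        if linkage_cut is not None and pts.shape[0] >= 2:
            from scipy.cluster.hierarchy import fcluster, linkage

            labels = fcluster(linkage(pts, method="single"), t=linkage_cut,
                              criterion="distance")
            parts = [pts[labels == k] for k in np.unique(labels)]
        else:
            parts = [pts]
        for part in parts:
            if part.shape[0] >= min_cells:
                out.append(CloneCluster(clone_id=int(clone_id), positions=part,
                                        locality_id=locality_id))
    return out


def measure_clones(
    clusters: list[CloneCluster],
    pair: SurfacePatchPair,
) -> list[CloneGeometryRecord]:
    """alpha/beta records for each cluster against one surface-patch pair.

    The local surface normal is the mean of the two patch normals
    (oriented consistently), which for near-parallel sheet surfaces is the
    sheet normal.
    """
    n_a = fit_plane_normal(pair.patch_a)
    n_b = fit_plane_normal(pair.patch_b)
    if np.dot(n_a, n_b) < 0:
        n_b = -n_b
    normal = n_a + n_b
    normal = normal / np.linalg.norm(normal)
    beta = surface_beta(pair)
    records = []
    for cl in clusters:
        _, ratio = principal_axis(cl)
        records.append(CloneGeometryRecord(
            clone_id=cl.clone_id,
            locality_id=cl.locality_id,
            n_cells=cl.positions.shape[0],
            alpha_deg=clone_alpha(cl, normal),
            beta_deg=beta,
            elongation_ratio=ratio,
        ))
    return records


def records_to_table(records: list[CloneGeometryRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.clone_id, r.locality_id, r.n_cells, r.alpha_deg, r.beta_deg, r.elongation_ratio)
         for r in records],
        columns=["clone_id", "locality_id", "n_cells", "alpha_deg", "beta_deg",
                 "elongation_ratio"],
    )
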