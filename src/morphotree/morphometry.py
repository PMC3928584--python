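"""Accumulative per-branch measurements.

Every quantity here is computed from the information of multiple segments
of one branch:

* **length** — sum of the Euclidean 3D lengths of all segments.
* **tapering** — slope of an ordinary least-squares fit of diameter
  (2 × radius) against cumulative 3D arc length along the branch, plus the
  mean diameter and its standard error.
* **DM tortuosity** — path length over the straight-line distance between
  the branch endpoints; dimensionless, ≥ 1, equal to 1 iff collinear.
* **SOAM tortuosity** — the sum-of-angles metric: total curvature (the
  combined in-plane and torsional angle at each interior point) divided by
  path length, in rad/µm, so branches of different length are comparable.
* **soma distances** — straight-line and along-the-genealogy path distance
  from the soma root point to the branch start.

For any point P_k the three consecutive chord vectors are
T1 = P_k − P_{k−1}, T2 = P_{k+1} − P_k and T3 = P_{k+2} − P_{k+1}.  The
in-plane angle IP_k = arccos(T̂1 · T̂2) and the torsional angle
TP_k = arccos((T1×T2)^ · (T2×T3)^) both lie in [0, π]; the total angle is
CP_k = sqrt(IP_k² + TP_k²) and SOAM = Σ CP_k / Σ |P_k − P_{k−1}|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .topology import Branch, BranchForest

__all__ = [
    "BranchMetrics",
    "branch_length",
    "arc_lengths",
    "dm_tortuosity",
    "soam_angles",
    "soam_tortuosity",
    "tapering",
    "soma_distances",
    "measure_branch",
]

#: Consecutive chords whose normalized cross product is shorter than this
#: (i.e. an in-plane turn below ~1e-4 rad) are treated as a collinear
#: continuation contributing no torsion (TP_k = 0).  The torsional angle
#: is ill-conditioned there: for near-parallel chords the cross product's
#: direction is dominated by coordinate round-off, not by geometry.
_DEGENERATE_SIN = 1e-4


@dataclass(frozen=True)
class BranchMetrics:
    """Accumulative measurements of one branch (lengths in µm)."""

    length: float
    euclidean_to_soma: float
    path_to_soma: float
    taper_slope: float  # µm diameter change per µm arc length; NaN if undefined
    mean_diameter: float
    diameter_sem: float
    dm: float  # dimensionless, >= 1; NaN for coincident endpoints
    soam: float  # rad/µm, >= 0
    soam_too_short: bool  # True when the branch has < 4 points


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative 3D arc length at each point (starts at 0)."""
    step = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(step)])


def branch_length(branch: Branch) -> float:
    """Sum of the Euclidean 3D lengths of all segments of the branch."""
    return float(arc_lengths(branch.points)[-1])


def dm_tortuosity(branch: Branch) -> float:
    """Path length divided by the straight endpoint distance (≥ 1).

    Undefined (NaN, with a warning) when the endpoints coincide.
    """
    chord = float(np.linalg.norm(branch.points[-1] - branch.points[0]))
    if chord == 0.0:
        warnings.warn(
            f"branch {branch.first_name}: coincident endpoints, DM undefined"
        )
        return math.nan
    return branch_length(branch) / chord


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def soam_angles(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point in-plane and torsional angles (IP_k, TP_k), both in
    [0, π], for every complete vector triple along the polyline.

    Returns two arrays of length max(n − 3, 0).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 4:
        return np.empty(0), np.empty(0)
    t = np.diff(pts, axis=0)  # chord vectors, (n-1, 3)
    ips = np.empty(n - 3)
    tps = np.empty(n - 3)
    for k in range(n - 3):
        u1, u2, u3 = _unit(t[k]), _unit(t[k + 1]), _unit(t[k + 2])
        ips[k] = math.acos(float(np.clip(np.dot(u1, u2), -1.0, 1.0)))
        c1 = np.cross(u1, u2)
        c2 = np.cross(u2, u3)
        n1, n2 = np.linalg.norm(c1), np.linalg.norm(c2)
        if n1 < _DEGENERATE_SIN or n2 < _DEGENERATE_SIN:
            tps[k] = 0.0  # straight continuation: no torsion
        else:
            tps[k] = math.acos(float(np.clip(np.dot(c1 / n1, c2 / n2), -1.0, 1.0)))
    return ips, tps


def soam_tortuosity(branch: Branch, combine: str = "euclidean") -> float:
    """Sum-of-angles-metric tortuosity in rad/µm.

    ``combine`` selects how the in-plane and torsional angles merge into
    the total angle CP_k: ``"euclidean"`` (default) uses
    sqrt(IP² + TP²); ``"sum"`` uses IP + TP (sensitivity variant).

    Branches with fewer than 4 points have no complete vector triple, so
    the angle sum is empty and SOAM is 0.
    """
    if combine not in ("euclidean", "sum"):
        raise ValueError(f"unknown combine mode {combine!r}")
    ips, tps = soam_angles(branch.points)
    if len(ips) == 0:
        return 0.0
    if combine == "euclidean":
        total = float(np.hypot(ips, tps).sum())
    else:
        total = float((ips + tps).sum())
    return total / branch_length(branch)


def tapering(branch: Branch) -> tuple[float, float, float]:
    """OLS taper slope, mean diameter and SEM of the per-point diameters.

    The regressor is the cumulative 3D arc length at each point; the
    response is the diameter 2 × radius.  The slope is NaN when all points
    share one arc length (degenerate abscissa).
    """
    s = arc_lengths(branch.points)
    d = 2.0 * branch.radii
    mean = float(np.mean(d))
    sem = (
        float(np.std(d, ddof=1) / math.sqrt(len(d))) if len(d) > 1 else 0.0
    )
    if np.ptp(s) == 0.0:
        return math.nan, mean, sem
    slope = float(np.polyfit(s, d, 1)[0])
    return slope, mean, sem


def soma_distances(branch: Branch, forest: BranchForest) -> tuple[float, float]:
    """(Euclidean, path) distance from the soma root point to the branch
    start.

    Euclidean is the straight-line distance from the tree's root point to
    P_0 of the branch; path is the sum of the lengths of all full-name
    ancestors.  Path ≥ Euclidean always (triangle inequality along the
    genealogy).
    """
    root_point = forest.tree_root_point(branch)
    euclid = float(np.linalg.norm(branch.start_point - root_point))
    path = 0.0
    for name in branch.full_name[:-1]:
        path += branch_length(forest.branches[name])
    return euclid, path


def measure_branch(branch: Branch, forest: BranchForest) -> BranchMetrics:
    """All accumulative metrics of one branch."""
    slope, mean_d, sem_d = tapering(branch)
    euclid, path = soma_distances(branch, forest)
    return BranchMetrics(
        length=branch_length(branch),
        euclidean_to_soma=euclid,
        path_to_soma=path,
        taper_slope=slope,
        mean_diameter=mean_d,
        diameter_sem=sem_d,
        dm=dm_tortuosity(branch),
        soam=soam_tortuosity(branch),
        soam_too_short=len(branch.points) < 4,
    )
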