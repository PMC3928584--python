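"""Directional vectors, bifurcation angles and per-bifurcation Rall
exponents.

A bifurcation angle is the angle between a daughter and its parent branch.
Because it does not depend only on the terminal segments, directional
vectors are extracted from a 3D linear regression over the first/last few
segments of each branch (five by default, user-configurable — the right
number really depends on the branch's tortuosity).  The regression is a
total least squares fit (first principal axis of the centered points),
since no coordinate axis is privileged in 3D, and the unit vector is
oriented along increasing arc length.

Rall's equivalent-cylinder model for passive dendrites predicts that at a
bifurcation the daughter diameters raised to 3/2 sum to the parent
diameter raised to 3/2 (the "3/2 power rule").  Each bifurcation's *Rall
exponent* is the E solving

    d_eq^E = Σ_i d_i^E

found by bracketed root finding on f(E) = (Σ d_i^E)^(1/E) − d_eq, which is
strictly decreasing in E (it is the E-norm of the daughter-diameter
vector).  A bifurcation obeying the classic rule returns exactly 3/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .topology import Branch, BranchForest

__all__ = [
    "DirectionalVector",
    "Bifurcation",
    "GeometryError",
    "directional_vector",
    "bifurcation_angle",
    "rall_exponent",
    "find_bifurcations",
]

DEFAULT_SEGMENTS = 5  # segments per branch used for directional vectors


class GeometryError(ValueError):
    """Degenerate geometry (e.g. all regression points coincident)."""


@dataclass(frozen=True)
class DirectionalVector:
    origin: np.ndarray  # 3D point the vector is anchored at
    direction: np.ndarray  # unit 3D vector, oriented with growth
    n_segments_used: int


@dataclass
class Bifurcation:
    """One branch point: its location, the adjacent diameters, and the
    derived angle/exponent measurements."""

    location: np.ndarray  # branch end point X_j
    parent_name: int
    daughter_names: list[int]
    parent_diameter: float  # d_eq, at the parent's final point
    daughter_diameters: list[float]  # d_i, at each daughter's first own point
    angles: list[float] = field(default_factory=list)  # radians, one per daughter
    rall_exponent: float = math.nan
    rall_failure: str | None = None


def directional_vector(
    branch: Branch, end: str, m: int = DEFAULT_SEGMENTS
) -> DirectionalVector:
    """Unit direction of the branch near its start or finish.

    Takes the first (``end="start"``) or last (``end="finish"``)
    ``min(m, available)`` segments — i.e. that many + 1 points — and fits
    the best 3D line through them by total least squares.  The returned
    unit vector points in the direction of increasing arc length.
    """
    if end not in ("start", "finish"):
        raise ValueError("end must be 'start' or 'finish'")
    if m < 1:
        raise ValueError("m must be >= 1")
    k = min(m, branch.segment_count)
    pts = branch.points[: k + 1] if end == "start" else branch.points[-(k + 1):]
    chord = pts[-1] - pts[0]
    centered = pts - pts.mean(axis=0)
    if not np.any(np.linalg.norm(centered, axis=1) > 0):
        raise GeometryError(
            f"branch {branch.first_name}: all points for the {end} vector coincide"
        )
    # First principal axis of the centered cloud.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    # Orient along growth (increasing arc length).
    sign = np.dot(direction, chord)
    if sign < 0:
        direction = -direction
    elif sign == 0 and np.linalg.norm(chord) == 0:
        raise GeometryError(
            f"branch {branch.first_name}: zero chord, cannot orient {end} vector"
        )
    origin = pts[0] if end == "start" else pts[-1]
    return DirectionalVector(origin=origin, direction=direction, n_segments_used=k)


def bifurcation_angle(
    parent: Branch, daughter: Branch, m: int = DEFAULT_SEGMENTS
) -> float:
    """Angle (radians, in [0, π]) between a daughter and its parent.

    Computed between the parent's finish vector and the daughter's start
    vector, both oriented away from the soma, so a daughter continuing
    exactly along the parent's line gives 0.
    """
    if daughter.parent_branch != parent.first_name:
        raise ValueError(
            f"branch {daughter.first_name} is not a daughter of {parent.first_name}"
        )
    vp = directional_vector(parent, "finish", m)
    vd = directional_vector(daughter, "start", m)
    cosang = float(np.clip(np.dot(vp.direction, vd.direction), -1.0, 1.0))
    return math.acos(cosang)


def rall_exponent(
    parent_diameter: float,
    daughter_diameters: list[float] | tuple[float, ...],
    tol: float = 1e-8,
    bracket: tuple[float, float] = (0.05, 20.0),
) -> tuple[float, str | None]:
    """Solve d_eq^E = Σ d_i^E for the exponent E.

    Returns ``(E, None)`` on success or ``(nan, reason)`` when no root
    exists in the bracket: f(E) = (Σ d_i^E)^(1/E) − d_eq decreases
    monotonically from near Σ d_i (E → 0⁺ side of the bracket) towards
    max d_i (E → ∞), so a root exists iff max d_i < d_eq < the value at
    the lower bracket edge.
    """
    d_eq = float(parent_diameter)
    di = np.asarray(daughter_diameters, dtype=float)
    if len(di) < 2:
        return math.nan, "fewer than 2 daughters"
    if d_eq <= 0 or np.any(di <= 0):
        return math.nan, "non-positive diameter"
    if d_eq <= di.max():
        return math.nan, "parent diameter not larger than the largest daughter"

    def f(e: float) -> float:
        # log-domain E-norm for numerical robustness
        logs = e * np.log(di)
        mx = logs.max()
        return math.exp((mx + math.log(np.exp(logs - mx).sum())) / e) - d_eq

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo, None
    if fhi == 0.0:
        return hi, None
    if flo < 0 or fhi > 0:
        return math.nan, "no sign change in bracket"
    root = brentq(f, lo, hi, rtol=tol)
    return float(root), None


def find_bifurcations(
    forest: BranchForest, m: int = DEFAULT_SEGMENTS, tol: float = 1e-8
) -> list[Bifurcation]:
    """All bifurcations of the forest with angles and Rall exponents.

    A bifurcation is the distal end X_j of any branch with ≥ 2 daughters.
    The parent diameter d_eq is measured at the parent's final point and
    each daughter diameter d_i at the daughter's first own point (the
    record just distal to X_j) — the values adjacent to the branch point.
    """
    out: list[Bifurcation] = []
    for b in forest:
        daughters = forest.daughters(b)
        if len(daughters) < 2:
            continue
        d_i = [2.0 * float(d.radii[1]) for d in daughters]
        bif = Bifurcation(
            location=b.end_point,
            parent_name=b.first_name,
            daughter_names=[d.first_name for d in daughters],
            parent_diameter=2.0 * float(b.radii[-1]),
            daughter_diameters=d_i,
        )
        bif.angles = [bifurcation_angle(b, d, m) for d in daughters]
        bif.rall_exponent, bif.rall_failure = rall_exponent(
            bif.parent_diameter, bif.daughter_diameters, tol=tol
        )
        out.append(bif)
    return out
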