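"""Z-axis smoothing of digitized reconstructions.

Reconstructions traced on bright-field systems often carry strong
digitization noise along the optical (z) axis while x and y are clean.
This module removes it with a per-branch moving-average filter.  Because
the spatial distribution of traced points is not uniform, the filter's
neighborhood is defined on the cumulative xy-projected arc length of the
branch (the *predictor*), not on point counts: every z value is replaced
by the mean of the z values whose predictor lies within a half-width
``window`` (µm) of its own.

Smoothing each branch in isolation would create z-jumps at bifurcations,
so two synthetic boundary points are concatenated before filtering: one
before the branch start whose z averages the parent's (already smoothed)
final z with the branch's own first z, and one past the branch end whose z
averages the initial z of all daughters.  Either point is omitted when the
corresponding neighbors do not exist (root or terminal branches).

Only z changes: x, y, radii, topology and point count are untouched, and a
zero window is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .swc import Reconstruction
from .topology import Branch, BranchForest, build_forest

__all__ = ["SmoothingConfig", "smooth_branch_z", "smooth_reconstruction", "xy_arc_length"]

#: Predictor tie-break for vertical segments (zero xy spacing), in µm.
_TIE_EPS = 1e-6


@dataclass(frozen=True)
class SmoothingConfig:
    """Moving-average filter configuration.

    window
        Half-width of the xy-arc-length neighborhood, in µm.  0 disables
        smoothing entirely (identity).  The default of 5 µm spans a few
        traced points at typical archive sampling densities.
    passes
        Number of filter applications; each pass contracts the remaining
        noise further.
    """

    window: float = 5.0
    passes: int = 1

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


def xy_arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length of the xy projection, made strictly
    increasing by epsilon perturbation of zero-length (vertical) steps."""
    d = np.hypot(np.diff(points[:, 0]), np.diff(points[:, 1]))
    d = np.maximum(d, _TIE_EPS)
    return np.concatenate([[0.0], np.cumsum(d)])


def smooth_branch_z(
    branch: Branch,
    parent_final_z: float | None,
    daughters_initial_z: list[float],
    cfg: SmoothingConfig,
) -> np.ndarray:
    """Return the smoothed z values for one branch's points.

    ``parent_final_z`` is the (already smoothed) z of the parent's end
    point, or ``None`` for a root branch; ``daughters_initial_z`` holds
    the initial z of every daughter (empty for terminals).
    """
    z = branch.points[:, 2].copy()
    if len(z) < 2:
        warnings.warn("branch with fewer than 2 points: smoothing is a no-op")
        return z
    if cfg.window == 0:
        return z

    s = xy_arc_length(branch.points)
    length = s[-1]
    mean_spacing = length / (len(s) - 1)

    pred = list(s)
    vals = list(z)
    # Boundary concatenation keeps continuity across the bifurcation; the
    # synthetic points sit one mean spacing outside the branch so their
    # filter weight is comparable to an interior point's.
    if parent_final_z is not None:
        pred.insert(0, -mean_spacing)
        vals.insert(0, 0.5 * (parent_final_z + z[0]))
    if daughters_initial_z:
        pred.append(length + mean_spacing)
        vals.append(float(np.mean(daughters_initial_z)))

    pred_arr = np.asarray(pred)
    vals_arr = np.asarray(vals)
    out = np.empty_like(z)
    for i, si in enumerate(s):
        mask = np.abs(pred_arr - si) <= cfg.window
        out[i] = vals_arr[mask].mean()
    return out


def smooth_reconstruction(
    rec: Reconstruction,
    cfg: SmoothingConfig,
    forest: BranchForest | None = None,
) -> Reconstruction:
    """Smooth the z coordinate of every branch, root-to-tip.

    Parent branches are filtered before their daughters so the boundary
    point a daughter sees already carries the smoothed parent z.  The
    attachment point P_0 of each branch is owned by the parent (or soma)
    and is never rewritten by the daughter.

    Returns a new :class:`Reconstruction`; x, y, radii, indices and record
    order are bit-identical to the input.
    """
    if forest is None:
        forest = build_forest(rec)

    new_z: dict[int, float] = {}  # record index -> smoothed z

    def current_z(branch: Branch, point_pos: int) -> float:
        idx = branch.record_indices[point_pos]
        if idx in new_z:
            return new_z[idx]
        return float(branch.points[point_pos, 2])

    for _ in range(cfg.passes):
        # Root-to-tip: parents first.
        order: list[Branch] = []
        stack = [forest.branches[r] for r in forest.roots]
        while stack:
            b = stack.pop()
            order.append(b)
            stack.extend(forest.daughters(b))
        for b in order:
            pts = b.points.copy()
            for pos, idx in enumerate(b.record_indices):
                if idx in new_z:
                    pts[pos, 2] = new_z[idx]
            work = replace_points(b, pts)
            parent = forest.parent(b)
            parent_z = current_z(parent, len(parent.points) - 1) if parent else None
            daughters_z = [current_z(d, 1) for d in forest.daughters(b) if len(d.points) > 1]
            zs = smooth_branch_z(work, parent_z, daughters_z, cfg)
            # Skip P_0: it belongs to the parent branch (or soma/root).
            for pos in range(1, len(b.record_indices)):
                new_z[b.record_indices[pos]] = float(zs[pos])

    records = [
        replace(r, z=new_z[r.index]) if r.index in new_z else r for r in rec.records
    ]
    return Reconstruction(records, header=list(rec.header), source_name=rec.source_name)


def replace_points(branch: Branch, points: np.ndarray) -> Branch:
    """Copy of ``branch`` with substituted point coordinates."""
    return Branch(
        first_name=branch.first_name,
        structure_flag=branch.structure_flag,
        points=points,
        radii=branch.radii,
        record_indices=branch.record_indices,
        parent_branch=branch.parent_branch,
        daughter_branches=list(branch.daughter_branches),
        full_name=list(branch.full_name),
        strahler=branch.strahler,
        centrifugal_order=branch.centrifugal_order,
    )
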