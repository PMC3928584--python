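"""Empirical morphometric models, virtual-neuron growth, and the
deterministic synthetic fixture factory.

Once a cell class has been vertically compressed into branch tables, its
neuroanatomy is summarized as per-centrifugal-order empirical
distributions of branch length, taper, diameter, SOAM tortuosity,
bifurcation angle, and the per-order branching probability.  The
:class:`MorphometryModel` stores those raw value lists and can resample
them to grow an unlimited number of non-identical *virtual neurons*,
emitted as valid SWC reconstructions ready for network simulations.

The growth procedure is this package's own design: at each branch of
centrifugal order *o* it draws length, diameter, taper and a SOAM target
from the order-*o* distributions, realizes the branch as a random walk
whose per-step curvature matches the SOAM target (rescaled to the drawn
length), then continues with two daughters — placed at drawn bifurcation
angles around a uniformly random azimuth about the parent axis — with the
order-*o* branching probability.  Identical (model, seed) pairs produce
byte-identical SWC output.

The fixture factory (:func:`make_fixture`) builds small deterministic
trees — chains, Y-trees, complete binary trees — with exactly planned
topology, branch lengths, taper, per-bifurcation Rall exponents and
optional z-noise, for use as ground truth in tests.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .swc import Reconstruction, SwcRecord
from .statistics import BranchTable

__all__ = [
    "MorphometryModel",
    "GrowthConfig",
    "FixtureSpec",
    "fit_morphometry_model",
    "generate_virtual_neuron",
    "make_fixture",
]


# --------------------------------------------------------------------------
# model fitting

@dataclass
class OrderStats:
    """Raw per-centrifugal-order value lists kept for resampling."""

    lengths: list[float] = field(default_factory=list)
    taper_slopes: list[float] = field(default_factory=list)
    mean_diameters: list[float] = field(default_factory=list)
    soams: list[float] = field(default_factory=list)
    angles: list[float] = field(default_factory=list)
    n_branches: int = 0
    n_with_daughters: int = 0

    @property
    def branching_probability(self) -> float:
        if self.n_branches == 0:
            return 0.0
        return self.n_with_daughters / self.n_branches


@dataclass
class MorphometryModel:
    """Per-order empirical distributions of branch morphometrics.

    ``order_stats`` maps centrifugal order (1-based) to the pooled raw
    values observed at that order across all fitted cells.  Sampling is by
    empirical resampling (draw a stored value uniformly at random).
    """

    order_stats: dict[int, OrderStats]
    conditioning: str = "centrifugal"  # or "strahler"

    @property
    def max_order(self) -> int:
        return max(self.order_stats, default=0)

    def stats_for(self, order: int) -> OrderStats:
        """Stats at ``order``, clamped to the deepest observed order."""
        return self.order_stats[min(order, self.max_order)]

    def branching_probability(self, order: int) -> float:
        if order > self.max_order:
            return 0.0
        return self.order_stats[order].branching_probability

    def _pooled_angles(self) -> list[float]:
        out: list[float] = []
        for st in self.order_stats.values():
            out.extend(st.angles)
        return out

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "conditioning": self.conditioning,
            "orders": {
                str(o): {
                    "lengths": st.lengths,
                    "taper_slopes": st.taper_slopes,
                    "mean_diameters": st.mean_diameters,
                    "soams": st.soams,
                    "angles": st.angles,
                    "n_branches": st.n_branches,
                    "n_with_daughters": st.n_with_daughters,
                }
                for o, st in sorted(self.order_stats.items())
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MorphometryModel":
        payload = json.loads(text)
        stats = {
            int(o): OrderStats(
                lengths=d["lengths"],
                taper_slopes=d["taper_slopes"],
                mean_diameters=d["mean_diameters"],
                soams=d["soams"],
                angles=d["angles"],
                n_branches=d["n_branches"],
                n_with_daughters=d["n_with_daughters"],
            )
            for o, d in payload["orders"].items()
        }
        return cls(order_stats=stats, conditioning=payload.get("conditioning", "centrifugal"))


def fit_morphometry_model(
    tables: list[BranchTable], conditioning: str = "centrifugal"
) -> MorphometryModel:
    """Pool branch rows by order and record the empirical distributions.

    The branching probability at each order is the fraction of branches at
    that order that have daughters.  ``conditioning`` selects the order
    column: centrifugal (default) or Strahler.
    """
    if not tables or all(len(t) == 0 for t in tables):
        raise ValueError("fit_morphometry_model requires at least one non-empty table")
    col = {"centrifugal": "centrifugal_order", "strahler": "strahler"}[conditioning]
    pooled = pd.concat(tables, ignore_index=True)
    stats: dict[int, OrderStats] = {}
    for order, group in pooled.groupby(col):
        st = OrderStats(n_branches=len(group))
        st.n_with_daughters = int((group["n_daughters"] > 0).sum())
        for column, target in [
            ("length", st.lengths),
            ("taper_slope", st.taper_slopes),
            ("mean_diameter", st.mean_diameters),
            ("soam", st.soams),
            ("angle_to_parent", st.angles),
        ]:
            vals = group[column].to_numpy(dtype=float)
            target.extend(float(v) for v in vals[np.isfinite(vals)])
        stats[int(order)] = st
    return MorphometryModel(order_stats=stats, conditioning=conditioning)


# --------------------------------------------------------------------------
# virtual-neuron growth

@dataclass(frozen=True)
class GrowthConfig:
    """Knobs of the stochastic growth procedure."""

    seed: int = 0
    n_trees: int = 1
    max_branches: int = 10_000  # safety cap per neuron
    soma_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    soma_radius: float = 5.0
    structure_flag: int = 3
    step: float = 2.0  # target inter-point spacing in µm
    min_diameter: float = 0.1  # clip floor for tapered diameters, µm

    def __post_init__(self) -> None:
        if self.max_branches <= 0:
            raise ValueError("max_branches must be positive")


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle``."""
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1 - math.cos(angle))
    )


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A unit vector perpendicular to ``v`` at a uniformly random azimuth."""
    while True:
        r = rng.standard_normal(3)
        r -= np.dot(r, v) * v
        norm = np.linalg.norm(r)
        if norm > 1e-12:
            return r / norm


def _draw(rng: np.random.Generator, values: list[float], default: float) -> float:
    if not values:
        return default
    v = float(values[int(rng.integers(len(values)))])
    return default if not math.isfinite(v) else v


def _realize_branch(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    soam_target: float,
    cfg: GrowthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random-walk polyline from ``start`` with per-step curvature scaled
    to the SOAM target, rescaled to the drawn length exactly."""
    n_steps = max(3, int(round(length / cfg.step)))
    ds = length / n_steps
    pts = [start]
    d = direction.copy()
    for _ in range(n_steps):
        bend = soam_target * ds
        if bend > 0:
            axis = _perpendicular(d, rng)
            d = _rotate(d, axis, bend)
            d /= np.linalg.norm(d)
        pts.append(pts[-1] + d * ds)
    return np.asarray(pts)


def generate_virtual_neuron(
    model: MorphometryModel, cfg: GrowthConfig
) -> Reconstruction:
    """Grow one virtual neuron by order-conditioned resampling.

    Deterministic given (model, cfg): the same seed reproduces the output
    byte for byte.  The result always passes SWC validation.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SwcRecord] = []
    soma = SwcRecord(
        1, 1, *cfg.soma_position, cfg.soma_radius, -1
    )
    records.append(soma)
    next_index = 2
    branches_grown = 0
    truncated = False
    pooled_angles = model._pooled_angles()

    # explicit stack: (order, start_point, start_index, direction)
    for _tree in range(cfg.n_trees):
        d0 = rng.standard_normal(3)
        d0 /= np.linalg.norm(d0)
        stack: list[tuple[int, np.ndarray, int, np.ndarray]] = [
            (1, np.asarray(cfg.soma_position, dtype=float), 1, d0)
        ]
        while stack:
            order, start, start_index, direction = stack.pop()
            if branches_grown >= cfg.max_branches:
                truncated = True
                break
            branches_grown += 1
            st = model.stats_for(order)
            length = _draw(rng, st.lengths, 30.0)
            mean_d = max(_draw(rng, st.mean_diameters, 1.0), cfg.min_diameter)
            taper = _draw(rng, st.taper_slopes, 0.0)
            soam = max(_draw(rng, st.soams, 0.0), 0.0)
            pts = _realize_branch(start, direction, length, soam, cfg, rng)
            # linear taper around the drawn mean, clipped away from zero
            s = np.linspace(0.0, length, len(pts))
            diam = np.clip(mean_d + taper * (s - length / 2.0), cfg.min_diameter, None)
            parent_idx = start_index
            for p, dm in zip(pts[1:], diam[1:]):
                records.append(
                    SwcRecord(
                        next_index, cfg.structure_flag,
                        float(p[0]), float(p[1]), float(p[2]),
                        float(dm / 2.0), parent_idx,
                    )
                )
                parent_idx = next_index
                next_index += 1
            end_index = parent_idx
            end_dir = pts[-1] - pts[-2]
            end_dir = end_dir / np.linalg.norm(end_dir)
            if rng.random() < model.branching_probability(order):
                angle_stats = model.stats_for(order + 1).angles or pooled_angles
                a1 = _draw(rng, angle_stats, math.pi / 4)
                a2 = _draw(rng, angle_stats, math.pi / 4)
                azimuth = _perpendicular(end_dir, rng)
                d1 = _rotate(end_dir, azimuth, a1)
                d2 = _rotate(end_dir, azimuth, -a2)  # opposite side of the parent axis
                for dd in (d1, d2):
                    stack.append(
                        (order + 1, pts[-1], end_index, dd / np.linalg.norm(dd))
                    )
        if truncated:
            break
    if truncated:
        warnings.warn(
            f"virtual neuron truncated at the {cfg.max_branches}-branch safety cap"
        )
    header = [
        "# virtual neuron grown by morphotree",
        f"# seed={cfg.seed} trees={cfg.n_trees} conditioning={model.conditioning}",
    ]
    return Reconstruction(records, header=header, source_name=f"virtual-seed{cfg.seed}")


# --------------------------------------------------------------------------
# deterministic fixtures

@dataclass(frozen=True)
class FixtureSpec:
    """Plan for a deterministic synthetic SWC tree.

    ``template`` is ``"chain"`` (one branch), ``"ytree"`` (a stem with two
    daughters) or ``"binary"`` (complete binary tree of ``depth`` levels,
    2**depth − 1 branches).  Branch lengths are ``branch_length`` scaled
    by a seeded jitter of relative amplitude ``length_jitter``; daughters
    leave their parent's axis at ``±daughter_angle_deg`` in the xy-plane,
    so the noise-free tree is planar (z = 0).  Diameters taper linearly at
    ``taper_slope`` within each branch and step down across bifurcations
    so that every branch point realizes exactly ``rall_exponent``.
    ``z_noise`` adds i.i.d. uniform(−a, +a) noise to every non-soma z;
    the z_noise=0 twin of the same spec is the ground truth for it.
    """

    template: str = "ytree"
    depth: int = 3  # binary template only
    branch_length: float = 50.0
    length_jitter: float = 0.0
    points_per_branch: int = 10  # own records per branch
    daughter_angle_deg: float = 60.0
    wiggle: float = 0.0  # in-plane sinusoid amplitude, µm
    taper_slope: float = 0.0  # µm diameter per µm length
    root_diameter: float = 2.0
    rall_exponent: float = 1.5
    z_noise: float = 0.0
    seed: int = 0
    structure_flag: int = 3
    soma_radius: float = 5.0


def _fixture_branch_points(
    start: np.ndarray, direction: np.ndarray, length: float, npts: int, wiggle: float
) -> np.ndarray:
    """Polyline of ``npts`` own points after ``start``, planar, with total
    arc length exactly ``length``."""
    t = np.linspace(0.0, 1.0, npts + 1)[:, None]
    perp = np.array([-direction[1], direction[0], 0.0])
    pts = start + direction * (t * length)
    if wiggle > 0:
        pts = pts + perp * (wiggle * np.sin(2 * math.pi * 2 * t))
        # rescale about the start so the arc length is exact
        arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        pts = start + (pts - start) * (length / arc)
    return pts


def make_fixture(spec: FixtureSpec) -> Reconstruction:
    """Build the planned synthetic reconstruction (see FixtureSpec)."""
    rng = np.random.default_rng(spec.seed)
    if spec.template == "chain":
        n_levels = 1
    elif spec.template == "ytree":
        n_levels = 2
    elif spec.template == "binary":
        n_levels = spec.depth
    else:
        raise ValueError(f"unknown template {spec.template!r}")

    records: list[SwcRecord] = [
        SwcRecord(1, 1, 0.0, 0.0, 0.0, spec.soma_radius, -1)
    ]
    next_index = 2
    rall_ratio = 2.0 ** (-1.0 / spec.rall_exponent)
    ang = math.radians(spec.daughter_angle_deg)

    # (level, start, parent_record_index, direction_angle_in_plane, start_diameter)
    stack = [(1, np.zeros(3), 1, math.pi / 2, spec.root_diameter)]
    while stack:
        level, start, parent_idx, theta, d_start = stack.pop()
        direction = np.array([math.cos(theta), math.sin(theta), 0.0])
        length = spec.branch_length * (
            1.0 + spec.length_jitter * float(rng.uniform(-1.0, 1.0))
        )
        pts = _fixture_branch_points(
            start, direction, length, spec.points_per_branch, spec.wiggle
        )
        s = np.linspace(0.0, length, spec.points_per_branch + 1)
        diam = d_start + spec.taper_slope * s
        idx = parent_idx
        for p, dm in zip(pts[1:], diam[1:]):
            records.append(
                SwcRecord(
                    next_index, spec.structure_flag,
                    float(p[0]), float(p[1]), float(p[2]),
                    float(dm / 2.0), idx,
                )
            )
            idx = next_index
            next_index += 1
        if level < n_levels:
            d_end = float(diam[-1])
            d_daughter = d_end * rall_ratio
            stack.append((level + 1, pts[-1], idx, theta + ang, d_daughter))
            stack.append((level + 1, pts[-1], idx, theta - ang, d_daughter))

    if spec.z_noise > 0:
        noisy = []
        for r in records:
            if r.structure_flag == 1:
                noisy.append(r)
            else:
                dz = float(rng.uniform(-spec.z_noise, spec.z_noise))
                noisy.append(SwcRecord(r.index, r.structure_flag, r.x, r.y, r.z + dz, r.radius, r.parent_index))
        records = noisy

    header = [
        f"# synthetic fixture template={spec.template} seed={spec.seed}",
        f"# planned rall_exponent={spec.rall_exponent} z_noise={spec.z_noise}",
    ]
    return Reconstruction(records, header=header, source_name=f"fixture-{spec.template}")
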