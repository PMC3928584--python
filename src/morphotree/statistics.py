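"""Branch tables ("vertical compression") and group distribution
summaries.

Once the accumulative parameters of every branch are known, the
reconstruction is *vertically compressed* into a table with one row per
branch carrying its topology, metrics, and the bifurcation measurements
at its distal end.  Populations of cells are then characterized by
frequency distributions of those parameters: per-cell histograms whose
bin count follows Sturges' rule, k = ⌈1 + log₂ n⌉, summarized across
cells as a per-bin mean ± standard error of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .branch_geometry import Bifurcation, find_bifurcations
from .morphometry import measure_branch
from .topology import BranchForest

__all__ = [
    "BranchTable",
    "DistributionSummary",
    "vertical_compress",
    "sturges_bins",
    "group_distribution",
    "DEFAULT_PARAMETERS",
]

#: A branch table is simply a pandas DataFrame with one row per branch.
BranchTable = pd.DataFrame

#: Parameters summarized by default (the classic per-branch panel set).
DEFAULT_PARAMETERS = (
    "length",
    "mean_diameter",
    "dm",
    "soam",
    "angle_to_parent",
    "euclidean_to_soma",
    "path_to_soma",
)

#: Dendritic structure flags (basal, apical) used by the default analyses.
DENDRITE_FLAGS = (3, 4)


def vertical_compress(
    forest: BranchForest,
    cell_id: str = "cell",
    m_segments: int = 5,
    flags: tuple[int, ...] | None = None,
) -> BranchTable:
    """One row per branch: topology, metrics, distal bifurcation fields.

    Missing values (undefined DM, Rall exponent, angle of a root branch)
    propagate as NaN.  ``flags`` optionally restricts the table to given
    structure flags (e.g. dendrites only); default keeps every branch.
    """
    bifs = {b.parent_name: b for b in find_bifurcations(forest, m=m_segments)}
    # angle of each branch w.r.t. its parent, looked up from the parent's
    # bifurcation record
    angle_of: dict[int, float] = {}
    for bif in bifs.values():
        for name, ang in zip(bif.daughter_names, bif.angles):
            angle_of[name] = ang

    rows = []
    for b in forest:
        if flags is not None and b.structure_flag not in flags:
            continue
        metrics = measure_branch(b, forest)
        bif: Bifurcation | None = bifs.get(b.first_name)
        rows.append(
            {
                "cell_id": cell_id,
                "first_name": b.first_name,
                "full_name": "-".join(map(str, b.full_name)),
                "structure_flag": b.structure_flag,
                "segment_count": b.segment_count,
                "parent_branch": b.parent_branch if b.parent_branch is not None else np.nan,
                "n_daughters": len(b.daughter_branches),
                "strahler": b.strahler,
                "centrifugal_order": b.centrifugal_order,
                "length": metrics.length,
                "euclidean_to_soma": metrics.euclidean_to_soma,
                "path_to_soma": metrics.path_to_soma,
                "taper_slope": metrics.taper_slope,
                "mean_diameter": metrics.mean_diameter,
                "diameter_sem": metrics.diameter_sem,
                "dm": metrics.dm,
                "soam": metrics.soam,
                "angle_to_parent": angle_of.get(b.first_name, np.nan),
                "rall_exponent": bif.rall_exponent if bif is not None else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) != (
        len(forest) if flags is None else sum(1 for b in forest if b.structure_flag in flags)
    ):
        raise RuntimeError("internal consistency error: row/branch count mismatch")
    return table


def sturges_bins(values: np.ndarray | list[float]) -> np.ndarray:
    """Equal-width bin edges per Sturges' rule, k = ⌈1 + log₂ n⌉.

    The bins span [min, max]; identical values get a single bin widened by
    ±0.5 so the histogram is still well defined.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 1:
        raise ValueError("sturges_bins requires at least one finite value")
    k = math.ceil(1 + math.log2(n)) if n > 1 else 1
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return np.array([lo - 0.5, hi + 0.5])
    return np.linspace(lo, hi, k + 1)


@dataclass
class DistributionSummary:
    """Sturges-binned frequency distribution of one parameter over one
    group of cells: per-cell counts plus the across-cell mean ± SEM."""

    parameter: str
    bin_edges: np.ndarray  # (k+1,)
    counts: np.ndarray  # (n_cells, k)
    cell_ids: list[str]
    mean: np.ndarray  # (k,)
    sem: np.ndarray  # (k,), NaN for a single-cell group

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "bin_edges": self.bin_edges.tolist(),
            "cell_ids": self.cell_ids,
            "counts": self.counts.tolist(),
            "mean": self.mean.tolist(),
            "sem": self.sem.tolist(),
            "n_cells": self.n_cells,
        }


def group_distribution(
    tables: list[BranchTable],
    parameter: str,
    bin_edges: np.ndarray | None = None,
) -> DistributionSummary:
    """Histogram a parameter per cell and summarize across cells.

    Bin edges default to Sturges' rule on the pooled finite values of the
    group; pass ``bin_edges`` explicitly (e.g. another group's edges) to
    compare distributions on a shared binning.  The rightmost bin is
    closed, so per-cell counts always sum to that cell's number of finite
    values.  SEM uses the n−1 standard deviation over cells; a single-cell
    group reports NaN rather than 0.
    """
    if not tables:
        raise ValueError("group_distribution requires at least one table")
    for t in tables:
        if parameter not in t.columns:
            raise KeyError(f"parameter {parameter!r} not present in branch table")
    pooled = np.concatenate([t[parameter].to_numpy(dtype=float) for t in tables])
    pooled = pooled[np.isfinite(pooled)]
    if bin_edges is None:
        bin_edges = sturges_bins(pooled)
    bin_edges = np.asarray(bin_edges, dtype=float)

    counts = []
    cell_ids = []
    for t in tables:
        v = t[parameter].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        c, _ = np.histogram(v, bins=bin_edges)
        # values outside explicit shared bins would be dropped silently;
        # clip-count them into the extreme bins instead
        c[0] += int(np.sum(v < bin_edges[0]))
        c[-1] += int(np.sum(v > bin_edges[-1]))
        counts.append(c)
        cell_ids.append(str(t["cell_id"].iloc[0]) if len(t) else "<empty>")
    counts_arr = np.asarray(counts)
    mean = counts_arr.mean(axis=0)
    if len(tables) > 1:
        sem = counts_arr.std(axis=0, ddof=1) / math.sqrt(len(tables))
    else:
        sem = np.full(counts_arr.shape[1], np.nan)
    return DistributionSummary(
        parameter=parameter,
        bin_edges=bin_edges,
        counts=counts_arr,
        cell_ids=cell_ids,
        mean=mean,
        sem=sem,
    )
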