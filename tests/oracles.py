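"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms and data structures than the
package: union-find over segment pairs for the branch partition, and a
node-level recursion for Strahler orders.
"""

from __future__ import annotations

import numpy as np

from morphotree.swc import Reconstruction


def brute_force_branch_partition(rec: Reconstruction) -> set[frozenset[int]]:
    """Partition of non-soma segments into branches by union-find.

    A segment is identified by its child record index.  Two chained
    segments (p→c) and (c→k) are merged iff c and k share a structure
    flag and c has exactly one child anywhere in the matrix.
    """
    index_map = {r.index: r for r in rec.records}
    n_children: dict[int, int] = {}
    for r in rec.records:
        if not r.is_root:
            n_children[r.parent_index] = n_children.get(r.parent_index, 0) + 1

    segs = [r.index for r in rec.records if not r.is_root and r.structure_flag != 1]
    parent_uf = {s: s for s in segs}

    def find(a: int) -> int:
        while parent_uf[a] != a:
            parent_uf[a] = parent_uf[parent_uf[a]]
            a = parent_uf[a]
        return a

    def union(a: int, b: int) -> None:
        parent_uf[find(a)] = find(b)

    for c in segs:
        child_rec = index_map[c]
        p = child_rec.parent_index
        if p in parent_uf:  # the upstream segment exists and is non-soma
            p_rec = index_map[p]
            if (
                p_rec.structure_flag == child_rec.structure_flag
                and n_children.get(p, 0) == 1
            ):
                union(c, p)

    groups: dict[int, set[int]] = {}
    for s in segs:
        groups.setdefault(find(s), set()).add(s)
    return {frozenset(g) for g in groups.values()}


def node_strahler(rec: Reconstruction) -> dict[int, int]:
    """Strahler order of every record, computed on the node tree.

    Leaves are 1; an internal node takes the maximum order of its
    children, incremented when at least two children attain it.
    """
    children: dict[int, list[int]] = {}
    for r in rec.records:
        if not r.is_root:
            children.setdefault(r.parent_index, []).append(r.index)
    order: dict[int, int] = {}
    stack = [(r.index, False) for r in rec.roots]
    while stack:
        idx, expanded = stack.pop()
        kids = children.get(idx, [])
        if not expanded:
            stack.append((idx, True))
            stack.extend((k, False) for k in kids)
        else:
            if not kids:
                order[idx] = 1
            else:
                vals = [order[k] for k in kids]
                m = max(vals)
                order[idx] = m + 1 if vals.count(m) >= 2 else m
    return order


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Normal-equations OLS slope (independent of numpy.polyfit)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())


def grid_search_rall(d_eq: float, daughters: list[float],
                     lo: float = 0.05, hi: float = 20.0, step: float = 1e-4) -> float:
    """Dense grid minimizer of |d_eq^E - sum d_i^E| (exponent oracle)."""
    grid = np.arange(lo, hi + step, step)
    di = np.asarray(daughters)
    err = np.abs(d_eq ** grid - (di[None, :] ** grid[:, None]).sum(axis=1))
    return float(grid[np.argmin(err)])
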