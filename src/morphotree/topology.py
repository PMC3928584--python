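"""Branch identification, genealogy (first-/full-names) and tree ordering.

A *branch* is a maximal unbranched chain of segments.  Two connected
segments belong to the same branch only if (i) the parent index of the
second equals the index of the first, (ii) both share the same structure
flag, and (iii) no other segment in the whole matrix shares that parent
index.  A branch therefore ends exactly at a bifurcation, at a structure
flag change, or at a tip.

Each branch gets a unique integer *first-name* (assigned depth-first in
file order) and a *full-name*: the ordered list of ancestor first-names
back to the soma ending with its own.  Full-name length equals the number
of ancestors plus one — the *centrifugal order*.

Strahler ordering is purely topological: terminal branches are order 1;
when two or more daughters of maximal order *m* meet, the parent is order
*m + 1*; when a branch of order *m* meets one of order *n > m*, the parent
continues order *n*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .swc import Reconstruction, SwcRecord, SOMA_FLAG, validate_reconstruction

__all__ = [
    "Branch",
    "BranchForest",
    "TopologyError",
    "identify_branches",
    "assign_full_names",
    "strahler_order",
    "build_forest",
]


class TopologyError(ValueError):
    """Raised for corrupt genealogies (cycles, orphans)."""


@dataclass
class Branch:
    """A maximal unbranched chain of segments.

    ``points`` holds the m+1 successive 3D points P_0..P_m of the chain
    (P_0 is the attachment point, owned by the parent branch or the soma);
    ``radii`` the radius recorded at each point.  ``record_indices`` are
    the SWC indices of those points, in order.
    """

    first_name: int
    structure_flag: int
    points: np.ndarray  # (m+1, 3)
    radii: np.ndarray  # (m+1,)
    record_indices: list[int]
    parent_branch: int | None = None
    daughter_branches: list[int] = field(default_factory=list)
    full_name: list[int] = field(default_factory=list)
    strahler: int = 0
    centrifugal_order: int = 0

    @property
    def segment_count(self) -> int:
        return len(self.points) - 1

    @property
    def is_terminal(self) -> bool:
        return not self.daughter_branches

    @property
    def is_root(self) -> bool:
        return self.parent_branch is None

    @property
    def start_point(self) -> np.ndarray:
        return self.points[0]

    @property
    def end_point(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class BranchForest:
    """All branches of a reconstruction, keyed by first-name.

    Every non-soma segment belongs to exactly one branch (partition
    property); there is one root branch per dendritic/axonal tree.
    """

    branches: dict[int, Branch]
    roots: list[int]
    reconstruction: Reconstruction

    def __len__(self) -> int:
        return len(self.branches)

    def __iter__(self):
        return iter(self.branches.values())

    def __getitem__(self, first_name: int) -> Branch:
        return self.branches[first_name]

    def total_segments(self) -> int:
        return sum(b.segment_count for b in self.branches.values())

    def daughters(self, branch: Branch) -> list[Branch]:
        return [self.branches[d] for d in branch.daughter_branches]

    def parent(self, branch: Branch) -> Branch | None:
        if branch.parent_branch is None:
            return None
        return self.branches[branch.parent_branch]

    def tree_root_point(self, branch: Branch) -> np.ndarray:
        """Start point of the root branch of this branch's tree (the soma
        attachment point used as origin for soma distances)."""
        b = branch
        seen = 0
        while b.parent_branch is not None:
            b = self.branches[b.parent_branch]
            seen += 1
            if seen > len(self.branches):
                raise TopologyError("cycle in branch genealogy")
        return b.start_point

    def max_strahler(self) -> int:
        return max((b.strahler for b in self.branches.values()), default=0)


def identify_branches(rec: Reconstruction, *, check: bool = True) -> BranchForest:
    """Partition all non-soma segments of ``rec`` into branches.

    First-names are sequential integers starting at 1, assigned in
    depth-first traversal of the file order.  Soma (flag-1) segments are
    never part of a branch; a dendrite or axon attached to a soma point
    roots its own tree there.

    With ``check=True`` the reconstruction is validated first and the
    function refuses (raises :class:`TopologyError`) if error-level
    findings exist.
    """
    if check:
        findings = [f for f in validate_reconstruction(rec) if f.severity == "error"]
        if findings:
            raise TopologyError(
                "reconstruction has validation findings; fix before branch "
                "identification: " + "; ".join(str(f) for f in findings)
            )

    index_map = {r.index: r for r in rec.records}
    children = rec.children_map()

    def is_branch_start(child: SwcRecord) -> bool:
        # The segment (parent, child) opens a new branch when the chain is
        # broken before it: no parent record, a flag change (incl. soma),
        # or a bifurcation at the parent.
        parent = index_map[child.parent_index]
        if parent.structure_flag != child.structure_flag:
            return True
        if len(children.get(parent.index, ())) >= 2:
            return True
        if parent.is_root:
            # Root record with a single same-flag child: the root point is
            # simply P_0 of this branch, not a branch of its own.
            return True
        return False

    branches: dict[int, Branch] = {}
    roots: list[int] = []
    # end-record index -> first_name, to wire parent branches afterwards
    end_of_branch: dict[int, int] = {}
    next_name = 1

    for root in rec.roots:
        # Depth-first over records, in file order.
        stack = list(reversed(children.get(root.index, [])))
        # Soma/flag handling is uniform: walk every record; open a branch at
        # every start segment whose child is non-soma.
        while stack:
            r = stack.pop()
            if r.structure_flag == SOMA_FLAG:
                stack.extend(reversed(children.get(r.index, [])))
                continue
            if not is_branch_start(r):
                # Consumed while extending the branch that contains it.
                continue
            # Build the maximal chain starting with segment (parent, r).
            parent = index_map[r.parent_index]
            chain = [parent, r]
            cur = r
            while True:
                kids = children.get(cur.index, [])
                if len(kids) == 1 and kids[0].structure_flag == cur.structure_flag:
                    cur = kids[0]
                    chain.append(cur)
                else:
                    stack.extend(reversed(kids))
                    break
            pts = np.array([c.xyz for c in chain], dtype=float)
            rad = np.array([c.radius for c in chain], dtype=float)
            branch = Branch(
                first_name=next_name,
                structure_flag=r.structure_flag,
                points=pts,
                radii=rad,
                record_indices=[c.index for c in chain],
            )
            branches[next_name] = branch
            end_of_branch[chain[-1].index] = next_name
            next_name += 1

    # Wire the genealogy: a branch's parent is the branch ending at its P_0
    # record, unless that record is soma/root (then this branch roots a tree).
    for b in branches.values():
        p_rec = index_map[b.record_indices[0]]
        name = end_of_branch.get(p_rec.index)
        if name is not None:
            b.parent_branch = name
            branches[name].daughter_branches.append(b.first_name)
        else:
            roots.append(b.first_name)
    roots.sort()

    return BranchForest(branches=branches, roots=roots, reconstruction=rec)


def assign_full_names(forest: BranchForest) -> BranchForest:
    """Compute every branch's full-name and centrifugal order, in place.

    A root branch's full-name is ``[own first-name]``; every other branch
    appends its first-name to its parent's full-name, so a branch's
    full-name is always its parent's plus one element.
    """
    visited = 0
    stack = [forest.branches[r] for r in forest.roots]
    for b in stack:
        b.full_name = [b.first_name]
        b.centrifugal_order = 1
    stack = list(stack)
    while stack:
        b = stack.pop()
        visited += 1
        if visited > len(forest.branches):
            raise TopologyError("cycle detected while building genealogy")
        for d in forest.daughters(b):
            d.full_name = b.full_name + [d.first_name]
            d.centrifugal_order = len(d.full_name)
            stack.append(d)
    if visited != len(forest.branches):
        raise TopologyError("genealogy does not reach every branch (orphans)")
    return forest


def strahler_order(forest: BranchForest) -> BranchForest:
    """Assign Strahler orders to every branch, in place.

    Terminals get order 1.  A parent whose daughters attain maximum order
    *M* at least twice gets *M + 1*; otherwise it continues order *M*.
    The rule generalizes unchanged to trifurcations and beyond.
    """
    # Iterative post-order to survive deep chains.
    for root in forest.roots:
        stack: list[tuple[Branch, bool]] = [(forest.branches[root], False)]
        while stack:
            b, expanded = stack.pop()
            if not expanded:
                stack.append((b, True))
                for d in forest.daughters(b):
                    stack.append((d, False))
            else:
                if b.is_terminal:
                    b.strahler = 1
                else:
                    orders = [d.strahler for d in forest.daughters(b)]
                    m = max(orders)
                    b.strahler = m + 1 if orders.count(m) >= 2 else m
    return forest


def build_forest(rec: Reconstruction, *, check: bool = True) -> BranchForest:
    """Identify branches, build the genealogy and assign Strahler orders."""
    forest = identify_branches(rec, check=check)
    assign_full_names(forest)
    strahler_order(forest)
    return forest
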