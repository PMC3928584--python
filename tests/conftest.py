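import numpy as np
import pytest

from morphotree.swc import Reconstruction, SwcRecord, parse_swc
from morphotree.topology import Branch, build_forest

CHAIN_SWC = """\
1 1 0 0 0 1 -1
2 3 1 0 0 0.5 1
3 3 2 0 0 0.5 2
"""

# root record 1 (dendrite), stem 1-2-3, then two single-segment daughters
YTREE_SWC = """\
# synthetic Y tree
# two header lines
1 3 0 0 0 1 -1
2 3 0 1 0 1 1
3 3 0 2 0 1 2
4 3 1 3 0 0.5 3
5 3 -1 3 0 0.5 3
"""


@pytest.fixture
def chain_rec() -> Reconstruction:
    return parse_swc(CHAIN_SWC, "chain")


@pytest.fixture
def ytree_rec() -> Reconstruction:
    return parse_swc(YTREE_SWC, "ytree")


@pytest.fixture
def ytree_forest(ytree_rec):
    return build_forest(ytree_rec)


def make_branch(points, radii=None, first_name=1, flag=3) -> Branch:
    """Assemble a standalone Branch from raw coordinates for metric tests."""
    pts = np.asarray(points, dtype=float)
    if radii is None:
        radii = np.ones(len(pts))
    return Branch(
        first_name=first_name,
        structure_flag=flag,
        points=pts,
        radii=np.asarray(radii, dtype=float),
        record_indices=list(range(1, len(pts) + 1)),
        full_name=[first_name],
        centrifugal_order=1,
    )


def random_reconstruction(rng: np.random.Generator, n_nodes: int,
                          flag_switch_prob: float = 0.0) -> Reconstruction:
    """A random single-root tree in SWC form (no soma, dendrite flags).

    Each new record attaches to a uniformly chosen earlier record with a
    random nonzero offset; with ``flag_switch_prob`` a subtree flips from
    basal (3) to apical (4), exercising flag-change branch boundaries.
    """
    records = [SwcRecord(1, 3, 0.0, 0.0, 0.0, 1.0, -1)]
    for i in range(2, n_nodes + 1):
        parent = records[int(rng.integers(len(records)))]
        offset = rng.normal(scale=3.0, size=3)
        while np.linalg.norm(offset) < 1e-3:
            offset = rng.normal(scale=3.0, size=3)
        flag = parent.structure_flag
        if flag == 3 and rng.random() < flag_switch_prob:
            flag = 4
        records.append(
            SwcRecord(
                i, flag,
                parent.x + float(offset[0]),
                parent.y + float(offset[1]),
                parent.z + float(offset[2]),
                float(rng.uniform(0.2, 1.0)),
                parent.index,
            )
        )
    return Reconstruction(records, source_name=f"random-{n_nodes}")
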