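import numpy as np
import pytest

from riparia.core import CommunityTable, PhyloTree


@pytest.fixture
def toy_table():
    counts = np.array(
        [
            [5, 0, 3, 2],
            [1, 4, 0, 5],
            [0, 2, 2, 6],
        ]
    )
    return CommunityTable(counts, ["s1", "s2", "s3"], ["A", "B", "C", "D"])


@pytest.fixture
def small_tree():
    return PhyloTree.from_newick(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def balanced8_tree():
    nwk = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    return PhyloTree.from_newick([nwk])
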