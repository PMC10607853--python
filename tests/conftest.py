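import numpy as np
import pandas as pd
import pytest
import skbio

from assemblyscope.io_core import CommunityTable, PhyloTree

FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def four_tip_tree() -> PhyloTree:
    return PhyloTree(skbio.TreeNode.read([FOUR_TIP_NEWICK]))


def make_table(counts, sample_ids=None, taxon_ids=None, metadata=None,
               altitudes=None, seasons=None):
    counts = np.asarray(counts)
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(counts.shape[0])]
    if taxon_ids is None:
        taxon_ids = [f"T{j + 1}" for j in range(counts.shape[1])]
    if metadata is None and (altitudes is not None or seasons is not None):
        metadata = pd.DataFrame(
            {
                "altitude": altitudes if altitudes is not None else 1000.0,
                "season": seasons if seasons is not None else "warm",
                "site": "x",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    return CommunityTable(counts, sample_ids, taxon_ids, metadata,
                          allow_empty_samples=True)


@pytest.fixture
def small_table() -> CommunityTable:
    return make_table([[5, 0, 3], [0, 5, 2], [2, 2, 4]])


def random_table(rng, n_samples=10, n_taxa=20, taxon_ids=None, density=0.7):
    counts = rng.integers(0, 50, size=(n_samples, n_taxa))
    counts *= rng.random((n_samples, n_taxa)) < density
    # guarantee non-empty samples
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_taxa)] = 1
    return make_table(counts, taxon_ids=taxon_ids)
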