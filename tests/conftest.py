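import numpy as np
import pandas as pd
import pytest

from benthicom import CommunityTable, PhyloTree, SampleMetadata, TaxonomyMap
import dendropy


@pytest.fixture
def small_table() -> CommunityTable:
    data = pd.DataFrame(
        [[10, 5, 0], [3, 4, 2]],
        index=["S1", "S2"],
        columns=["ASV_1", "ASV_2", "ASV_3"],
    )
    return CommunityTable(data=data, domain="bacteria")


@pytest.fixture
def two_group_table() -> CommunityTable:
    rng = np.random.default_rng(7)
    counts = rng.multinomial(1000, np.full(20, 0.05), size=12)
    data = pd.DataFrame(
        counts,
        index=[f"BG_{i}" for i in range(1, 7)] + [f"CG_{i}" for i in range(1, 7)],
        columns=[f"ASV_{j}" for j in range(1, 21)],
    )
    return CommunityTable(data=data, domain="bacteria")


@pytest.fixture
def metadata(two_group_table) -> SampleMetadata:
    frame = pd.DataFrame(
        {"group": ["BG"] * 6 + ["CG"] * 6}, index=two_group_table.sample_ids
    )
    return SampleMetadata(frame=frame)


@pytest.fixture
def toy_tree() -> PhyloTree:
    tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    return PhyloTree(tree=tree)


@pytest.fixture
def taxonomy() -> TaxonomyMap:
    return TaxonomyMap.from_lineage_strings({
        "ASV_1": "Proteobacteria;Gammaproteobacteria",
        "ASV_2": "Proteobacteria",
        "ASV_3": "Firmicutes",
    })
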