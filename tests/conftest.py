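import numpy as np
import pytest

import protasr as pa


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_alignment():
    return pa.Alignment(list("ABCD"),
                        ["MK-AW-", "MR-AW-", "LKCAW-", "MKCVW-"],
                        name="toy")


@pytest.fixture
def four_taxon_tree():
    return pa.read_newick("((A:0.3,B:0.12):0.2,C:0.5,D:0.08);")


@pytest.fixture
def six_taxon_unrooted():
    return pa.read_newick(
        "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,(E:0.1,F:0.1):0.1);")


@pytest.fixture
def six_taxon_rooted(six_taxon_unrooted):
    return pa.root_by_outgroup(six_taxon_unrooted, {"A", "B"})
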