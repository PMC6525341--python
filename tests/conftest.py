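import numpy as np
import pytest

import lsekit as lk
from lsekit.gainloss import BDParams
from lsekit.simulate import ADEPHAGA_TIPS, POLYPHAGA_TIPS, fixture_clade_map


@pytest.fixture(scope="session")
def beetle_tree():
    return lk.fixture_tree()


@pytest.fixture(scope="session")
def clade_map():
    return fixture_clade_map()


@pytest.fixture(scope="session")
def group_map():
    gm = {s: "A" for s in ADEPHAGA_TIPS}
    gm.update({s: "P" for s in POLYPHAGA_TIPS})
    return gm


@pytest.fixture
def three_tip_tree():
    return lk.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_painted_tree():
    """Six-tip ultrametric tree painted into two three-tip regimes."""
    nwk = "(((A:20,B:20):30,C:50):50,((D:35,E:35):25,F:60):40);"
    ptree = lk.read_newick(nwk)
    return lk.paint_regimes(
        ptree, {"L": {"A", "B", "C"}, "R": {"D", "E", "F"}}, root_regime="root"
    )


@pytest.fixture
def bd_params():
    return BDParams(0.002, 0.0018)
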