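import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from cladesum import SimulationConfig, Tree, parse_newick, simulate_serial_tree


@pytest.fixture
def balanced_six_tip() -> Tree:
    return parse_newick("((A:1,B:1):2,((C:1,D:1):1,(E:1,F:1):1):1);")


@pytest.fixture
def serial_tree() -> Tree:
    """A 6-tip tree with one fossil tip, used for MCMC-scale tests."""
    return simulate_serial_tree(SimulationConfig(n_extant=5, n_fossil=1, seed=4))


def random_time_tree(n_tips: int, seed: int, n_fossil: int = 0) -> Tree:
    """Small random serially sampled tree (test helper, not a fixture)."""
    return simulate_serial_tree(
        SimulationConfig(n_extant=n_tips - n_fossil, n_fossil=n_fossil,
                         death_rate=0.4 if n_fossil else 0.0, seed=seed)
    )


@pytest.fixture
def toy_nexus_sample(tmp_path):
    """A 4-tree NEXUS .t file with a translate table (3 identical + 1 variant)."""
    text = """#NEXUS
begin trees;
\ttranslate
\t\t1 A,
\t\t2 B,
\t\t3 C,
\t\t4 D;
\ttree gen.0 = [&R] ((1:1,2:1):1,(3:1,4:1):1);
\ttree gen.1 = [&R] ((1:1,2:1):1,(3:1,4:1):1);
\ttree gen.2 = [&R] ((1:1,2:1):1,(3:1,4:1):1);
\ttree gen.3 = [&R] ((1:1,3:1):1,(2:1,4:1):1);
end;
"""
    path = tmp_path / "toy.t"
    path.write_text(text)
    return path
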