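import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message="The hashes produced for directed graphs")

from rnascreen.pockets import DEFAULT_RELATION_VOCAB, PocketGraph
from rnascreen.synthetic import gen_library, make_benchmark


def build_path_graph(n: int, pocket_id: str = "path", nts: str | None = None) -> PocketGraph:
    """A simple single-chain backbone path of n nucleotides."""
    g = PocketGraph(pocket_id, DEFAULT_RELATION_VOCAB)
    nts = nts or ("ACGU" * n)[:n]
    for i in range(n):
        g.add_node(f"A.{i + 1}", nts[i])
    for i in range(n - 1):
        g.add_interaction(f"A.{i + 1}", f"A.{i + 2}", "B53")
    return g


@pytest.fixture(scope="session")
def small_library():
    return gen_library(40, seed=11)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted benchmark shared by screening/robustness tests."""
    return make_benchmark(n_pockets=10, n_compounds=80, seed=3)
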