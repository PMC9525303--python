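import warnings

import numpy as np
import pytest

from phylogeo.io import Alignment
from phylogeo.simulate import sim_env_occurrences, sim_phylogeography

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")
try:
    from sklearn.exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def phylo_bundle():
    """One mid-sized phylogeographic bundle shared across tests."""
    return sim_phylogeography(seed=42, n_tips=16, n_regions=3, seq_len=400)


@pytest.fixture(scope="session")
def env_bundle_small():
    """A small environmental bundle (fast; 2 informative, 2 noise)."""
    return sim_env_occurrences(
        seed=7, nx=40, ny=30, n_informative=2, n_noise=2, n_redundant=1,
        n_presence=120,
    )


@pytest.fixture()
def tiny_alignment():
    return Alignment(
        ids=["a", "b", "c", "d", "e"],
        seqs=["ACGTACGT", "ACGTACGT", "ACGTACGA", "AC--ACGT", "ACGTACGT"],
        meta={
            "a": {"region": "DIN", "population": "p1"},
            "b": {"region": "DIN", "population": "p1"},
            "c": {"region": "SC", "population": "p2"},
            "d": {"region": "EC", "population": "p3"},
            "e": {"region": "SC", "population": "p2"},
        },
    )


def random_haplotype_instance(rng: np.random.Generator):
    """A random alignment with <=8 distinct sequences over <=6 varying
    columns, for network-oracle tests."""
    n_var = int(rng.integers(2, 7))
    n_hap = int(rng.integers(2, min(8, 2**n_var) + 1))
    n_const = 20
    seqs = set()
    while len(seqs) < n_hap:
        seqs.add("".join("ACGT"[i] for i in rng.integers(0, 2, n_var)))
    seqs = sorted(seqs)
    const = "".join("ACGT"[i] for i in rng.integers(0, 4, n_const))
    ids = [f"s{i}" for i in range(len(seqs))]
    return Alignment(ids=ids, seqs=[s + const for s in seqs])
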