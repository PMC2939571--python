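import numpy as np
import pytest

from wboot import Alignment, Alphabet, simulate_alignment


@pytest.fixture
def small_dna():
    """4-taxon, 8-column DNA alignment with one clear split."""
    return Alignment(
        ("A", "B", "C", "D"),
        ("ACGTACGT", "ACGTACGA", "TGCATGCA", "TGCATGCC"),
        Alphabet.DNA,
    )


@pytest.fixture
def primate_like():
    """Synthetic stand-in for a 12-taxon, 896-base mtDNA alignment."""
    tree, aln = simulate_alignment(12, 896, Alphabet.DNA, seed=11)
    return tree, aln


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree_distance(n, rng):
    """An additive distance matrix from a random tree with positive lengths.

    Returns (true split set over leaf indices, distance matrix).
    """
    from oracles import topology_splits

    from wboot import Phylogeny

    # random topology by sequential edge attachment
    edges = [(n, 0), (n, 1), (n, 2)]
    nxt = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges)))
        a, b = edges.pop(k)
        edges.extend([(a, nxt), (nxt, b), (nxt, leaf)])
        nxt += 1
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    taxa = tuple(f"x{i}" for i in range(n))
    tree = Phylogeny(taxa, tuple((a, b, float(w)) for (a, b), w in zip(edges, lengths)))
    return topology_splits(edges, n), tree.patristic()
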