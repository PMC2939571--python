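"""Noise injection, the ls_bd robustness statistic and the sweep driver.

Two ways of corrupting an alignment are implemented, mimicking sequencing
or alignment error (Strategy 1) and insertion/deletion events (Strategy 2):

* **substitution** noise changes each non-gap character independently with
  probability NR to a uniformly chosen *different* canonical symbol
  (1/3 per alternative nucleotide, 1/19 per alternative amino acid);
* **indel** noise eliminates or inserts contiguous blocks of characters,
  drawn with random sizes between n*l*NR/10 and n*l*NR/2, until about
  n*l*NR characters are affected.  Eliminations overwrite a run within one
  row with gaps; insertions add random characters to one row and pad every
  other row with gap columns so the alignment stays rectangular.  Sequences
  are never realigned afterwards.

The **combined** strategy applies one or the other with probability 1/2,
so repeated draws mix the two 50/50.

Robustness of a bootstrap strategy is measured by the least-squares
bootstrap deviation ``ls_bd = sum_k (bs_k - bsn_k)**2`` between the
noise-free scores bs and the scores bsn of the *same* branches of the
original tree recomputed from noisy data; the lower the deviation, the
less sensitive the strategy is to noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import _corrected_values, default_distance_kind
from .io_formats import Alignment, Alphabet, ConsistencyError, Phylogeny, WbootError, states
from .resampling import stream
from .support import (
    STRATEGIES,
    SupportTable,
    _split_labels,
    _sub_seed,
    sum_support,
    tables_for_reference,
)
from .tree_inference import nj_tree

__all__ = [
    "NoiseSpec",
    "RobustnessCurve",
    "add_substitution_noise",
    "add_indel_noise",
    "add_combined_noise",
    "add_noise",
    "ls_bootstrap_deviation",
    "noise_sweep",
    "simulate_alignment",
]

logger = logging.getLogger(__name__)

NOISE_STRATEGIES = ("substitution", "indel", "combined")

#: per-noise-level robustness results, one row per (level, strategy)
RobustnessCurve = pd.DataFrame


@dataclass(frozen=True)
class NoiseSpec:
    """A noise configuration: rate, strategy and seed."""

    rate: float
    strategy: str = "combined"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise WbootError(f"noise rate must be in [0, 1], got {self.rate}")
        if self.strategy not in NOISE_STRATEGIES:
            raise WbootError(f"unknown noise strategy {self.strategy!r}")


# --------------------------------------------------------------------------
# Strategy 1: substitutions
# --------------------------------------------------------------------------

def add_substitution_noise(
    aln: Alignment, NR: float, rng: np.random.Generator
) -> Alignment:
    """Flip each non-gap character to a different symbol with prob. NR."""
    if not 0.0 <= NR <= 1.0:
        raise WbootError(f"noise rate must be in [0, 1], got {NR}")
    if NR == 0.0:
        return aln
    symbols = states(aln.alphabet)
    k = len(symbols)
    rows = []
    for row in aln.rows:
        chars = list(row)
        hit = rng.random(len(chars)) < NR
        for pos in np.flatnonzero(hit):
            ch = chars[pos]
            if ch == "-":
                continue
            # uniform over the other canonical symbols; ambiguity codes are
            # replaced by a uniform canonical symbol
            choices = [s for s in symbols if s != ch] if ch in symbols else list(symbols)
            chars[pos] = choices[rng.integers(0, len(choices))]
        rows.append("".join(chars))
    return Alignment(aln.taxa, tuple(rows), aln.alphabet)


# --------------------------------------------------------------------------
# Strategy 2: indel blocks
# --------------------------------------------------------------------------

def _indel_noise_with_audit(
    aln: Alignment, NR: float, rng: np.random.Generator
) -> tuple[Alignment, int, list[tuple[str, int, int, int]]]:
    """Indel noise plus an audit trail of (kind, row, position, size)."""
    if not 0.0 <= NR <= 1.0:
        raise WbootError(f"noise rate must be in [0, 1], got {NR}")
    if NR == 0.0:
        return aln, 0, []
    n, l0 = aln.n, aln.l
    budget = math.ceil(n * l0 * NR)
    lo = max(1, math.ceil(n * l0 * NR / 10))
    hi = max(lo, math.ceil(n * l0 * NR / 2))
    symbols = states(aln.alphabet)
    rows = [list(r) for r in aln.rows]
    affected = 0
    events: list[tuple[str, int, int, int]] = []
    while affected < budget:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, budget - affected)
        row = int(rng.integers(0, n))
        if rng.random() < 0.5:
            # elimination: gap-mask a contiguous run within one row
            l = len(rows[0])
            start = int(rng.integers(0, l))
            actual = min(size, l - start)
            if actual < size:
                logger.debug(
                    "elimination block truncated from %d to %d at row %d",
                    size, actual, row,
                )
            rows[row][start:start + actual] = ["-"] * actual
            events.append(("elim", row, start, actual))
            affected += actual
        else:
            # insertion: random characters into one row, gap columns elsewhere
            l = len(rows[0])
            start = int(rng.integers(0, l + 1))
            block = [symbols[int(i)] for i in rng.integers(0, len(symbols), size)]
            for r in range(n):
                insert = block if r == row else ["-"] * size
                rows[r][start:start] = insert
            events.append(("ins", row, start, size))
            affected += size
    noisy = Alignment(aln.taxa, tuple("".join(r) for r in rows), aln.alphabet)
    return noisy, affected, events


def add_indel_noise(aln: Alignment, NR: float, rng: np.random.Generator) -> Alignment:
    """Apply block elimination/insertion noise totalling ~n*l*NR characters."""
    noisy, _, _ = _indel_noise_with_audit(aln, NR, rng)
    return noisy


def add_combined_noise(aln: Alignment, NR: float, rng: np.random.Generator) -> Alignment:
    """Apply Strategy 1 or Strategy 2, each with probability 1/2, at full NR."""
    if rng.random() < 0.5:
        return add_substitution_noise(aln, NR, rng)
    return add_indel_noise(aln, NR, rng)


_NOISE_FN = {
    "substitution": add_substitution_noise,
    "indel": add_indel_noise,
    "combined": add_combined_noise,
}


def add_noise(aln: Alignment, spec: NoiseSpec) -> Alignment:
    """Apply a :class:`NoiseSpec` (seeded from its own noise substream)."""
    rng = stream(spec.seed, "noise", 0)
    return _NOISE_FN[spec.strategy](aln, spec.rate, rng)


# --------------------------------------------------------------------------
# ls_bd
# --------------------------------------------------------------------------

def ls_bootstrap_deviation(bs: SupportTable, bsn: SupportTable) -> float:
    """Least-squares bootstrap deviation between noise-free and noisy scores.

    Both tables must be indexed by the same m splits of the original tree,
    in the same order.
    """
    if bs.splits != bsn.splits:
        raise ConsistencyError("tables are not over the same splits")
    return float(np.sum((bs.scores - bsn.scores) ** 2))


# --------------------------------------------------------------------------
# sweep driver
# --------------------------------------------------------------------------

def noise_sweep(
    aln: Alignment,
    levels: list[float],
    strategies: tuple[str, ...] = STRATEGIES,
    noise_strategy: str = "combined",
    N: int = 100,
    Ns: int = 100,
    repeats: int = 1,
    seed: int = 0,
    distance_kind: str = "auto",
) -> RobustnessCurve:
    """Robustness of each bootstrap strategy across noise levels.

    For every level the original alignment is corrupted, support for the
    *original* tree's branches is recomputed from replicates of the noisy
    data, and the sum of scores plus the ls_bd against the noise-free
    tables are recorded.  Tables at every level (including the noise-free
    baseline) are averages over ``repeats`` runs whose replicate streams
    are keyed by the repeat index only — so a level of 0 follows the exact
    seed path of the baseline and its ls_bd is identically zero.
    """
    if sorted(levels) != list(levels):
        raise WbootError("noise levels must be increasing")
    if distance_kind == "auto":
        distance_kind = default_distance_kind(aln.alphabet)
    enc = aln.encoded()
    njt = nj_tree(_corrected_values(enc, distance_kind))
    ref_idx = njt.split_indices()
    keys = _split_labels(ref_idx, aln.taxa)

    def averaged_tables(level: float) -> dict[str, SupportTable]:
        acc = {s: np.zeros(len(keys)) for s in strategies}
        for r in range(repeats):
            noise_rng = stream(seed, "noise", r)
            noisy = _NOISE_FN[noise_strategy](aln, level, noise_rng)
            tables, _, _ = tables_for_reference(
                noisy, ref_idx, keys, strategies, N, Ns,
                distance_kind, _sub_seed(seed, r), repeats=1,
            )
            for s in strategies:
                acc[s] += tables[s].scores
        return {
            s: SupportTable(keys, acc[s] / repeats, s) for s in strategies
        }

    baseline = averaged_tables(0.0)
    records = []
    for level in levels:
        noisy_tables = baseline if level == 0.0 else averaged_tables(level)
        for s in strategies:
            records.append(
                {
                    "noise": level,
                    "strategy": s,
                    "sum_support": sum_support(noisy_tables[s]),
                    "ls_bd": ls_bootstrap_deviation(baseline[s], noisy_tables[s]),
                }
            )
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# synthetic data generator
# --------------------------------------------------------------------------

def _random_topology(
    n: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Uniform random unrooted binary topology by sequential edge attachment."""
    # start from the 3-leaf star; node n is its center
    edges = [(n, 0), (n, 1), (n, 2)]
    next_internal = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges)))
        a, b = edges.pop(k)
        mid = next_internal
        next_internal += 1
        edges.extend([(a, mid), (mid, b), (mid, leaf)])
    return edges


def simulate_alignment(
    taxa: int,
    length: int,
    alphabet: Alphabet | str = Alphabet.DNA,
    tree: Phylogeny | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[Phylogeny, Alignment]:
    """Evolve a tree-shaped alignment under a symmetric substitution model.

    If no tree is given, a uniform random resolved topology over ``taxa``
    leaves is drawn with branch lengths uniform in [0.02, 0.3]
    substitutions/site.  Sites evolve i.i.d. from a uniform root state
    under the k-state symmetric (Jukes–Cantor-type) process matching the
    alphabet, so the package's distance corrections are consistent
    estimators of the branch lengths.  Returns the true tree and the
    alignment (taxon labels ``t1 .. tn``).
    """
    alphabet = Alphabet(alphabet) if not isinstance(alphabet, Alphabet) else alphabet
    if rng is None:
        rng = stream(0 if seed is None else seed, "simulate")
    if tree is None:
        if taxa < 4:
            raise WbootError("simulation needs at least 4 taxa")
        if length < 1:
            raise WbootError("simulation needs a positive length")
        topo = _random_topology(taxa, rng)
        lengths = rng.uniform(0.02, 0.3, size=len(topo))
        labels = tuple(f"t{i + 1}" for i in range(taxa))
        tree = Phylogeny(
            labels,
            tuple((a, b, float(w)) for (a, b), w in zip(topo, lengths)),
        )
    else:
        taxa = tree.n
        if length < 1:
            raise WbootError("simulation needs a positive length")

    k = len(states(alphabet))
    symbols = states(alphabet)
    adj = tree.adjacency()
    n = tree.n
    root = n  # first internal node; present for any tree built here
    if root not in adj:
        root = next(node for node in adj if node >= n)

    seq: dict[int, np.ndarray] = {
        root: rng.integers(0, k, size=length)
    }
    stack = [(root, nb, w) for nb, w in adj[root]]
    while stack:
        parent, node, b = stack.pop()
        # k-state symmetric process: P(change) = (k-1)/k * (1 - exp(-k/(k-1) b))
        p_change = (k - 1) / k * (1.0 - math.exp(-k / (k - 1) * b))
        parent_seq = seq[parent]
        child = parent_seq.copy()
        hit = np.flatnonzero(rng.random(length) < p_change)
        if hit.size:
            # uniform over the k-1 other states
            shift = rng.integers(1, k, size=hit.size)
            child[hit] = (parent_seq[hit] + shift) % k
        seq[node] = child
        for nb, w in adj[node]:
            if nb != parent:
                stack.append((node, nb, w))
    rows = tuple(
        "".join(symbols[s] for s in seq[leaf]) for leaf in range(n)
    )
    return tree, Alignment(tree.taxa, rows, alphabet)
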