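"""Weighted and unweighted branch-support computation, end to end.

Five strategies score each internal branch of a reference tree T against N
pseudo-replicated NJ trees:

===========  =============================================================
``std``      traditional bootstrap: every replicate weighs 1/N
``ls``       weights inversely proportional to the replicate LS coefficient
``norm_ls``  weights proportional to 1 - min-max-normalized LS
``sbs``      weights proportional to the average secondary bootstrap score
``norm_sbs`` weights proportional to the min-max-normalized SBS
===========  =============================================================

The score of branch k is ``100 * sum_t w_t * [k in B_t]`` where B_t is the
split set of replicate tree t; with uniform weights this is exactly the
classical percentage-of-replicates support.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import _corrected_values, default_distance_kind
from .io_formats import (
    Alignment,
    ConsistencyError,
    Phylogeny,
    Split,
    WbootError,
)
from .resampling import sample_column_indices, stream
from .tree_inference import NJTree, nj_tree
from .weighting import (
    QualityVector,
    WeightVector,
    ls_values,
    minmax_normalize,
    weights_from_quality,
)

__all__ = [
    "STRATEGIES",
    "SupportTable",
    "RunResult",
    "weighted_support",
    "run_strategy",
    "run_all_strategies",
    "compare_strategy_tables",
    "sum_support",
    "load_reference_score_table",
    "table_from_scores",
]

STRATEGIES = ("std", "ls", "norm_ls", "sbs", "norm_sbs")

#: strategies that need the secondary (two-level) bootstrap
_NEEDS_SECONDARY = {"sbs", "norm_sbs"}
_NEEDS_LS = {"ls", "norm_ls"}


@dataclass(frozen=True)
class SupportTable:
    """Per-branch support scores of one strategy for a reference tree.

    ``splits`` are ordered hashable keys (canonical label splits for trees
    built here; plain branch ids for externally published tables) and
    ``scores`` the matching values in [0, 100].
    """

    splits: tuple[Hashable, ...]
    scores: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.splits),):
            raise WbootError("one score per split required")
        if s.size and (s.min() < -1e-9 or s.max() > 100 + 1e-9):
            raise WbootError("support scores must lie in [0, 100]")
        object.__setattr__(self, "scores", np.clip(s, 0.0, 100.0))

    @property
    def m(self) -> int:
        return len(self.splits)

    def as_dict(self) -> dict[Hashable, float]:
        return dict(zip(self.splits, self.scores))

    def rounded(self, decimals: int = 1) -> np.ndarray:
        """Scores at reporting precision (1 decimal by default)."""
        return np.round(self.scores, decimals)


@dataclass(frozen=True)
class RunResult:
    """Everything one bootstrap run produced, for audit and output."""

    tree: Phylogeny
    tables: Mapping[str, SupportTable]
    quality: Mapping[str, QualityVector]
    weights: Mapping[str, WeightVector]
    seed: int
    N: int
    Ns: int
    repeats: int = 1


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def weighted_support(
    ref_splits: Sequence[Split],
    rep_splits: Sequence[Iterable[Split]],
    w: WeightVector | np.ndarray,
    strategy: str = "std",
) -> SupportTable:
    """Score each reference split as 100 x the total weight of the
    replicates whose tree contains it."""
    weights = w.w if isinstance(w, WeightVector) else np.asarray(w, float)
    if len(rep_splits) != weights.size:
        raise ConsistencyError(
            f"{len(rep_splits)} replicate split sets but {weights.size} weights"
        )
    rep_sets = [frozenset(s) for s in rep_splits]
    counts = np.array(
        [sum(1 for s in rep_sets if split in s) for split in ref_splits],
        dtype=float,
    )
    if weights.size and np.all(weights == weights[0]):
        # uniform weights reduce exactly to the classical count/N percentage
        scores = 100.0 * counts / weights.size
    else:
        scores = np.array(
            [
                100.0 * sum(wt for wt, s in zip(weights, rep_sets) if split in s)
                for split in ref_splits
            ]
        )
    return SupportTable(tuple(ref_splits), scores, strategy)


def sum_support(table: SupportTable) -> float:
    """Sum of the branch scores of a table (0 for an empty table)."""
    return float(table.scores.sum())


def compare_strategy_tables(a: SupportTable, b: SupportTable) -> dict[str, int]:
    """Count branches where a's score is lower than / equal to / higher
    than b's, judged at one-decimal reporting precision."""
    if a.splits != b.splits:
        raise ConsistencyError("tables are not over the same splits")
    ra, rb = a.rounded(), b.rounded()
    return {
        "lower": int(np.sum(ra < rb)),
        "equal": int(np.sum(ra == rb)),
        "higher": int(np.sum(ra > rb)),
    }


# --------------------------------------------------------------------------
# the bootstrap engine
# --------------------------------------------------------------------------

def _analyze_replicates(
    enc: np.ndarray,
    N: int,
    Ns: int,
    kind: str,
    seed: int,
    need_ls: bool,
    need_ss: bool,
) -> tuple[list[set[frozenset[int]]], np.ndarray | None, np.ndarray | None]:
    """Split sets (and quality values) of the N primary replicate trees.

    Works on the encoded alignment and index splits throughout; replicate t
    draws from stream (primary, t), secondary replicate (t, s) from
    (secondary, t, s).
    """
    l = enc.shape[1]
    splits_list: list[set[frozenset[int]]] = []
    ls_vals: list[float] = []
    ss_vals: list[float] = []
    for t in range(N):
        idx = sample_column_indices(l, stream(seed, "primary", t))
        enc_t = enc[:, idx]
        d_t = _corrected_values(enc_t, kind)
        njt = nj_tree(d_t)
        ordered = njt.split_indices()
        splits_list.append(set(ordered))
        if need_ls:
            ls_vals.append(ls_values(d_t, njt.patristic()))
        if need_ss:
            counts = np.zeros(len(ordered))
            lt = enc_t.shape[1]
            for s in range(Ns):
                idx2 = sample_column_indices(lt, stream(seed, "secondary", t, s))
                sec = set(nj_tree(_corrected_values(enc_t[:, idx2], kind)).split_indices())
                for k, spl in enumerate(ordered):
                    if spl in sec:
                        counts[k] += 1
            ss_vals.append(float(100.0 * counts.mean() / Ns))
    return (
        splits_list,
        np.array(ls_vals) if need_ls else None,
        np.array(ss_vals) if need_ss else None,
    )


def _strategy_weights(
    strategies: Sequence[str],
    N: int,
    ls: np.ndarray | None,
    ss: np.ndarray | None,
) -> tuple[dict[str, WeightVector], dict[str, QualityVector]]:
    weights: dict[str, WeightVector] = {}
    quality: dict[str, QualityVector] = {}
    for strat in strategies:
        if strat == "std":
            weights[strat] = WeightVector(np.full(N, 1.0 / N))
            continue
        if strat in _NEEDS_LS:
            q = QualityVector(ls, "ls")
        else:
            q = QualityVector(ss, "sbs")
        if strat.startswith("norm_"):
            q = minmax_normalize(q)
        quality[strat] = q
        weights[strat] = weights_from_quality(q)
    return weights, quality


def _score_tables(
    ref_idx_splits: Sequence[frozenset[int]],
    split_keys: tuple[Hashable, ...],
    splits_list: Sequence[set[frozenset[int]]],
    weights: Mapping[str, WeightVector],
) -> dict[str, SupportTable]:
    presence = np.array(
        [[1.0 if rs in sp else 0.0 for sp in splits_list] for rs in ref_idx_splits]
    )
    tables = {}
    for strat, wv in weights.items():
        if not len(split_keys):
            scores = np.zeros(0)
        elif np.all(wv.w == wv.w[0]):
            # exact classical reduction (std, or degenerate-uniform weights)
            scores = 100.0 * presence.sum(axis=1) / wv.N
        else:
            scores = 100.0 * presence @ wv.w
        tables[strat] = SupportTable(split_keys, scores, strat)
    return tables


def _sub_seed(seed: int, r: int) -> int:
    """Root seed of repeat r (repeat 0 keeps the user's seed verbatim)."""
    if r == 0:
        return int(seed)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(4, r))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def tables_for_reference(
    aln: Alignment,
    ref_idx_splits: Sequence[frozenset[int]],
    split_keys: tuple[Hashable, ...],
    strategies: Sequence[str],
    N: int,
    Ns: int,
    distance_kind: str,
    seed: int,
    repeats: int = 1,
) -> tuple[dict[str, SupportTable], dict[str, QualityVector], dict[str, WeightVector]]:
    """Strategy tables for a fixed set of reference splits, averaged over
    ``repeats`` independently seeded runs.

    Used both for ordinary support (reference = tree of ``aln``) and for
    the noise protocol (reference = tree of the clean alignment, replicates
    drawn from the noisy one).
    """
    need_ls = any(s in _NEEDS_LS for s in strategies)
    need_ss = any(s in _NEEDS_SECONDARY for s in strategies)
    if need_ss and Ns < 1:
        raise WbootError("secondary strategies need Ns >= 1")
    enc = aln.encoded()
    acc: dict[str, np.ndarray] = {s: np.zeros(len(split_keys)) for s in strategies}
    first_quality: dict[str, QualityVector] = {}
    first_weights: dict[str, WeightVector] = {}
    for r in range(repeats):
        seed_r = _sub_seed(seed, r)
        splits_list, ls, ss = _analyze_replicates(
            enc, N, Ns, distance_kind, seed_r, need_ls, need_ss
        )
        weights, quality = _strategy_weights(strategies, N, ls, ss)
        tables = _score_tables(ref_idx_splits, split_keys, splits_list, weights)
        for s in strategies:
            acc[s] += tables[s].scores
        if r == 0:
            first_quality, first_weights = quality, weights
    tables = {
        s: SupportTable(split_keys, acc[s] / repeats, s) for s in strategies
    }
    return tables, first_quality, first_weights


def _reference_tree(aln: Alignment, distance_kind: str) -> tuple[Phylogeny, NJTree]:
    enc = aln.encoded()
    njt = nj_tree(_corrected_values(enc, distance_kind))
    return njt.to_phylogeny(aln.taxa), njt


def _split_labels(
    ref_idx_splits: Sequence[frozenset[int]], taxa: Sequence[str]
) -> tuple[Split, ...]:
    return tuple(frozenset(taxa[i] for i in s) for s in ref_idx_splits)


def run_all_strategies(
    aln: Alignment,
    strategies: Sequence[str] = STRATEGIES,
    N: int = 100,
    Ns: int = 100,
    distance_kind: str = "auto",
    seed: int = 0,
    repeats: int = 1,
) -> RunResult:
    """Full weighted-bootstrap analysis of an alignment.

    Builds the reference NJ tree, draws N primary (and, for SBS kinds,
    N x Ns secondary) pseudo-replicates, and returns one
    :class:`SupportTable` per requested strategy, all sharing the reference
    tree's split ordering.  With ``repeats > 1`` the tables are averages of
    that many independently seeded runs.
    """
    if aln.n < 4:
        raise WbootError("support analysis needs at least 4 taxa")
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise WbootError(f"unknown strategies: {sorted(unknown)}")
    if N < 1 or repeats < 1:
        raise WbootError("N and repeats must be positive")
    if distance_kind == "auto":
        distance_kind = default_distance_kind(aln.alphabet)
    tree, njt = _reference_tree(aln, distance_kind)
    ref_idx = njt.split_indices()
    keys = _split_labels(ref_idx, aln.taxa)
    tables, quality, weights = tables_for_reference(
        aln, ref_idx, keys, strategies, N, Ns, distance_kind, seed, repeats
    )
    return RunResult(tree, tables, quality, weights, seed, N, Ns, repeats)


def run_strategy(
    aln: Alignment,
    strategy: str = "std",
    N: int = 100,
    Ns: int = 100,
    distance_kind: str = "auto",
    seed: int = 0,
    repeats: int = 1,
) -> RunResult:
    """Single-strategy convenience wrapper around :func:`run_all_strategies`."""
    if strategy == "all":
        return run_all_strategies(aln, STRATEGIES, N, Ns, distance_kind, seed, repeats)
    return run_all_strategies(aln, (strategy,), N, Ns, distance_kind, seed, repeats)


# --------------------------------------------------------------------------
# published reference scores (PheRS dataset)
# --------------------------------------------------------------------------

def load_reference_score_table() -> pd.DataFrame:
    """Published five-strategy branch scores for the 32-taxon PheRS data.

    One row per internal branch (29), with columns ``<strategy>`` for the
    noise-free scores and ``<strategy>_noisy`` for the scores after 10%
    noise.  Strategy columns: std, sb, ls, nsb, nls.
    """
    ref = resources.files("wboot.data") / "phers_reference_scores.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="branch")


def table_from_scores(
    scores: Sequence[float],
    strategy: str,
    splits: Sequence[Hashable] | None = None,
) -> SupportTable:
    """Wrap a plain score column (e.g. a published table) as a SupportTable."""
    if splits is None:
        splits = tuple(range(1, len(scores) + 1))
    return SupportTable(tuple(splits), np.asarray(scores, float), strategy)
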