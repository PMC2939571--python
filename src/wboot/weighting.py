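"""Per-replicate tree quality measures and bootstrap weights.

Each pseudo-replicated tree gets a quality score:

* the least-squares (LS) coefficient — the sum over unordered taxon pairs
  of squared differences between the replicate's distance matrix and the
  patristic distances of the tree inferred from it (smaller = better fit);
* or the average secondary bootstrap score (SBS) — the mean standard
  bootstrap support of the tree's internal branches, estimated from a
  second level of resampling (larger = more robust).

Either measure, raw or min–max normalized, is turned into a weight vector
w with w_t in [0, 1] and sum(w) = 1.  Weights are proportional to the
quality for higher-is-better kinds (sbs, norm_sbs), inversely proportional
for raw LS, and proportional to the complement 1 - norm_ls for normalized
LS.  A constant quality vector degenerates to uniform weights, which makes
every weighted strategy reduce exactly to traditional bootstrapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix, distance_matrix
from .io_formats import Alignment, ConsistencyError, Phylogeny, WbootError
from .resampling import ReplicateSet, resample_columns, stream
from .tree_inference import neighbor_joining, nontrivial_splits

__all__ = [
    "QualityVector",
    "WeightVector",
    "ls_coefficient",
    "replicate_ls_vector",
    "average_secondary_support",
    "minmax_normalize",
    "weights_from_quality",
]

logger = logging.getLogger(__name__)

#: floor applied to a zero LS coefficient before inversion, so a perfectly
#: additive replicate gets the maximal finite weight instead of dividing
#: by zero
LS_EPSILON = 1e-12

_HIGHER_BETTER = {"sbs", "norm_sbs"}
_KINDS = {"ls", "sbs", "norm_ls", "norm_sbs"}


@dataclass(frozen=True)
class QualityVector:
    """Per-replicate quality values of one kind.

    ``orientation`` is derived from ``kind``: LS kinds are lower-is-better,
    SBS kinds higher-is-better.  ``degenerate`` marks a constant input
    vector (e.g. after a failed min–max normalization); downstream weights
    then fall back to uniform.
    """

    values: np.ndarray
    kind: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise WbootError(f"unknown quality kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise WbootError("quality vector must be a non-empty 1-d array")
        if self.kind == "ls" and np.any(v < 0):
            raise WbootError("LS coefficients cannot be negative")
        if self.kind == "sbs" and (np.any(v < 0) or np.any(v > 100)):
            raise WbootError("secondary bootstrap scores must lie in [0, 100]")
        if self.kind.startswith("norm_") and (np.any(v < 0) or np.any(v > 1)):
            raise WbootError("normalized quality values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def orientation(self) -> str:
        return "higher_better" if self.kind in _HIGHER_BETTER else "lower_better"

    @property
    def N(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class WeightVector:
    """Replicate weights: each in [0, 1], summing to one."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0) or np.any(w > 1):
            raise WbootError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise WbootError(f"weights sum to {w.sum()}, expected 1")
        object.__setattr__(self, "w", w)

    @property
    def N(self) -> int:
        return self.w.size


# --------------------------------------------------------------------------
# LS quality
# --------------------------------------------------------------------------

def ls_coefficient(D: DistanceMatrix, tree: Phylogeny) -> float:
    """Least-squares fit of a tree to a distance matrix.

    ``sum_{i<j} (d(i,j) - delta(i,j))**2`` over unordered pairs, where
    delta is the patristic distance in ``tree``.
    """
    if D.taxa != tree.taxa:
        raise ConsistencyError(
            "distance matrix and tree are over different taxa"
        )
    resid = D.values - tree.patristic()
    iu = np.triu_indices(D.n, k=1)
    return float(np.sum(resid[iu] ** 2))


def ls_values(d: np.ndarray, delta: np.ndarray) -> float:
    """Raw-array form of :func:`ls_coefficient` for the fast pipeline."""
    iu = np.triu_indices(d.shape[0], k=1)
    return float(np.sum((d[iu] - delta[iu]) ** 2))


def replicate_ls_vector(replicates: ReplicateSet, distance_kind: str = "auto") -> QualityVector:
    """LS coefficient of each pseudo-replicate's own NJ tree.

    For each PRA_t: distance matrix -> NJ tree -> LS between the two.
    """
    values = []
    for rep in replicates.replicates:
        dm = distance_matrix(rep, distance_kind)
        tree = neighbor_joining(dm)
        values.append(ls_coefficient(dm, tree))
    return QualityVector(np.array(values), "ls")


# --------------------------------------------------------------------------
# SBS quality
# --------------------------------------------------------------------------

def average_secondary_support(
    tree_t: Phylogeny,
    pra_t: Alignment,
    Ns: int,
    distance_kind: str = "auto",
    rng: np.random.Generator | None = None,
) -> float:
    """Average secondary bootstrap score ss_t of a pseudo-replicated tree.

    Draws ``Ns`` secondary pseudo-replicates of ``pra_t``, infers an NJ
    tree from each, scores every internal branch of ``tree_t`` by the
    percentage of secondary trees containing it, and returns the mean over
    the internal branches (in [0, 100]).
    """
    if Ns < 1:
        raise WbootError(f"need at least one secondary replicate, got Ns={Ns}")
    ref_splits = nontrivial_splits(tree_t)
    if not ref_splits:
        raise WbootError(
            "tree has no internal branches; secondary support is undefined"
        )
    if rng is None:
        rng = stream(0, "secondary", 0)
    counts = {s: 0 for s in ref_splits}
    for _ in range(Ns):
        spra = resample_columns(pra_t, rng)
        sec_tree = neighbor_joining(distance_matrix(spra, distance_kind))
        sec_splits = nontrivial_splits(sec_tree)
        for s in ref_splits:
            if s in sec_splits:
                counts[s] += 1
    per_branch = np.array([100.0 * c / Ns for c in counts.values()])
    return float(per_branch.mean())


# --------------------------------------------------------------------------
# normalization and weights
# --------------------------------------------------------------------------

def minmax_normalize(q: QualityVector) -> QualityVector:
    """Min–max normalize a quality vector onto [0, 1].

    A constant vector cannot be normalized; the result is flagged
    ``degenerate`` and downstream weights become uniform.
    """
    if q.kind.startswith("norm_"):
        raise WbootError("quality vector is already normalized")
    if q.N < 2:
        raise WbootError("min-max normalization needs at least two values")
    lo, hi = q.values.min(), q.values.max()
    kind = f"norm_{q.kind}"
    if hi == lo:
        logger.warning("constant %s vector: normalization degenerate", q.kind)
        return QualityVector(np.zeros_like(q.values), kind, degenerate=True)
    return QualityVector((q.values - lo) / (hi - lo), kind)


def weights_from_quality(q: QualityVector) -> WeightVector:
    """Turn a quality vector into replicate weights (sum = 1).

    sbs / norm_sbs: w_t ∝ value; ls: w_t ∝ 1/value (zero values floored at
    ``LS_EPSILON`` so an exactly tree-like replicate gets the maximal
    finite weight); norm_ls: w_t ∝ 1 - value.  Degenerate inputs (constant
    vector, all-zero denominator) give uniform weights, reproducing
    traditional bootstrapping.
    """
    v = q.values
    N = q.N
    uniform = np.full(N, 1.0 / N)
    if q.degenerate or np.all(v == v[0]):
        return WeightVector(uniform)
    if q.kind in _HIGHER_BETTER:
        raw = v.copy()
    elif q.kind == "ls":
        floored = np.maximum(v, LS_EPSILON)
        if np.any(v < LS_EPSILON):
            logger.info(
                "%d replicate(s) with LS=0 floored at %.0e before inversion",
                int(np.sum(v < LS_EPSILON)), LS_EPSILON,
            )
        raw = 1.0 / floored
    else:  # norm_ls
        raw = 1.0 - v
    total = raw.sum()
    if total <= 0:
        return WeightVector(uniform)
    return WeightVector(raw / total)
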