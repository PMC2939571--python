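"""Column bootstrap resampling of alignments.

A pseudo-replicated alignment (PRA) is built by drawing l columns of the
parent alignment uniformly with replacement; secondary pseudo-replicates
(SPRA) resample a PRA the same way.  All randomness derives from one root
seed through named substreams, so the full nested design is reproducible:
primary replicate t uses the stream keyed (primary, t), secondary replicate
(t, s) uses (secondary, t, s), and streams for noise injection and
simulation get their own namespaces.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io_formats import Alignment, WbootError

__all__ = [
    "ReplicateSet",
    "ReplicateLevel",
    "stream",
    "resample_columns",
    "generate_replicates",
]

# substream namespaces under the root seed
_NS = {"primary": 0, "secondary": 1, "noise": 2, "simulate": 3, "repeat": 4}


def stream(seed: int, *key) -> np.random.Generator:
    """Independent generator for a named substream of a root seed.

    ``key`` mixes namespace strings (see module docstring) and integers,
    e.g. ``stream(42, "secondary", t, s)``.
    """
    spawn_key = tuple(_NS[k] if isinstance(k, str) else int(k) for k in key)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key)
    )


class ReplicateLevel(enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


@dataclass(frozen=True)
class ReplicateSet:
    """N pseudo-replicated alignments drawn from one parent."""

    parent: Alignment
    replicates: tuple[Alignment, ...]
    seed: int
    level: ReplicateLevel = ReplicateLevel.PRIMARY

    @property
    def N(self) -> int:
        return len(self.replicates)


def sample_column_indices(l: int, rng: np.random.Generator) -> np.ndarray:
    """The i.i.d.-with-replacement column draw shared by all resampling."""
    return rng.integers(0, l, size=l)


def resample_columns(aln: Alignment, rng: np.random.Generator) -> Alignment:
    """One bootstrap pseudo-replicate: l columns drawn with replacement."""
    idx = sample_column_indices(aln.l, rng)
    return aln.take_columns(idx)


def generate_replicates(aln: Alignment, N: int, seed: int) -> ReplicateSet:
    """Generate the N primary pseudo-replicates PRA_1 .. PRA_N.

    Replicate t is drawn from the substream ``(primary, t)`` of ``seed``,
    so any single replicate can be regenerated independently.
    """
    if N < 1:
        raise WbootError(f"need at least one replicate, got N={N}")
    reps = tuple(
        resample_columns(aln, stream(seed, "primary", t)) for t in range(N)
    )
    return ReplicateSet(aln, reps, seed, ReplicateLevel.PRIMARY)
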