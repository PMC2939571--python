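"""Evolutionary distance estimation from alignments.

Two distance corrections are provided: Jukes–Cantor for DNA and the Kimura
approximation for proteins.  Both start from the observed proportion of
differing sites (p-distance) under pairwise deletion: positions with a gap
or ambiguity code in either sequence of a pair are excluded for that pair
only.  Saturated pairs (where the correction's logarithm argument is
non-positive) are capped at a large finite distance so downstream
least-squares fits and Neighbor-Joining stay well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Alignment, Alphabet, WbootError

__all__ = [
    "DistanceMatrix",
    "DegeneratePairError",
    "SATURATION_CAP",
    "p_distance",
    "jc69_distance",
    "kimura_protein_distance",
    "distance_matrix",
    "write_distance_matrix",
]

#: finite distance assigned to saturated pairs (substitutions per site)
SATURATION_CAP = 5.0


class DegeneratePairError(WbootError):
    """A sequence pair shares no comparable (ungapped, unambiguous) sites."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances, zero on the diagonal.

    ``values`` is an ``(n, n)`` float array in expected substitutions per
    site, indexed by ``taxa`` order.
    """

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise WbootError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise WbootError("non-finite distances")
        if not np.allclose(v, v.T):
            raise WbootError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise WbootError("distance matrix diagonal is not zero")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


# --------------------------------------------------------------------------
# p-distance
# --------------------------------------------------------------------------

def _p_matrix(enc: np.ndarray) -> np.ndarray:
    """Pairwise p-distance from an encoded alignment (missing = -1)."""
    valid = enc >= 0
    # pairwise comparable-site and mismatch counts, vectorized over pairs
    comp = (valid[:, None, :] & valid[None, :, :])
    diff = comp & (enc[:, None, :] != enc[None, :, :])
    ncomp = comp.sum(axis=2)
    off_diagonal = ~np.eye(len(enc), dtype=bool)
    if np.any((ncomp == 0) & off_diagonal):
        i, j = np.argwhere((ncomp == 0) & off_diagonal)[0]
        raise DegeneratePairError(
            f"sequences {i} and {j} share no comparable sites"
        )
    with np.errstate(invalid="ignore"):
        p = np.where(ncomp > 0, diff.sum(axis=2) / np.maximum(ncomp, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    return p


def p_distance(aln: Alignment, i: str, j: str) -> float:
    """Proportion of differing sites between taxa *i* and *j*.

    Sites with a gap or ambiguity code in either sequence are excluded
    (pairwise deletion).  Raises :class:`DegeneratePairError` when no site
    is comparable.
    """
    if i == j:
        raise WbootError("p_distance requires two distinct taxa")
    enc = aln.encoded()
    a = enc[aln.taxa.index(i)]
    b = enc[aln.taxa.index(j)]
    comp = (a >= 0) & (b >= 0)
    if not comp.any():
        raise DegeneratePairError(f"taxa {i!r} and {j!r} share no comparable sites")
    return float((a[comp] != b[comp]).mean())


# --------------------------------------------------------------------------
# corrections
# --------------------------------------------------------------------------

def jc69_correct(p: np.ndarray) -> np.ndarray:
    """Jukes–Cantor correction d = -(3/4) ln(1 - (4/3) p), capped."""
    p = np.asarray(p, dtype=float)
    arg = 1.0 - (4.0 / 3.0) * p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), SATURATION_CAP)
    return np.minimum(d, SATURATION_CAP)


def kimura_protein_correct(p: np.ndarray) -> np.ndarray:
    """Kimura protein correction d = -ln(1 - p - 0.2 p^2), capped."""
    p = np.asarray(p, dtype=float)
    arg = 1.0 - p - 0.2 * p * p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(arg > 0, -np.log(np.where(arg > 0, arg, 1.0)), SATURATION_CAP)
    return np.minimum(d, SATURATION_CAP)


def _corrected_values(enc: np.ndarray, kind: str) -> np.ndarray:
    p = _p_matrix(enc)
    if kind == "jc69":
        return jc69_correct(p)
    if kind == "kimura":
        return kimura_protein_correct(p)
    raise WbootError(f"unknown distance kind {kind!r}")


def jc69_distance(aln: Alignment) -> DistanceMatrix:
    """Jukes–Cantor distance matrix for a DNA alignment."""
    if aln.alphabet is not Alphabet.DNA:
        raise WbootError("Jukes-Cantor correction applies to DNA alignments")
    return DistanceMatrix(aln.taxa, _corrected_values(aln.encoded(), "jc69"))


def kimura_protein_distance(aln: Alignment) -> DistanceMatrix:
    """Kimura distance matrix for a protein alignment."""
    if aln.alphabet is not Alphabet.PROTEIN:
        raise WbootError("Kimura protein correction applies to protein alignments")
    return DistanceMatrix(aln.taxa, _corrected_values(aln.encoded(), "kimura"))


def default_distance_kind(alphabet: Alphabet) -> str:
    return "jc69" if alphabet is Alphabet.DNA else "kimura"


def distance_matrix(aln: Alignment, kind: str = "auto") -> DistanceMatrix:
    """Distance matrix under the named correction (``auto`` picks by alphabet)."""
    if kind == "auto":
        kind = default_distance_kind(aln.alphabet)
    if kind == "jc69":
        return jc69_distance(aln)
    if kind == "kimura":
        return kimura_protein_distance(aln)
    raise WbootError(f"unknown distance kind {kind!r}")


def write_distance_matrix(dm: DistanceMatrix, path, decimals: int = 6) -> None:
    """Write a PHYLIP-square style distance matrix (TSV body)."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for taxon, row in zip(dm.taxa, dm.values):
            cells = "\t".join(f"{x:.{decimals}f}" for x in row)
            fh.write(f"{taxon}\t{cells}\n")
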