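"""Core data containers and standard-format IO.

Defines the immutable :class:`Alignment` and :class:`Phylogeny` containers
used throughout the package, reads/writes alignments in FASTA and relaxed
sequential PHYLIP, and parses/serializes trees in newick.

Splits (bipartitions of the taxon set induced by internal branches) are
stored canonically as the side of the partition *not* containing the first
taxon of a fixed taxon ordering, so split sets from different trees over the
same taxa compare by plain set operations.
"""

from __future__ import annotations

import enum
import io
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "Alignment",
    "Phylogeny",
    "Split",
    "SplitSet",
    "WbootError",
    "AlignmentError",
    "FormatError",
    "AlphabetError",
    "ParseError",
    "ConsistencyError",
    "read_alignment",
    "write_alignment",
    "parse_newick",
    "write_newick",
    "canonical_split",
]


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class WbootError(Exception):
    """Base class for all package errors."""


class AlignmentError(WbootError):
    """Ragged or otherwise structurally invalid alignment."""


class FormatError(WbootError):
    """File does not parse under the named dialect."""


class AlphabetError(WbootError):
    """Sequence contains characters outside the declared alphabet."""


class ParseError(WbootError):
    """Malformed newick string."""


class ConsistencyError(WbootError):
    """Objects that must agree (taxa, splits, lengths) do not."""


# --------------------------------------------------------------------------
# alphabets
# --------------------------------------------------------------------------

class Alphabet(enum.Enum):
    DNA = "dna"
    PROTEIN = "protein"


GAP = "-"

# canonical state symbols, in the order used by the integer encoding
DNA_STATES = "ACGT"
PROTEIN_STATES = "ACDEFGHIKLMNPQRSTVWY"

# IUPAC ambiguity codes, accepted on input and treated as missing in
# distance computation (pairwise deletion)
DNA_AMBIGUOUS = set("RYSWKMBDHVNU")  # U is RNA uracil, mapped to T
PROTEIN_AMBIGUOUS = set("XBZJUO*")

_DNA_ALLOWED = set(DNA_STATES) | DNA_AMBIGUOUS | {GAP}
_PROTEIN_ALLOWED = set(PROTEIN_STATES) | PROTEIN_AMBIGUOUS | {GAP}


def _allowed(alphabet: Alphabet) -> set[str]:
    return _DNA_ALLOWED if alphabet is Alphabet.DNA else _PROTEIN_ALLOWED


def states(alphabet: Alphabet) -> str:
    """Canonical (unambiguous) state symbols of an alphabet."""
    return DNA_STATES if alphabet is Alphabet.DNA else PROTEIN_STATES


def _encoding_table(alphabet: Alphabet) -> np.ndarray:
    """Map ASCII codes to state indices; -1 = gap/ambiguity (missing)."""
    table = np.full(128, -1, dtype=np.int8)
    for idx, ch in enumerate(states(alphabet)):
        table[ord(ch)] = idx
    if alphabet is Alphabet.DNA:
        table[ord("U")] = DNA_STATES.index("T")
    return table


_TABLES = {a: _encoding_table(a) for a in Alphabet}


# --------------------------------------------------------------------------
# Alignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple sequence alignment.

    Parameters
    ----------
    taxa
        Ordered, unique sequence labels (length ``n``).
    rows
        One uppercase sequence string per taxon, all of common length ``l``.
    alphabet
        :class:`Alphabet` the sequences are written in.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError(
                f"{len(self.taxa)} labels but {len(self.rows)} sequences"
            )
        if len(self.taxa) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged rows, lengths {sorted(lengths)}")
        if self.l < 1:
            raise AlignmentError("alignment has zero columns")
        allowed = _allowed(self.alphabet)
        for taxon, row in zip(self.taxa, self.rows):
            for pos, ch in enumerate(row):
                if ch not in allowed:
                    raise AlphabetError(
                        f"illegal character {ch!r} at position {pos + 1} "
                        f"of sequence {taxon!r} ({self.alphabet.value})"
                    )

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def l(self) -> int:  # noqa: E741 - field name follows MSA convention
        return len(self.rows[0])

    def encoded(self) -> np.ndarray:
        """``(n, l)`` int8 matrix; canonical states 0.., missing/gap = -1."""
        table = _TABLES[self.alphabet]
        data = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.l)
        return table[data]

    def take_columns(self, idx: Sequence[int]) -> "Alignment":
        """Alignment restricted to (possibly repeated) column indices."""
        cols = [[row[i] for row in self.rows] for i in idx]
        rows = tuple("".join(col[r] for col in cols) for r in range(self.n))
        return Alignment(self.taxa, rows, self.alphabet)

    @classmethod
    def from_sequences(
        cls,
        pairs: Iterable[tuple[str, str]],
        alphabet: Alphabet,
    ) -> "Alignment":
        taxa, rows = [], []
        for name, seq in pairs:
            taxa.append(name)
            rows.append(seq.upper())
        return cls(tuple(taxa), tuple(rows), alphabet)


# --------------------------------------------------------------------------
# alignment IO (FASTA / relaxed sequential PHYLIP via Biopython)
# --------------------------------------------------------------------------

_BIO_FORMAT = {"fasta": "fasta", "phylip": "phylip-relaxed"}


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    alphabet: Alphabet | str = Alphabet.DNA,
) -> Alignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    Taxon order is preserved from the file.  Raises
    :class:`AlignmentError` for ragged rows, :class:`FormatError` for
    duplicate labels or dialect problems, :class:`AlphabetError` for
    characters outside the declared alphabet.
    """
    alphabet = Alphabet(alphabet) if not isinstance(alphabet, Alphabet) else alphabet
    if format not in _BIO_FORMAT:
        raise FormatError(f"unknown alignment format {format!r}")
    path = Path(path)
    text = path.read_text()
    if format == "fasta":
        # Bio.AlignIO rejects ragged FASTA outright; parse records first so
        # raggedness is reported as an alignment error, not a format error.
        records = _parse_fasta_records(text)
        pairs = records
    else:
        try:
            msa = AlignIO.read(io.StringIO(text), _BIO_FORMAT[format])
        except Exception as exc:  # Biopython raises bare ValueError
            raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
        pairs = [(rec.id, str(rec.seq)) for rec in msa]
    if not pairs:
        raise FormatError(f"no sequences found in {path}")
    return Alignment.from_sequences(pairs, alphabet)


def _parse_fasta_records(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        elif name is None:
            raise FormatError("FASTA data before first header line")
        else:
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment; the file re-reads to an equal :class:`Alignment`."""
    if format not in _BIO_FORMAT:
        raise FormatError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    )
    with open(path, "w") as handle:
        AlignIO.write(msa, handle, _BIO_FORMAT[format])


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------

#: One bipartition, canonically the side not containing the first taxon.
Split = frozenset
#: The non-trivial bipartitions of a tree, one per internal branch.
SplitSet = frozenset


def canonical_split(side: Iterable[str], taxa: Sequence[str]) -> Split:
    """Canonicalize a bipartition side against a fixed taxon ordering."""
    side = frozenset(side)
    if taxa[0] in side:
        side = frozenset(taxa) - side
    return side


# --------------------------------------------------------------------------
# Phylogeny
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Phylogeny:
    """An unrooted phylogenetic tree with labelled leaves.

    Nodes are integers: ``0 .. n-1`` are the leaves in ``taxa`` order,
    larger ids are internal.  ``edges`` is an undirected edge list with
    real-valued lengths (``nan`` when the source had none).  NJ can produce
    negative branch lengths; they are kept as-is.
    """

    taxa: tuple[str, ...]
    edges: tuple[tuple[int, int, float], ...]
    #: support annotations carried from input newick internal-node labels
    support: Mapping[Split, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for a, b, w in self.edges:
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))
        return adj

    def leaf_sets(self) -> dict[tuple[int, int], frozenset[int]]:
        """For each directed edge (a, b): leaves on the b side of the edge."""
        adj = self.adjacency()
        below: dict[tuple[int, int], set[int]] = {}
        # iterative post-order from leaf 0
        visit: list[tuple[int, int, bool]] = [(0, nb, False) for nb, _ in adj[0]]
        while visit:
            parent, node, done = visit.pop()
            if done:
                leaves = set()
                if node < self.n:
                    leaves.add(node)
                for nb, _ in adj[node]:
                    if nb != parent:
                        leaves |= below[(node, nb)]
                below[(parent, node)] = frozenset(leaves)
                continue
            visit.append((parent, node, True))
            for nb, _ in adj[node]:
                if nb != parent:
                    visit.append((node, nb, False))
        return below

    def splits(self) -> SplitSet:
        """Canonical non-trivial splits, one per internal branch."""
        return frozenset(dict(self._edge_splits()).values())

    def _edge_splits(self) -> list[tuple[tuple[int, int], Split]]:
        """(directed internal edge, canonical split) pairs, post-order."""
        out = []
        for (a, b), leaves in self.leaf_sets().items():
            if 2 <= len(leaves) <= self.n - 2:
                side = frozenset(self.taxa[i] for i in leaves)
                out.append(((a, b), canonical_split(side, self.taxa)))
        return out

    def patristic(self) -> np.ndarray:
        """``(n, n)`` matrix of leaf-to-leaf path lengths."""
        adj = self.adjacency()
        n = self.n
        out = np.zeros((n, n))
        for src in range(n):
            dist = {src: 0.0}
            queue = deque([src])
            while queue:
                node = queue.popleft()
                for nb, w in adj[node]:
                    if nb not in dist:
                        if math.isnan(w):
                            raise ConsistencyError(
                                "patristic distance needs branch lengths on "
                                "every edge"
                            )
                        dist[nb] = dist[node] + w
                        queue.append(nb)
            for leaf in range(n):
                out[src, leaf] = dist[leaf]
        return out


# --------------------------------------------------------------------------
# newick
# --------------------------------------------------------------------------

def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into an unrooted :class:`Phylogeny`.

    Internal-node labels, when numeric, are preserved as support
    annotations keyed by the canonical split under that node.
    """
    import dendropy

    text = text.strip()
    if not text.endswith(";"):
        raise ParseError("newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed newick: {exc}") from exc
    # a rooted bifurcation at the top is an artefact of the string form
    if len(tree.seed_node.child_nodes()) == 2:
        tree.collapse_basal_bifurcation()

    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ParseError("newick tree needs at least two leaves")
    taxa = tuple(lf.taxon.label for lf in leaves)
    if len(set(taxa)) != len(taxa):
        raise ParseError("duplicate leaf labels in newick")

    ids: dict = {}
    for i, lf in enumerate(leaves):
        ids[lf] = i
    next_id = len(leaves)
    edges: list[tuple[int, int, float]] = []
    support: dict[Split, float] = {}
    n = len(taxa)
    for node in tree.preorder_node_iter():
        if node not in ids:
            ids[node] = next_id
            next_id += 1
        if not node.is_leaf() and node.label and node.parent_node is not None:
            # numeric internal labels are support values for the split
            # under this node
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= n - 2:
                try:
                    support[canonical_split(side, taxa)] = float(node.label)
                except ValueError:
                    pass
        if node.parent_node is not None:
            length = node.edge.length
            edges.append(
                (ids[node.parent_node], ids[node],
                 float("nan") if length is None else float(length))
            )
    return Phylogeny(taxa, tuple(edges), support)


def write_newick(
    tree: Phylogeny,
    support: Mapping[Split, float] | None = None,
    decimals: int = 6,
) -> str:
    """Serialize to newick, optionally labelling internal nodes with support.

    ``support`` maps canonical splits of *this* tree to scores; a key that
    is not a split of the tree raises :class:`ConsistencyError`.
    """
    if support is not None:
        extra = set(support) - set(tree.splits())
        if extra:
            raise ConsistencyError(
                f"support given for {len(extra)} split(s) absent from tree"
            )
    split_of = dict(tree._edge_splits())
    adj = tree.adjacency()

    # root at the neighbour of leaf 0 so leaf 0 heads the outer grouping
    root = adj[0][0][0] if tree.n > 1 else 0

    def fmt_len(w: float) -> str:
        return "" if math.isnan(w) else f":{w:.{decimals}f}"

    def render(parent: int, node: int, w: float) -> str:
        children = [(nb, wt) for nb, wt in adj[node] if nb != parent]
        if not children:
            return f"{tree.taxa[node]}{fmt_len(w)}"
        inner = ",".join(render(node, nb, wt) for nb, wt in children)
        label = ""
        if support is not None:
            split = split_of.get((parent, node))
            if split is not None and split in support:
                label = f"{support[split]:.1f}"
        return f"({inner}){label}{fmt_len(w)}"

    # emit the branch to leaf 0 first so the canonical-split anchor taxon
    # stays first when the string is reparsed
    children = sorted(adj[root], key=lambda e: e[0] != 0)
    parts = [render(root, nb, wt) for nb, wt in children]
    return f"({','.join(parts)});"
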