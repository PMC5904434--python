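"""Core domain types and readers/writers for the standard formats the toolkit touches.

The toolkit operates on four kinds of objects: a gapped reference multiple
sequence alignment over a fixed column space, a rooted reference phylogeny
with branch lengths and uniquely labeled tips, an optional ranked taxonomy
per tip, and sample-by-feature count tables.  Trees are exchanged as newick,
alignments and fragments as FASTA, placements as jplace (v3), taxonomies and
count tables as TSV.

Conventions
-----------
* Alignment columns are addressed 1-based in user-facing interfaces; internal
  storage is 0-based Python indexing.
* Sequence alphabet after normalization is ``{A, C, G, T, -, N}``.  ``U`` maps
  to ``T``, ``.`` to ``-``, lowercase to uppercase, and any other IUPAC code
  to ``N``.
* Every non-root tree node owns the edge to its parent.  Edge identifiers are
  consecutive integers assigned in depth-first postorder, which is also the
  order in which ``{n}`` markers appear in an edge-numbered (jplace) newick
  string, so identifiers are stable across serialization.
* jplace ``distal_length`` is measured from the edge's child (tipward) node.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from skbio import TreeNode

from .errors import (
    AlignmentShapeError,
    EdgeReferenceError,
    IdentifierError,
    PlacefragError,
)

_NORMALIZE = str.maketrans(
    {
        "u": "T",
        "U": "T",
        ".": "-",
        "a": "A",
        "c": "C",
        "g": "G",
        "t": "T",
        "n": "N",
    }
)
_ALPHABET = frozenset("ACGT-N")


def normalize_sequence(seq: str) -> str:
    """Normalize a gapped nucleotide string to the ``{A,C,G,T,-,N}`` alphabet."""
    out = seq.translate(_NORMALIZE).upper()
    if not _ALPHABET.issuperset(out):
        out = "".join(c if c in _ALPHABET else "N" for c in out)
    return out


@dataclass
class MultipleAlignment:
    """A gapped multiple sequence alignment over a fixed column space.

    Parameters
    ----------
    rows
        Mapping from sequence identifier to gapped sequence string.  All rows
        must have exactly ``n_columns`` characters.
    n_columns
        Number of alignment columns.
    """

    rows: dict[str, str]
    n_columns: int

    def __post_init__(self) -> None:
        for name, seq in self.rows.items():
            if len(seq) != self.n_columns:
                raise AlignmentShapeError(
                    f"row {name!r} has {len(seq)} columns, expected {self.n_columns}"
                )

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "MultipleAlignment":
        """Build a normalized alignment from ``(identifier, sequence)`` pairs."""
        rows: dict[str, str] = {}
        n_columns = None
        for name, seq in records:
            if name in rows:
                raise IdentifierError(f"duplicate sequence identifier {name!r}")
            seq = normalize_sequence(seq)
            if n_columns is None:
                n_columns = len(seq)
            elif len(seq) != n_columns:
                raise AlignmentShapeError(
                    f"row {name!r} has {len(seq)} columns, expected {n_columns}"
                )
            rows[name] = seq
        if n_columns is None:
            raise AlignmentShapeError("alignment contains no records")
        return cls(rows=rows, n_columns=n_columns)

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, names: Iterable[str]) -> "MultipleAlignment":
        """Row-induced sub-alignment (same column space)."""
        missing = [n for n in names if n not in self.rows]
        if missing:
            raise IdentifierError(f"unknown alignment rows: {missing[:5]}")
        return MultipleAlignment(
            rows={n: self.rows[n] for n in names}, n_columns=self.n_columns
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.rows.items():
                fh.write(f">{name}\n{seq}\n")


def read_alignment(path) -> MultipleAlignment:
    """Read a FASTA alignment file into a normalized :class:`MultipleAlignment`.

    Raises
    ------
    AlignmentShapeError
        If records do not all share the length of the first record.
    IdentifierError
        If two records share an identifier.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as fh:
        records = [(title.split()[0], seq) for title, seq in SimpleFastaParser(fh)]
    return MultipleAlignment.from_records(records)


class ReferenceTree:
    """A rooted phylogeny with branch lengths, labeled tips and stable edge ids.

    Wraps a ``skbio.TreeNode``.  On construction, tip labels are checked for
    uniqueness, missing branch lengths are replaced by ``0.0`` with a warning,
    and every non-root node is assigned an integer ``edge_num`` (the id of the
    edge to its parent) in depth-first postorder.
    """

    def __init__(self, tree: TreeNode):
        self.tree = tree
        names = [t.name for t in tree.tips()]
        if any(n is None for n in names):
            raise IdentifierError("tree contains unlabeled tips")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise IdentifierError(f"duplicate tip labels: {dupes[:5]}")
        self._edges: list[TreeNode] = []
        missing_lengths = 0
        for node in tree.postorder(include_self=True):
            if node.is_root():
                continue
            if node.length is None:
                node.length = 0.0
                missing_lengths += 1
            elif node.length < 0 or not math.isfinite(node.length):
                raise PlacefragError(
                    f"edge above {node.name!r} has invalid length {node.length}"
                )
            node.edge_num = len(self._edges)
            self._edges.append(node)
        if missing_lengths:
            warnings.warn(
                f"{missing_lengths} edges had no branch length; set to 0.0",
                stacklevel=2,
            )
        self._tip_index = {t.name: t for t in tree.tips()}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "ReferenceTree":
        return cls(TreeNode.read([text], convert_underscores=False))

    @classmethod
    def read(cls, path) -> "ReferenceTree":
        return cls(TreeNode.read(str(path), convert_underscores=False))

    def copy(self) -> "ReferenceTree":
        return ReferenceTree(self.tree.copy())

    # -- basic accessors --------------------------------------------------
    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def tip_set(self) -> frozenset[str]:
        return frozenset(self._tip_index)

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def find_tip(self, name: str) -> TreeNode:
        try:
            return self._tip_index[name]
        except KeyError:
            raise IdentifierError(f"unknown tip {name!r}") from None

    def edge_node(self, edge_id: int) -> TreeNode:
        """Child node owning edge ``edge_id``."""
        if not 0 <= edge_id < len(self._edges):
            raise EdgeReferenceError(f"edge {edge_id} not in tree")
        return self._edges[edge_id]

    def edges(self) -> Sequence[TreeNode]:
        return tuple(self._edges)

    def total_branch_length(self) -> float:
        return sum(n.length for n in self._edges)

    def mean_tip_depth(self) -> float:
        """Mean root-to-tip path length."""
        total = 0.0
        for tip in self.tree.tips():
            total += tip.accumulate_to_ancestor(self.tree)
        return total / self.n_tips

    # -- serialization ----------------------------------------------------
    def to_newick(self) -> str:
        return str(self.tree).strip()

    def write(self, path) -> None:
        self.tree.write(str(path))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ReferenceTree: {self.n_tips} tips, {self.n_edges} edges>"


@dataclass
class Taxonomy:
    """Ranked lineages per tip label.

    ``ranks`` orders the rank names; ``lineages`` maps a tip label to a tuple
    of taxon names, one per rank.  Empty strings mark missing ranks, and
    lineages shorter than ``ranks`` are implicitly missing at the deep end.
    """

    lineages: dict[str, tuple[str, ...]]
    ranks: tuple[str, ...] = (
        "kingdom",
        "phylum",
        "class",
        "order",
        "family",
        "genus",
        "species",
    )

    def lineage_prefix(self, tip: str, depth: int) -> tuple[str, ...] | None:
        """Lineage truncated to ``depth`` ranks, or None if any rank is missing."""
        lin = self.lineages.get(tip)
        if lin is None or len(lin) < depth:
            return None
        prefix = lin[:depth]
        if any(not part for part in prefix):
            return None
        return prefix

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for tip, lin in self.lineages.items():
                fh.write(f"{tip}\t{'; '.join(lin)}\n")


def read_taxonomy(path, ranks: tuple[str, ...] | None = None) -> Taxonomy:
    """Read a two-column TSV (tip id, semicolon-delimited lineage)."""
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tip, _, lin = line.partition("\t")
            lineages[tip] = tuple(part.strip() for part in lin.split(";"))
    if ranks is None:
        default = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
        depth = max((len(v) for v in lineages.values()), default=1)
        ranks = default[: max(depth, 1)]
    return Taxonomy(lineages=lineages, ranks=ranks)


class CountTable:
    """Samples-by-features table of non-negative integer counts."""

    def __init__(self, data: pd.DataFrame):
        if (data.values < 0).any():
            raise PlacefragError("count table contains negative entries")
        self.data = data.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def presence(self) -> pd.DataFrame:
        return (self.data > 0).astype(int)

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass(frozen=True)
class Placement:
    """Attachment of one query fragment to one reference edge.

    ``distal_length`` is the distance from the edge's child (tipward) node to
    the attachment point; ``pendant_length`` is the length of the new branch
    carrying the fragment tip (always positive); ``score`` is the optimized
    per-site relative log-likelihood of the attachment.
    """

    fragment_id: str
    edge_id: int
    distal_length: float
    pendant_length: float
    score: float
    subset_id: int | None = None


_JPLACE_FIELDS = [
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
]


def _edge_numbered_newick(tree: ReferenceTree) -> str:
    """Serialize with jplace curly-brace edge numbers after each branch length."""

    def rec(node: TreeNode) -> str:
        if node.is_tip():
            s = node.name
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.name:
                s += node.name
        if node.is_root():
            return s + ";"
        return f"{s}:{node.length!r}{{{node.edge_num}}}"

    return rec(tree.tree)


def write_jplace(placements: Sequence[Placement], tree: ReferenceTree, path) -> None:
    """Write placements as a jplace v3 JSON file.

    Raises
    ------
    EdgeReferenceError
        If a placement references an edge id absent from ``tree``.
    """
    for plc in placements:
        tree.edge_node(plc.edge_id)  # raises on unknown edge
    doc = {
        "version": 3,
        "tree": _edge_numbered_newick(tree),
        "fields": list(_JPLACE_FIELDS),
        "placements": [
            {
                "p": [
                    [
                        plc.edge_id,
                        plc.score,
                        1.0,
                        plc.distal_length,
                        plc.pendant_length,
                    ]
                ],
                "n": [plc.fragment_id],
            }
            for plc in placements
        ],
        "metadata": {"invocation": "placefrag"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_jplace(path) -> tuple[list[Placement], ReferenceTree]:
    """Read a jplace file written by :func:`write_jplace` (or compatible)."""
    with open(path) as fh:
        doc = json.load(fh)
    tree_str = doc["tree"]
    edge_nums = [int(m) for m in re.findall(r"\{(\d+)\}", tree_str)]
    tree = ReferenceTree.from_newick(re.sub(r"\{\d+\}", "", tree_str))
    # {n} markers appear in the same depth-first postorder used for edge ids;
    # remap in case the producer numbered edges differently.
    jplace_to_node = {num: tree.edges()[i] for i, num in enumerate(edge_nums)}
    fields = doc["fields"]
    idx = {f: fields.index(f) for f in _JPLACE_FIELDS if f in fields}
    placements = []
    for entry in doc["placements"]:
        names = entry.get("n") or entry.get("nm") or ["?"]
        name = names[0] if not isinstance(names[0], list) else names[0][0]
        for p in entry["p"]:
            node = jplace_to_node[int(p[idx["edge_num"]])]
            placements.append(
                Placement(
                    fragment_id=name,
                    edge_id=node.edge_num,
                    distal_length=float(p[idx["distal_length"]]),
                    pendant_length=float(p[idx["pendant_length"]]),
                    score=float(p[idx["likelihood"]]),
                )
            )
    return placements, tree
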