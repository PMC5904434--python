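"""Generation, dereplication, classification and mutation of amplicon fragments.

A *fragment* is the degapped slice of one alignment row over a fixed column
window (the in-silico analog of an amplified variable region such as 16S V4),
trimmed to a fixed target length.  Because distinct full-length sequences can
yield identical slices, fragments are dereplicated and each unique sequence
keeps the set of reference identifiers it originated from (its *ambiguity*).

The window is addressed 1-based with an exclusive end, so ``(2263, 3794)``
denotes 1,531 alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import (
    InvariantViolationError,
    SaturationError,
    WindowRangeError,
)
from .model_io import MultipleAlignment, normalize_sequence

_BASES = "ACGT"


@dataclass(frozen=True)
class Fragment:
    """A dereplicated fixed-length ungapped fragment and its originating rows."""

    id: str
    sequence: str
    origins: frozenset[str]

    @property
    def ambiguity(self) -> int:
        return len(self.origins)

    def __post_init__(self) -> None:
        if not self.origins:
            raise InvariantViolationError(f"fragment {self.id!r} has no origins")
        if "-" in self.sequence:
            raise InvariantViolationError(f"fragment {self.id!r} contains gaps")


@dataclass
class FragmentSet:
    """Unique fragments plus the bookkeeping counts of their extraction.

    ``stats`` keys: ``n_input``, ``n_too_short_discarded``, ``n_trimmed``,
    ``n_kept``, ``n_duplicates``, ``n_unique``; the identities
    ``n_kept = n_input - n_too_short_discarded`` and
    ``n_unique = n_kept - n_duplicates`` always hold.
    """

    fragments: list[Fragment]
    stats: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def by_id(self) -> dict[str, Fragment]:
        return {f.id: f for f in self.fragments}

    def unambiguous(self) -> list[Fragment]:
        return [f for f in self.fragments if f.ambiguity == 1]

    def write(self, path) -> None:
        """Write fragments as FASTA; headers carry ``;origins=a,b;`` annotations."""
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(f">{f.id};origins={','.join(sorted(f.origins))};\n")
                fh.write(f.sequence + "\n")

    @classmethod
    def read(cls, path) -> "FragmentSet":
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        fragments = []
        with open(path) as fh:
            for title, seq in SimpleFastaParser(fh):
                fid, _, rest = title.partition(";")
                origins = frozenset()
                for part in rest.split(";"):
                    if part.startswith("origins="):
                        origins = frozenset(part[len("origins=") :].split(","))
                fragments.append(
                    Fragment(id=fid, sequence=normalize_sequence(seq), origins=origins or frozenset({fid}))
                )
        return cls(fragments=fragments, stats={})


def extract_fragments(
    alignment: MultipleAlignment,
    window_start: int,
    window_end: int,
    target_len: int,
) -> FragmentSet:
    """Slice a column window out of every row, degap, length-filter, dereplicate.

    Parameters
    ----------
    window_start, window_end
        1-based half-open column window (``window_end`` is exclusive).
    target_len
        Fragment length in nt.  Degapped slices shorter than this are
        discarded; longer slices are trimmed to their first ``target_len``
        characters.

    Notes
    -----
    Rows whose window contains ``N`` are kept; sequences are compared
    literally during dereplication, so an ``N`` never merges with a base.
    Origins of duplicates are merged as a set union, and fragment ids are
    assigned in lexicographic sequence order so the result is independent of
    the input row order.
    """
    if not (1 <= window_start < window_end <= alignment.n_columns + 1):
        raise WindowRangeError(
            f"window [{window_start}, {window_end}) outside 1..{alignment.n_columns}"
        )
    n_too_short = 0
    n_trimmed = 0
    by_seq: dict[str, set[str]] = {}
    lo, hi = window_start - 1, window_end - 1
    for name, row in alignment.rows.items():
        piece = row[lo:hi].replace("-", "")
        if len(piece) < target_len:
            n_too_short += 1
            continue
        if len(piece) > target_len:
            n_trimmed += 1
            piece = piece[:target_len]
        by_seq.setdefault(piece, set()).add(name)
    n_input = len(alignment.rows)
    n_kept = n_input - n_too_short
    n_unique = len(by_seq)
    fragments = [
        Fragment(id=f"F{i:06d}", sequence=seq, origins=frozenset(origins))
        for i, (seq, origins) in enumerate(sorted(by_seq.items()))
    ]
    stats = {
        "n_input": n_input,
        "n_too_short_discarded": n_too_short,
        "n_trimmed": n_trimmed,
        "n_kept": n_kept,
        "n_duplicates": n_kept - n_unique,
        "n_unique": n_unique,
    }
    return FragmentSet(fragments=fragments, stats=stats)


@dataclass(frozen=True)
class FragmentClassification:
    ambiguity_bin: str
    representative_only: bool


def classify_fragment(
    fragment: Fragment,
    representative_ids: frozenset[str] | set[str],
    bin_cap: int = 7,
) -> FragmentClassification:
    """Bin a fragment by ambiguity and flag whether all origins are reference tips.

    Ambiguities above ``bin_cap`` collapse into a single ``">cap"`` bin
    (the evaluation figures bin everything beyond 7 originating OTUs).
    """
    if bin_cap < 1:
        raise ValueError("bin_cap must be >= 1")
    amb = fragment.ambiguity  # Fragment guarantees >= 1
    bin_label = str(amb) if amb <= bin_cap else f">{bin_cap}"
    rep_only = fragment.origins <= frozenset(representative_ids)
    return FragmentClassification(ambiguity_bin=bin_label, representative_only=rep_only)


def mutate_fragment(
    sequence: str,
    k: int,
    rng: int | np.random.Generator,
    forbidden: Iterable[str] = (),
    max_tries: int = 1000,
) -> str:
    """Introduce exactly ``k`` point mutations, avoiding a forbidden set.

    Each mutated position is hit once and changed to a different base, so the
    Hamming distance to the input is exactly ``k``.  If the mutant is in
    ``forbidden``, the full position set is redrawn (an unbiased resampling
    policy) until a novel sequence is found or ``max_tries`` is exhausted.
    """
    if not 0 <= k <= len(sequence):
        raise ValueError(f"k={k} outside 0..{len(sequence)}")
    if k == 0:
        return sequence
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    forbidden = frozenset(forbidden)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for _ in range(max_tries):
        positions = rng.choice(len(sequence), size=k, replace=False)
        chars = list(sequence)
        for pos in positions:
            old = chars[pos]
            # draw one of the three other bases uniformly
            offset = int(rng.integers(1, 4))
            chars[pos] = _BASES[(base_idx.get(old, int(rng.integers(0, 4))) + offset) % 4]
        mutant = "".join(chars)
        if mutant not in forbidden:
            return mutant
    raise SaturationError(
        f"could not find a novel {k}-mutant within {max_tries} tries"
    )
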