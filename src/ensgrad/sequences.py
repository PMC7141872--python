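"""Amino-acid alphabet, CDR-H3 validation and (relaxed) one-hot encoding.

Sequences are strings over the 20 canonical residues.  Library and seed
CDR-H3 loops are 10-18 residues long; the encoder itself accepts 1..20 so
that edge cases and padding can be exercised directly.  The fixed encoding
is a 20-position x 20-channel matrix: the sequence occupies the leftmost
positions (one 1 per column), the remainder are all-zero padding columns.
There is no dedicated pad channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

#: Fixed number of encoder positions (columns of the one-hot matrix).
MAX_POSITIONS = 20

#: Library / seed CDR-H3 length bounds.
MIN_CDR_LENGTH = 10
MAX_CDR_LENGTH = 18


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of the 20 canonical amino-acid one-letter codes."""

    residues: str = "ACDEFGHIKLMNPQRSTVWY"

    def __post_init__(self) -> None:
        if len(self.residues) != 20 or len(set(self.residues)) != 20:
            raise ValueError("alphabet must contain 20 distinct residues")
        if not self.residues.isupper():
            raise ValueError("alphabet residues must be uppercase letters")

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, residue: str) -> bool:
        return residue in self.residues

    def index_of(self, residue: str) -> int:
        """0-based channel index of ``residue``; raises on unknown codes."""
        i = self.residues.find(residue)
        if i < 0:
            raise ValueError(f"residue {residue!r} is not a canonical amino acid")
        return i

    def indices(self, residues: Iterable[str]) -> list[int]:
        return [self.index_of(r) for r in residues]


#: Default canonical alphabet, alphabetical order.
ALPHABET = Alphabet()


def validate_sequence(
    seq: str,
    alphabet: Alphabet = ALPHABET,
    min_length: int = MIN_CDR_LENGTH,
    max_length: int = MAX_CDR_LENGTH,
) -> str:
    """Check that ``seq`` is a CDR-H3 candidate within the length bounds.

    Returns the sequence unchanged; raises ``ValueError`` naming the first
    offending position on a non-alphabet character, or on a length
    violation.
    """
    if not min_length <= len(seq) <= max_length:
        raise ValueError(
            f"sequence length {len(seq)} outside [{min_length}, {max_length}]: {seq!r}"
        )
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(f"invalid residue {ch!r} at position {i} in {seq!r}")
    return seq


def encode_onehot(seq: str, alphabet: Alphabet = ALPHABET) -> np.ndarray:
    """Encode a sequence as a (MAX_POSITIONS, 20) one-hot matrix.

    Position ``i`` carries a 1 in the channel of ``seq[i]``; positions at
    and beyond ``len(seq)`` are all-zero padding columns.  Accepts lengths
    0..20 (the empty string encodes to the all-zero matrix).
    """
    if len(seq) > MAX_POSITIONS:
        raise ValueError(f"sequence length {len(seq)} exceeds {MAX_POSITIONS}")
    m = np.zeros((MAX_POSITIONS, len(alphabet)), dtype=np.float64)
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(f"invalid residue {ch!r} at position {i} in {seq!r}")
        m[i, alphabet.index_of(ch)] = 1.0
    return m


def encode_batch(seqs: Sequence[str], alphabet: Alphabet = ALPHABET) -> np.ndarray:
    """Stack one-hot encodings into a (n, MAX_POSITIONS, 20) array."""
    return np.stack([encode_onehot(s, alphabet) for s in seqs])


def decode_argmax(
    matrix: np.ndarray, length: int, alphabet: Alphabet = ALPHABET
) -> str:
    """Project a relaxed matrix back to a discrete sequence of ``length``.

    Each of the first ``length`` positions maps to the channel with the
    maximal value; ties break deterministically toward the lowest channel
    index (numpy argmax convention).
    """
    if not 1 <= length <= MAX_POSITIONS:
        raise ValueError(f"length {length} outside [1, {MAX_POSITIONS}]")
    matrix = np.asarray(matrix)
    if matrix.shape != (MAX_POSITIONS, len(alphabet)):
        raise ValueError(
            f"expected shape ({MAX_POSITIONS}, {len(alphabet)}), got {matrix.shape}"
        )
    idx = np.argmax(matrix[:length], axis=1)
    return "".join(alphabet.residues[i] for i in idx)


# ---------------------------------------------------------------------------
# Plain-text sequence I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (header, sequence) pairs."""
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def read_sequence_lines(path: str | Path) -> list[str]:
    """Read one sequence per line, ignoring blanks."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def iter_unique(seqs: Iterable[str]) -> Iterator[str]:
    """Yield sequences in first-seen order, dropping duplicates."""
    seen: set[str] = set()
    for s in seqs:
        if s not in seen:
            seen.add(s)
            yield s
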