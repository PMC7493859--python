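"""FASTA input/output, alphabet validation and one-hot encoding.

Sequences live over the four-letter DNA alphabet ``A, C, G, T``.  A
sequence of length ``L`` is encoded as a binary matrix of shape
``(L, 4)`` -- positions along the rows, one indicator channel per symbol
along the columns, in fixed alphabetical channel order ``(A, C, G, T)``.
A batch of ``N`` equal-length sequences is the tensor ``(N, L, 4)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical DNA alphabet; also the fixed one-hot channel order.
ALPHABET = "ACGT"

_CHANNEL = {base: i for i, base in enumerate(ALPHABET)}


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into usable records."""


class AlphabetError(ValueError):
    """Raised under the strict policy when a sequence contains non-ACGT symbols."""


@dataclass
class DnaSequence:
    """A named DNA sequence with an optional binary class label.

    Label convention: 1 = nucleosome (positive class), 0 = linker.
    """

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """A collection of equal-length, fully labeled DNA sequences."""

    sequences: list[DnaSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("dataset is empty")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        missing = [s.id for s in self.sequences if s.label not in (0, 1)]
        if missing:
            raise ValueError(f"sequences without a binary label: {missing[:5]}")

    @property
    def length(self) -> int:
        """Common sequence length L in bp."""
        return len(self.sequences[0])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sequences], dtype=np.int64)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        y = self.labels
        return int((y == 1).sum()), int((y == 0).sum())

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.sequences[i] for i in indices])

    def encode(self) -> np.ndarray:
        """One-hot encode the whole dataset, shape (N, L, 4)."""
        return one_hot_encode(self.sequences)

    @classmethod
    def from_fasta(cls, positives: str, negatives: str,
                   policy: str = "strict") -> "LabeledDataset":
        """Build a dataset from the two-FASTA convention.

        ``positives`` holds nucleosome sequences (label 1), ``negatives``
        linker sequences (label 0).  ``policy`` is passed through to
        :func:`validate_alphabet`.
        """
        seqs = read_fasta(positives, label=1) + read_fasta(negatives, label=0)
        return cls(validate_alphabet(seqs, policy=policy))

    def to_fasta(self, positives: str, negatives: str) -> None:
        write_fasta([s for s in self.sequences if s.label == 1], positives)
        write_fasta([s for s in self.sequences if s.label == 0], negatives)


def read_fasta(path: str, label: int | None = None) -> list[DnaSequence]:
    """Read a FASTA file into a list of :class:`DnaSequence`.

    Sequences are uppercase-normalized; ``label`` (if given) is attached
    to every record.  Raises :class:`FastaParseError` on an empty file or
    a record with a header but no sequence line.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaParseError(
                f"record {rec.id!r} in {path} has no sequence data")
        out.append(DnaSequence(id=rec.id, seq=str(rec.seq), label=label))
    return out


def write_fasta(seqs: Sequence[DnaSequence], path: str,
                line_width: int = 70) -> None:
    """Write sequences to ``path`` in wrapped FASTA format."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), line_width):
                fh.write(s.seq[i:i + line_width] + "\n")


def validate_alphabet(seqs: Sequence[DnaSequence],
                      policy: str = "strict") -> list[DnaSequence]:
    """Enforce the four-letter alphabet.

    policy="strict"
        Raise :class:`AlphabetError` on the first sequence containing a
        symbol outside ACGT (IUPAC ambiguity codes and N included),
        naming the sequence and the 1-based offending position.
    policy="drop"
        Silently remove offending sequences; the number dropped is
        logged at INFO level.
    """
    if policy not in ("strict", "drop"):
        raise ValueError(f"unknown policy {policy!r}; use 'strict' or 'drop'")
    kept: list[DnaSequence] = []
    dropped = 0
    for s in seqs:
        bad = next((i for i, ch in enumerate(s.seq) if ch not in _CHANNEL), None)
        if bad is None:
            kept.append(s)
        elif policy == "strict":
            raise AlphabetError(
                f"sequence {s.id!r} contains non-ACGT symbol "
                f"{s.seq[bad]!r} at position {bad + 1}")
        else:
            dropped += 1
    if dropped:
        logger.info("validate_alphabet: dropped %d sequence(s) with "
                    "non-ACGT symbols", dropped)
    return kept


def one_hot_encode(seqs) -> np.ndarray:
    """One-hot encode sequences into a ``(N, L, 4)`` binary tensor.

    Accepts :class:`DnaSequence` objects or plain strings.  All
    sequences must share one length and be ACGT-only.
    """
    strings = [s.seq if isinstance(s, DnaSequence) else str(s).upper()
               for s in seqs]
    ids = [s.id if isinstance(s, DnaSequence) else f"seq{i}"
           for i, s in enumerate(seqs)]
    if not strings:
        raise ValueError("nothing to encode")
    L = len(strings[0])
    offenders = [i for s, i in zip(strings, ids) if len(s) != L]
    if offenders:
        raise ValueError(f"unequal sequence lengths; offending ids: {offenders}")
    # Map characters to channel indices in one vectorized pass.
    lut = np.full(128, -1, dtype=np.int64)
    for base, ch in _CHANNEL.items():
        lut[ord(base)] = ch
    codes = lut[np.frombuffer("".join(strings).encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise AlphabetError("non-ACGT symbol encountered; validate first")
    codes = codes.reshape(len(strings), L)
    out = np.zeros((len(strings), L, 4), dtype=np.float32)
    np.put_along_axis(out, codes[:, :, None], 1.0, axis=2)
    return out


def one_hot_decode(tensor: np.ndarray) -> list[str]:
    """Invert :func:`one_hot_encode`.

    ``tensor`` may be a single ``(L, 4)`` matrix or a ``(N, L, 4)``
    batch.  Every position row must be a valid one-hot indicator.
    """
    t = np.asarray(tensor)
    if t.ndim == 2:
        t = t[None]
    if t.ndim != 3 or t.shape[-1] != 4:
        raise ValueError(f"expected shape (N, L, 4), got {t.shape}")
    sums = t.sum(axis=2)
    bad = np.argwhere(sums != 1)
    if bad.size:
        n, l = bad[0]
        raise ValueError(
            f"row at sequence {n}, position {l} is not one-hot "
            f"(channel sum {sums[n, l]:g})")
    idx = t.argmax(axis=2)
    chars = np.array(list(ALPHABET))
    return ["".join(row) for row in chars[idx]]
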