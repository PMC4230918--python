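"""DNA sequence-to-signal mapping via doublet (dinucleotide) values.

A DNA sequence of length ``M`` yields ``M - 1`` overlapping doublets.  Each
doublet carries a numeric value from a 16-entry table, and a sliding window
of ``alpha`` consecutive doublet values is combined (sum by default) into one
signal sample, giving a real-valued signal of length ``M - alpha``.  Larger
``alpha`` smooths the signal and widens its amplitude alphabet; it also
controls how far a single substitution propagates (at most ``alpha + 1``
samples shift vertically, while indels shift the signal tail horizontally).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO

__all__ = [
    "DEFAULT_DOUBLET_VALUES",
    "DoubletTable",
    "MappingConfig",
    "DNASequence",
    "DNASignal",
    "read_fasta",
    "write_fasta",
    "doublet_value",
    "map_sequence",
]

NUCLEOTIDES = "ACGT"

#: Default doublet-to-value assignment.
DEFAULT_DOUBLET_VALUES: dict[str, float] = {
    "AA": 0, "AT": 1, "TA": 2, "AG": 3, "TT": 4, "TG": 5, "AC": 6, "TC": 7,
    "GA": 8, "CA": 9, "GT": 10, "GG": 11, "CT": 12, "GC": 13, "CG": 14, "CC": 15,
}

Combiner = Literal["sum", "mean", "positional"]
NonACGTPolicy = Literal["error", "drop"]


@dataclass(frozen=True)
class DoubletTable:
    """Mapping from each of the 16 ordered dinucleotides to a real value."""

    values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOUBLET_VALUES)
    )

    def __post_init__(self) -> None:
        expected = {a + b for a, b in product(NUCLEOTIDES, repeat=2)}
        keys = set(self.values)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise ValueError(
                f"doublet table must have exactly the 16 ordered dinucleotides; "
                f"missing={missing}, unexpected={extra}"
            )

    def __getitem__(self, doublet: str) -> float:
        return self.values[doublet]

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoubletTable":
        """Read a two-column (doublet, value) CSV/TSV table."""
        values: dict[str, float] = {}
        with open(path, newline="") as fh:
            sample = fh.read(1024)
            fh.seek(0)
            delim = "\t" if "\t" in sample else ","
            for row in csv.reader(fh, delimiter=delim):
                if not row or row[0].strip().lower() in ("doublet", ""):
                    continue
                d = row[0].strip().upper()
                if d in values:
                    raise ValueError(f"duplicate doublet {d!r} in {path}")
                values[d] = float(row[1])
        return cls(values)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["doublet", "value"])
            for d in sorted(self.values):
                writer.writerow([d, self.values[d]])


@dataclass(frozen=True)
class MappingConfig:
    """Window magnitude and combining rule for doublet-value mapping.

    alpha
        Number of consecutive doublet values combined into one sample
        (must satisfy ``alpha <= M - 1`` for a length-``M`` sequence).
    combiner
        ``sum`` (default), ``mean`` (sum / alpha), or ``positional``
        (sum of ``16**j * v_j``, a K-strings-style radix encoding).
    non_acgt_policy
        ``error`` rejects any residue outside ACGT; ``drop`` removes it
        before mapping.
    """

    alpha: int = 3
    combiner: Combiner = "sum"
    non_acgt_policy: NonACGTPolicy = "error"

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError(f"alpha must be >= 1, got {self.alpha}")
        if self.combiner not in ("sum", "mean", "positional"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.non_acgt_policy not in ("error", "drop"):
            raise ValueError(f"unknown non-ACGT policy {self.non_acgt_policy!r}")


@dataclass(frozen=True)
class DNASequence:
    """An identified DNA sequence over the ACGT alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def validated(self, policy: NonACGTPolicy = "error") -> "DNASequence":
        """Return a copy with non-ACGT residues handled per *policy*."""
        bad = [
            (i, c) for i, c in enumerate(self.residues) if c not in NUCLEOTIDES
        ]
        if not bad:
            return self
        if policy == "error":
            pos, char = bad[0]
            raise ValueError(
                f"record {self.id!r}: non-ACGT residue {char!r} at position "
                f"{pos + 1} (1-based)"
            )
        kept = "".join(c for c in self.residues if c in NUCLEOTIDES)
        return DNASequence(self.id, kept)


@dataclass(frozen=True)
class DNASignal:
    """A real-valued signal derived from one DNA sequence."""

    source_id: str
    values: np.ndarray
    alpha: int
    denoised: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    def __len__(self) -> int:
        return len(self.values)


def read_fasta(path: str | Path) -> list[DNASequence]:
    """Read a multi-record FASTA file.

    Record ids are the first whitespace-delimited token of each header;
    residues are uppercased.  Raises on an empty file.
    """
    records = [
        DNASequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[DNASequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def doublet_value(doublet: str, table: DoubletTable | None = None) -> float:
    """Value of one ordered dinucleotide under *table* (default table if None)."""
    table = table or DoubletTable()
    d = doublet.upper()
    if d not in table.values:
        raise KeyError(f"unknown doublet {doublet!r}")
    return table[d]


def map_sequence(
    seq: DNASequence,
    table: DoubletTable | None = None,
    cfg: MappingConfig | None = None,
) -> DNASignal:
    """Map a DNA sequence to its doublet-value signal.

    Sample ``n`` (0-based) combines the values of the ``alpha`` doublets
    starting at residue ``n``; the output has ``M - alpha`` samples for a
    length-``M`` sequence.
    """
    table = table or DoubletTable()
    cfg = cfg or MappingConfig()
    seq = seq.validated(cfg.non_acgt_policy)
    m = len(seq)
    if m < cfg.alpha + 1:
        raise ValueError(
            f"sequence {seq.id!r} has length {m}; needs at least "
            f"alpha + 1 = {cfg.alpha + 1} residues"
        )
    res = seq.residues
    dvals = np.array(
        [table[res[i : i + 2]] for i in range(m - 1)], dtype=float
    )
    a = cfg.alpha
    if cfg.combiner == "positional":
        weights = 16.0 ** np.arange(a)
    else:
        weights = np.ones(a)
    values = np.convolve(dvals, weights[::-1], mode="valid")
    if cfg.combiner == "mean":
        values = values / a
    return DNASignal(source_id=seq.id, values=values, alpha=a)
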