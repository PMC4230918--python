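"""Seeded generators for synthetic DNA sequences and mutation protocols.

Every generator is a pure function of its parameters and seed, so the
experiments built on top of them (cumulative-substitution distance
profiles, progressive mutation series, exhaustive single/double/triple
change neighborhoods) are fully reproducible.  Mutants are literal and
uniform: substituted bases are drawn uniformly from the three alternatives,
no evolutionary model is imposed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement, product
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .seqsignal import NUCLEOTIDES, DNASequence

__all__ = [
    "MutationSpec",
    "random_sequence",
    "apply_mutations",
    "cumulative_substitution_series",
    "progressive_mutation_set",
    "exhaustive_neighborhood",
    "write_manifest",
]

MutationKind = Literal["substitution", "insertion", "deletion"]


@dataclass(frozen=True)
class MutationSpec:
    """One point mutation: a substitution, insertion or deletion.

    ``position`` is a 0-based residue index into the sequence the spec is
    applied to (for insertions, the base is inserted *before* that index,
    so position may equal the sequence length).
    """

    kind: MutationKind
    position: int
    base: str | None = None

    def __post_init__(self) -> None:
        if self.kind in ("substitution", "insertion"):
            if self.base not in tuple(NUCLEOTIDES):
                raise ValueError(
                    f"{self.kind} requires a base in ACGT, got {self.base!r}"
                )
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")


def random_sequence(n: int, seed: int | np.random.Generator) -> DNASequence:
    """An i.i.d. uniform random DNA sequence of length *n* (>= 2)."""
    if n < 2:
        raise ValueError(f"sequence length must be >= 2, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = rng.choice(list(NUCLEOTIDES), size=n)
    return DNASequence(id=f"random_{n}nt", residues="".join(bases))


def apply_mutations(seq: DNASequence, specs: Sequence[MutationSpec]) -> DNASequence:
    """Apply mutations left to right with index bookkeeping for indels.

    Positions in every spec refer to the *current* sequence at the moment
    that spec is applied.  A substitution that would write the base already
    present is rejected, as is any out-of-range position.
    """
    residues = list(seq.residues)
    for spec in specs:
        if spec.kind == "substitution":
            if spec.position >= len(residues):
                raise IndexError(
                    f"substitution position {spec.position} out of range "
                    f"(length {len(residues)})"
                )
            if residues[spec.position] == spec.base:
                raise ValueError(
                    f"no-op substitution at position {spec.position}: base "
                    f"is already {spec.base!r}"
                )
            residues[spec.position] = spec.base
        elif spec.kind == "deletion":
            if spec.position >= len(residues):
                raise IndexError(
                    f"deletion position {spec.position} out of range "
                    f"(length {len(residues)})"
                )
            del residues[spec.position]
        elif spec.kind == "insertion":
            if spec.position > len(residues):
                raise IndexError(
                    f"insertion position {spec.position} out of range "
                    f"(length {len(residues)})"
                )
            residues.insert(spec.position, spec.base)
        else:  # pragma: no cover - dataclass validates kind
            raise ValueError(f"unknown mutation kind {spec.kind!r}")
    return DNASequence(id=f"{seq.id}_mut", residues="".join(residues))


def _substitute(rng: np.random.Generator, base: str) -> str:
    alternatives = [b for b in NUCLEOTIDES if b != base]
    return alternatives[rng.integers(3)]


def cumulative_substitution_series(
    template: DNASequence,
    counts: Sequence[int] = (1, 3, 5, 10),
    seed: int | np.random.Generator = 0,
) -> list[DNASequence]:
    """Mutants carrying strictly increasing numbers of cumulative substitutions.

    Each mutant extends the previous one's substitution set; positions are
    sampled without replacement, so the k-th mutant sits at Hamming
    distance ``counts[k]`` from the template.
    """
    counts = list(counts)
    if any(b <= a for a, b in zip(counts, counts[1:])) or counts[0] < 1:
        raise ValueError(f"counts must be strictly increasing and >= 1: {counts}")
    m = len(template)
    if counts[-1] > m:
        raise ValueError(f"cannot place {counts[-1]} substitutions in {m} nt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = rng.choice(m, size=counts[-1], replace=False)
    residues = list(template.residues)
    out: list[DNASequence] = []
    done = 0
    for target in counts:
        for pos in positions[done:target]:
            residues[pos] = _substitute(rng, residues[pos])
        done = target
        out.append(
            DNASequence(id=f"{template.id}_sub{target}", residues="".join(residues))
        )
    return out


def progressive_mutation_set(
    template: DNASequence,
    per_round: int = 10,
    stop_fraction: float = 0.20,
    seed: int | np.random.Generator = 0,
) -> list[DNASequence]:
    """Rounds of substitutions in previously untouched bases.

    Each round adds ``per_round`` new substitutions at positions never
    mutated before, until ``stop_fraction`` of the template has changed.
    A 10,000 nt template with defaults yields 200 sequences, the k-th at
    Hamming distance ``10 * k``.
    """
    if per_round < 1:
        raise ValueError("per_round must be >= 1")
    if not 0 < stop_fraction <= 1:
        raise ValueError(f"stop_fraction must lie in (0, 1], got {stop_fraction}")
    m = len(template)
    total = int(round(stop_fraction * m))
    if total % per_round:
        import warnings

        warnings.warn(
            f"{total} target substitutions not divisible by per_round="
            f"{per_round}; final round truncated",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = rng.choice(m, size=total, replace=False)
    residues = list(template.residues)
    out: list[DNASequence] = []
    k = 0
    done = 0
    while done < total:
        batch = positions[done : done + per_round]
        for pos in batch:
            residues[pos] = _substitute(rng, residues[pos])
        done += len(batch)
        k += 1
        out.append(
            DNASequence(id=f"{template.id}_round{k}", residues="".join(residues))
        )
    return out


def exhaustive_neighborhood(
    template: DNASequence,
    max_changes: int = 3,
    kinds: Iterable[MutationKind] = ("substitution",),
    guard: int = 10**6,
) -> list[tuple[DNASequence, dict]]:
    """Every distinct sequence within ``max_changes`` changes of one kind.

    Each kind is enumerated separately (no mixed-type combinations).  For
    substitutions on a 20 nt template this gives 60 singles, 1,710 doubles
    and 30,780 triples.  Duplicate sequences (e.g. indels inside
    homopolymer runs) are removed.  Returns (sequence, summary) pairs with
    the summary recording kind and change count.
    """
    m = len(template)
    est = sum((m * 4) ** k for k in range(1, max_changes + 1)) * len(tuple(kinds))
    if est > guard:
        raise ValueError(
            f"enumeration of ~{est} variants exceeds guard {guard}; "
            "use a sampling protocol instead"
        )
    res = template.residues
    out: list[tuple[DNASequence, dict]] = []
    for kind in kinds:
        seen: set[str] = {res}
        for k in range(1, max_changes + 1):
            for variant in _enumerate_kind(res, kind, k):
                if variant in seen:
                    continue
                seen.add(variant)
                out.append(
                    (
                        DNASequence(
                            id=f"{template.id}_{kind[:3]}{k}_{len(out)}",
                            residues=variant,
                        ),
                        {"kind": kind, "changes": k},
                    )
                )
    return out


def _enumerate_kind(res: str, kind: MutationKind, k: int):
    m = len(res)
    if kind == "substitution":
        for positions in combinations(range(m), k):
            alt_sets = [
                [b for b in NUCLEOTIDES if b != res[p]] for p in positions
            ]
            for bases in product(*alt_sets):
                chars = list(res)
                for p, b in zip(positions, bases):
                    chars[p] = b
                yield "".join(chars)
    elif kind == "deletion":
        for positions in combinations(range(m), k):
            keep = set(range(m)) - set(positions)
            yield "".join(res[i] for i in sorted(keep))
    elif kind == "insertion":
        for slots in combinations_with_replacement(range(m + 1), k):
            for bases in product(NUCLEOTIDES, repeat=k):
                chars = list(res)
                # insert right-to-left so earlier slot indices stay valid
                for slot, base in sorted(zip(slots, bases), reverse=True):
                    chars.insert(slot, base)
                yield "".join(chars)
    else:  # pragma: no cover
        raise ValueError(f"unknown kind {kind!r}")


def write_manifest(
    path: str | Path,
    rows: Iterable[tuple[str, str, int, str, str]],
) -> None:
    """Write a TSV mutation manifest: id, kind, position, from, to."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sequence_id", "kind", "position", "from", "to"])
        for row in rows:
            writer.writerow(row)
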