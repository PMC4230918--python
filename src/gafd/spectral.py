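"""Power spectra and the alignment-free distance between DNA signals.

Signals derived from sequences of different length are zero-padded on the
right to the maximum length in the set before the DFT, so every spectrum in
one comparison lives on the same frequency grid.  The distance between two
sequences is the mean squared error between the two power spectra
(``|DFT|**2`` over all N bins).  The distance is symmetric, nonnegative and
zero on identical signals; the triangle inequality is *not* claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqsignal import DNASignal

__all__ = [
    "PowerSpectrum",
    "DistanceMatrix",
    "power_spectrum",
    "gafd_distance",
    "distance_matrix",
]


@dataclass(frozen=True)
class PowerSpectrum:
    """Magnitude-squared DFT of one zero-padded signal."""

    source_id: str
    pad_length: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distance matrix over labelled sequences."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(d < 0):
            raise ValueError("distance matrix entries must be >= 0")
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def to_phylip(self, path: str | Path) -> None:
        """Write a PHYLIP-style square distance matrix."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                vals = " ".join(f"{v:.10g}" for v in row)
                fh.write(f"{label} {vals}\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            lines = [ln for ln in (l.strip() for l in fh) if ln]
        n = int(lines[0])
        labels, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        return cls(labels, np.array(rows))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def power_spectrum(
    x: DNASignal,
    pad_length: int,
    remove_dc: bool = False,
    one_sided: bool = False,
) -> PowerSpectrum:
    """Magnitude-squared DFT of *x* right-padded with zeros to *pad_length*.

    ``remove_dc`` subtracts the signal mean before the transform;
    ``one_sided`` keeps only bins ``0 .. floor(N/2)``.  Both default off.
    """
    v = np.asarray(x.values, dtype=float)
    if pad_length < v.size:
        raise ValueError(
            f"pad_length {pad_length} < signal length {v.size} for "
            f"{x.source_id!r}"
        )
    if remove_dc:
        v = v - v.mean()
    spec = np.abs(np.fft.fft(v, n=pad_length)) ** 2
    if one_sided:
        spec = spec[: pad_length // 2 + 1]
    return PowerSpectrum(x.source_id, pad_length, spec)


def gafd_distance(p: PowerSpectrum, q: PowerSpectrum) -> float:
    """Mean squared error between two power spectra on a common grid."""
    if p.pad_length != q.pad_length or p.values.size != q.values.size:
        raise ValueError(
            f"pad lengths differ ({p.pad_length} vs {q.pad_length}); apply "
            "set-wide zero padding first"
        )
    diff = p.values - q.values
    return float(np.mean(diff * diff))


def distance_matrix(
    signals: list[DNASignal],
    remove_dc: bool = False,
    one_sided: bool = False,
) -> DistanceMatrix:
    """All-pairs alignment-free distances over a set of signals.

    The common pad length is the maximum signal length in the set.
    """
    if len(signals) < 2:
        raise ValueError("need at least 2 signals")
    ids = [s.source_id for s in signals]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    pad = max(len(s) for s in signals)
    spectra = [
        power_spectrum(s, pad, remove_dc=remove_dc, one_sided=one_sided)
        for s in signals
    ]
    n = len(signals)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = gafd_distance(spectra[i], spectra[j])
    return DistanceMatrix(ids, d)
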