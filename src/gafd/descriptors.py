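"""DSP similarity descriptors for pairs of DNA signals.

Three complementary pairwise measures place a signal pair in a 3-D
similarity space:

* **correlation** — absolute Pearson correlation in [0, 1]; the sign is
  discarded because only the degree of (anti)correlation matters.
* **coherence** — mean magnitude-squared coherence over a frequency grid,
  with the spectral density matrix estimated from a bivariate
  autoregressive (AR) model of the two channels.
* **derivative** — mean absolute difference between the first finite
  differences of the two signals; 0 means identical trend.  Differencing
  removes the constant vertical offset that a substitution imprints on a
  doublet signal, so this descriptor responds to shape changes (indels)
  rather than level shifts.

A perfectly matching pair sits at (1, 1, 0).  The module also implements
the signal-dictionary domain search: a reference signal is tiled into
non-overlapping fragments, and each fragment is slid across a target
signal; offsets where correlation and coherence exceed their thresholds
and the derivative descriptor falls below its cap are reported as hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqsignal import DNASignal

__all__ = [
    "ARModel",
    "DescriptorPoint",
    "DictionaryEntry",
    "MatchThresholds",
    "correlation_descriptor",
    "fit_bivariate_ar",
    "ar_spectral_matrix",
    "coherence_descriptor",
    "derivative_descriptor",
    "similarity_point",
    "build_dictionary",
    "dictionary_search",
]

DEFAULT_AR_ORDER = 10
DEFAULT_NFREQ = 128


@dataclass(frozen=True)
class ARModel:
    """A fitted bivariate autoregressive model.

    ``coef[k]`` is the 2x2 coefficient matrix at lag ``k + 1``;
    ``sigma`` is the 2x2 innovation covariance.
    """

    order: int
    coef: np.ndarray  # shape (order, 2, 2)
    sigma: np.ndarray  # shape (2, 2)
    nobs: int


@dataclass(frozen=True)
class DescriptorPoint:
    """One signal pair's coordinates in the similarity space."""

    id1: str
    id2: str
    corr: float
    coh: float
    deriv: float

    def as_array(self) -> np.ndarray:
        return np.array([self.corr, self.coh, self.deriv])


@dataclass(frozen=True)
class DictionaryEntry:
    """One non-overlapping fragment of a reference signal."""

    source_id: str
    index: int
    offset: int  # 0-based start in the reference signal
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def entry_id(self) -> str:
        return f"{self.source_id}.{self.index}"


@dataclass(frozen=True)
class MatchThresholds:
    """Acceptance thresholds of the dictionary search (conjunction of three)."""

    corr_min: float = 0.9
    coh_min: float = 0.9
    deriv_max: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.corr_min <= 1 and 0 <= self.coh_min <= 1):
            raise ValueError("corr_min and coh_min must lie in [0, 1]")
        if self.deriv_max < 0:
            raise ValueError("deriv_max must be >= 0")


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv = np.asarray(x.values if isinstance(x, DNASignal) else x, dtype=float)
    yv = np.asarray(y.values if isinstance(y, DNASignal) else y, dtype=float)
    return xv, yv


def _truncate_to_common(xv: np.ndarray, yv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = min(xv.size, yv.size)
    return xv[:n], yv[:n]


def correlation_descriptor(x, y) -> float:
    """Absolute Pearson correlation of two equal-length signals."""
    xv, yv = _pair(x, y)
    if xv.size != yv.size:
        raise ValueError(
            f"length mismatch ({xv.size} vs {yv.size}); window or truncate first"
        )
    if xv.size < 2:
        raise ValueError("need at least 2 samples")
    sx, sy = np.std(xv), np.std(yv)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a zero-variance signal")
    if np.array_equal(xv, yv):
        return 1.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(min(abs(r), 1.0))


def fit_bivariate_ar(x, y, p: int = DEFAULT_AR_ORDER) -> ARModel:
    """Conditional least-squares fit of a bivariate AR(p) model.

    Regresses each sample vector on its ``p`` predecessors (no intercept;
    channels are mean-centred first).  ``p`` is guarded to at most a tenth
    of the series length so the regression stays well-conditioned.
    """
    xv, yv = _pair(x, y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch ({xv.size} vs {yv.size})")
    n = xv.size
    if p < 1:
        raise ValueError(f"AR order must be >= 1, got {p}")
    if p > n // 10:
        raise ValueError(
            f"AR order {p} too large for series length {n} (max {n // 10})"
        )
    z = np.column_stack([xv - xv.mean(), yv - yv.mean()])  # (n, 2)
    # regressor rows: [z[t-1], z[t-2], ..., z[t-p]] flattened
    rows = n - p
    regressors = np.empty((rows, 2 * p))
    for k in range(1, p + 1):
        regressors[:, 2 * (k - 1) : 2 * k] = z[p - k : n - k]
    response = z[p:]
    beta, _, rank, _ = np.linalg.lstsq(regressors, response, rcond=None)
    if rank < 2 * p:
        raise np.linalg.LinAlgError(
            f"rank-deficient AR regression (rank {rank} < {2 * p}); "
            "try a smaller order"
        )
    resid = response - regressors @ beta
    dof = max(rows - 2 * p, 1)
    sigma = resid.T @ resid / dof
    coef = np.stack(
        [beta[2 * (k - 1) : 2 * k].T for k in range(1, p + 1)]
    )  # (p, 2, 2)
    return ARModel(order=p, coef=coef, sigma=sigma, nobs=rows)


def ar_spectral_matrix(model: ARModel, freqs: np.ndarray) -> np.ndarray:
    """Spectral density matrices S(f) = H(f) Σ H(f)* of a bivariate AR model.

    ``H(f) = (I - Σ_k A_k e^{-i 2π f k})^{-1}``; returns shape
    ``(len(freqs), 2, 2)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    lags = np.arange(1, model.order + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * lags[None, :])  # (F, p)
    a_f = np.tensordot(phase, model.coef, axes=([1], [0]))  # (F, 2, 2)
    eye = np.eye(2)
    inv_h = eye[None, :, :] - a_f
    h = np.linalg.inv(inv_h)
    sigma = model.sigma
    return h @ sigma[None, :, :] @ np.conjugate(np.swapaxes(h, 1, 2))


def coherence_descriptor(
    x,
    y,
    p: int = DEFAULT_AR_ORDER,
    nfreq: int = DEFAULT_NFREQ,
) -> float:
    """Mean magnitude-squared coherence of a signal pair from an AR fit.

    The coherence |S_xy|^2 / (S_xx S_yy) is evaluated on ``nfreq`` equally
    spaced frequencies in (0, 0.5] cycles/sample and averaged.  An exactly
    identical pair short-circuits to 1; a singular innovation covariance is
    regularised by a small diagonal load (1e-8 x trace).
    """
    xv, yv = _pair(x, y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch ({xv.size} vs {yv.size})")
    if np.array_equal(xv, yv):
        return 1.0
    model = fit_bivariate_ar(xv, yv, p)
    sigma = model.sigma
    load = 1e-8 * max(np.trace(sigma), np.finfo(float).tiny)
    model = ARModel(model.order, model.coef, sigma + load * np.eye(2), model.nobs)
    freqs = np.arange(1, nfreq + 1) / (2.0 * nfreq)  # (0, 0.5]
    s = ar_spectral_matrix(model, freqs)
    sxx = np.real(s[:, 0, 0])
    syy = np.real(s[:, 1, 1])
    denom = sxx * syy
    ok = denom > np.finfo(float).tiny
    if not np.any(ok):
        raise ValueError("auto-spectra numerically zero at every frequency")
    if not np.all(ok):
        warnings.warn(
            f"{np.count_nonzero(~ok)} frequencies excluded (zero auto-spectrum)",
            stacklevel=2,
        )
    coh = np.abs(s[ok, 0, 1]) ** 2 / denom[ok]
    return float(np.clip(np.mean(coh), 0.0, 1.0))


def derivative_descriptor(x, y) -> float:
    """Mean absolute difference of first differences; 0 = identical trend."""
    xv, yv = _pair(x, y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch ({xv.size} vs {yv.size})")
    if xv.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean(np.abs(np.diff(xv) - np.diff(yv))))


def similarity_point(
    x,
    y,
    p: int = DEFAULT_AR_ORDER,
    nfreq: int = DEFAULT_NFREQ,
    truncate: bool = True,
) -> DescriptorPoint:
    """All three descriptors for one pair of signals.

    If lengths differ (the indel case) and ``truncate`` is set, descriptors
    are computed on the common-length prefix.
    """
    xv, yv = _pair(x, y)
    if truncate:
        xv, yv = _truncate_to_common(xv, yv)
    id1 = x.source_id if isinstance(x, DNASignal) else "x"
    id2 = y.source_id if isinstance(y, DNASignal) else "y"
    return DescriptorPoint(
        id1=id1,
        id2=id2,
        corr=correlation_descriptor(xv, yv),
        coh=coherence_descriptor(xv, yv, p=p, nfreq=nfreq),
        deriv=derivative_descriptor(xv, yv),
    )


def build_dictionary(signal: DNASignal, fragment_len: int = 100) -> list[DictionaryEntry]:
    """Tile a reference signal into non-overlapping fragments, left to right.

    A trailing remainder shorter than ``fragment_len`` is discarded.
    """
    if fragment_len < 2:
        raise ValueError("fragment length must be >= 2")
    v = np.asarray(signal.values, dtype=float)
    entries = []
    for idx, start in enumerate(range(0, v.size - fragment_len + 1, fragment_len)):
        entries.append(
            DictionaryEntry(
                source_id=signal.source_id,
                index=idx,
                offset=start,
                values=v[start : start + fragment_len],
            )
        )
    return entries


def dictionary_search(
    dictionary: list[DictionaryEntry],
    target: DNASignal,
    thresholds: MatchThresholds | None = None,
    p: int = DEFAULT_AR_ORDER,
    nfreq: int = DEFAULT_NFREQ,
) -> list[tuple[str, int]]:
    """Slide each dictionary fragment over a target signal and report hits.

    A hit at offset ``o`` requires corr > corr_min, coh > coh_min and
    deriv < deriv_max between the fragment and ``target[o : o + W]``.
    Correlation and derivative are screened first; the (costlier) AR
    coherence is only evaluated at offsets that survive both — the hit set
    is unchanged because acceptance is a conjunction.  Fragments longer
    than the target are skipped with a warning.
    """
    thresholds = thresholds or MatchThresholds()
    t = np.asarray(target.values, dtype=float)
    hits: list[tuple[str, int]] = []
    for entry in dictionary:
        w = entry.values.size
        if w > t.size:
            warnings.warn(
                f"fragment {entry.entry_id} (length {w}) longer than target "
                f"{target.source_id!r} (length {t.size}); skipped",
                stacklevel=2,
            )
            continue
        frag = entry.values
        dfrag = np.diff(frag)
        n_off = t.size - w + 1
        windows = np.lib.stride_tricks.sliding_window_view(t, w)
        # vectorised screening descriptors over all offsets
        dwin = np.diff(windows, axis=1)
        deriv = np.mean(np.abs(dwin - dfrag[None, :]), axis=1)
        fc = frag - frag.mean()
        wc = windows - windows.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(fc) * np.linalg.norm(wc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(wc @ fc) / denom
        corr = np.nan_to_num(corr, nan=0.0)
        candidate = (corr > thresholds.corr_min) & (deriv < thresholds.deriv_max)
        for off in np.nonzero(candidate)[0][:n_off]:
            coh = coherence_descriptor(frag, windows[off], p=p, nfreq=nfreq)
            if coh > thresholds.coh_min:
                hits.append((entry.entry_id, int(off)))
    return hits
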