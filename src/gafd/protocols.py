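"""End-to-end pipelines and the canonical synthetic experiments.

``sequences_to_signals`` is the standard front half of the method: doublet
mapping at a chosen window magnitude followed (by default) by wavelet
denoising.  On top of it sit the three study protocols used throughout the
test battery:

* ``substitution_distance_profile`` — distance from a random template to
  mutants carrying 1/3/5/10 cumulative substitutions; the distance should
  grow with the substitution count.
* ``similarity_space_experiment`` — exhaustive change neighborhoods of a
  short template placed in the 3-D descriptor space; more changes scatter
  points farther from the perfect-match corner (1, 1, 0), and indels
  separate from substitutions along the correlation and derivative axes.
* ``dictionary_assay`` — the sliding-window domain search of reference
  fragments inside target signals.

Descriptors are computed on raw (un-denoised) doublet signals: the
descriptors are local shape measures, and thresholding would blur the very
perturbations they are meant to resolve.  Denoising stays in the distance
pipeline, where it suppresses spectrum noise before the MSE comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoise import DenoiseConfig, denoise_signal
from .descriptors import (
    DescriptorPoint,
    MatchThresholds,
    build_dictionary,
    dictionary_search,
    similarity_point,
)
from .seqsignal import DNASequence, DNASignal, DoubletTable, MappingConfig, map_sequence
from .spectral import distance_matrix
from .synthio import (
    cumulative_substitution_series,
    exhaustive_neighborhood,
    random_sequence,
)

__all__ = [
    "sequences_to_signals",
    "substitution_distance_profile",
    "similarity_space_experiment",
    "SimilaritySpaceResult",
    "dictionary_assay",
]


def sequences_to_signals(
    seqs: list[DNASequence],
    alpha: int = 3,
    combiner: str = "sum",
    denoise: bool = True,
    table: DoubletTable | None = None,
    denoise_cfg: DenoiseConfig | None = None,
) -> list[DNASignal]:
    """Map sequences to doublet signals and optionally denoise them."""
    cfg = MappingConfig(alpha=alpha, combiner=combiner)
    signals = [map_sequence(s, table=table, cfg=cfg) for s in seqs]
    if denoise:
        signals = [denoise_signal(s, denoise_cfg) for s in signals]
    return signals


def substitution_distance_profile(
    length: int = 10_000,
    counts: tuple[int, ...] = (1, 3, 5, 10),
    alpha: int = 3,
    seed: int = 0,
    denoise: bool = True,
) -> dict[int, float]:
    """Template-to-mutant distances for cumulative substitution counts.

    Returns ``{count: distance}`` for one random template under one seed.
    """
    rng = np.random.default_rng(seed)
    template = random_sequence(length, rng)
    mutants = cumulative_substitution_series(template, counts, rng)
    signals = sequences_to_signals([template] + mutants, alpha=alpha, denoise=denoise)
    dm = distance_matrix(signals)
    return {
        c: dm[template.id, mut.id] for c, mut in zip(counts, mutants)
    }


@dataclass(frozen=True)
class SimilaritySpaceResult:
    """Descriptor points of one exhaustive-neighborhood experiment,
    grouped by mutation kind and change count."""

    points: dict[tuple[str, int], list[DescriptorPoint]]

    def cloud(self, kind: str, changes: int | None = None) -> np.ndarray:
        """(n, 3) array of (corr, coh, deriv) rows for one group."""
        rows = []
        for (k, c), pts in self.points.items():
            if k == kind and (changes is None or c == changes):
                rows.extend(p.as_array() for p in pts)
        return np.array(rows)

    def mean_distance_from_ideal(self, kind: str, changes: int) -> float:
        """Mean Euclidean distance from the perfect-match corner (1, 1, 0)."""
        cloud = self.cloud(kind, changes)
        ideal = np.array([1.0, 1.0, 0.0])
        return float(np.mean(np.linalg.norm(cloud - ideal, axis=1)))


def similarity_space_experiment(
    length: int = 20,
    max_changes: int = 3,
    kinds: tuple[str, ...] = ("substitution",),
    alpha: int = 3,
    seed: int = 0,
    ar_order: int = 10,
    nfreq: int = 128,
) -> SimilaritySpaceResult:
    """Exhaustive change neighborhoods of one template in descriptor space.

    Each variant within ``max_changes`` changes of each kind is compared to
    the template with the three descriptors.  The AR order is capped at a
    tenth of the common signal length (minimum 1), as required for short
    signals.  Variants whose common-length prefix is degenerate (constant)
    are skipped.
    """
    rng = np.random.default_rng(seed)
    template = random_sequence(length, rng)
    cfg = MappingConfig(alpha=alpha)
    t_sig = map_sequence(template, cfg=cfg)
    points: dict[tuple[str, int], list[DescriptorPoint]] = {}
    for variant, summary in exhaustive_neighborhood(template, max_changes, kinds):
        v_sig = map_sequence(variant, cfg=cfg)
        n_common = min(len(t_sig), len(v_sig))
        p = max(1, min(ar_order, n_common // 10))
        try:
            pt = similarity_point(t_sig, v_sig, p=p, nfreq=nfreq)
        except ValueError:
            continue  # zero-variance prefix; cannot place in the space
        key = (summary["kind"], summary["changes"])
        points.setdefault(key, []).append(pt)
    return SimilaritySpaceResult(points)


def dictionary_assay(
    reference: DNASignal,
    targets: list[DNASignal],
    fragment_len: int = 100,
    thresholds: MatchThresholds | None = None,
    ar_order: int = 10,
    nfreq: int = 128,
) -> dict[str, list[tuple[str, int]]]:
    """Search reference-signal fragments in each target signal.

    Returns ``{target id: [(fragment id, offset), ...]}`` at the given
    acceptance thresholds.
    """
    dictionary = build_dictionary(reference, fragment_len)
    return {
        t.source_id: dictionary_search(
            dictionary, t, thresholds, p=ar_order, nfreq=nfreq
        )
        for t in targets
    }
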