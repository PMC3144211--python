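"""From fused score profiles to residue labels and helix intervals.

Because helix-enriched residues carry *negative* index values, a position is
called transmembrane when its fused score falls *below* the local threshold.
The threshold may be a single constant (classically 0) or a piecewise
profile encoded by a :class:`~tmhseg.ga_optimizer.ThresholdChromosome`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .index_model import IndexTable, compositional_index
from .io_formats import Interval, ProteinRecord
from .profiling import ResidueProfile, build_profile

__all__ = [
    "Prediction",
    "PredictOptions",
    "call_residues",
    "labels_to_segments",
    "segments_to_labels",
    "merge_segments",
    "predict",
]


@dataclass
class Prediction:
    """Residue labels (True = transmembrane) and derived helix intervals."""

    protein_id: str
    labels: np.ndarray
    segments: List[Interval]


def call_residues(profile: ResidueProfile, chromosome) -> np.ndarray:
    """Label position j transmembrane iff fused_j < threshold at j.

    ``chromosome`` is anything exposing ``length`` and ``thresholds() ->
    per-position array`` (see :class:`~tmhseg.ga_optimizer.ThresholdChromosome`).
    """
    if chromosome.length != len(profile):
        raise ValueError(
            f"chromosome length {chromosome.length} != profile length {len(profile)}"
        )
    return profile.fused < chromosome.thresholds()


def labels_to_segments(labels: Sequence[bool], min_length: int = 5) -> List[Interval]:
    """Maximal runs of True as 1-based inclusive intervals, length-filtered.

    Runs shorter than ``min_length`` are dropped; ``min_length`` of 1
    disables filtering.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    labels = np.asarray(labels, dtype=bool)
    padded = np.concatenate(([False], labels, [False])).astype(int)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1) + 1  # 1-based
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s + 1 >= min_length]


def segments_to_labels(segments: Sequence[Interval], length: int) -> np.ndarray:
    """Inverse of :func:`labels_to_segments` for valid, gap-separated intervals."""
    labels = np.zeros(length, dtype=bool)
    for start, end in segments:
        if start < 1 or end < start or end > length:
            raise ValueError(f"interval ({start}, {end}) out of range for length {length}")
        labels[start - 1 : end] = True
    return labels


def merge_segments(segments: Sequence[Interval], max_gap: int) -> List[Interval]:
    """Join consecutive intervals separated by at most ``max_gap`` residues."""
    merged: List[Interval] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(tuple(seg))
    return merged


@dataclass
class PredictOptions:
    """Knobs for the end-to-end single-protein pipeline.

    ``mode`` is ``"fixed"`` (one constant threshold, default 0), ``"ga"``
    (per-protein piecewise threshold optimized against the record's own
    reference segments — the benchmark protocol), or ``"template"`` (apply a
    pre-fitted threshold template rescaled to this protein's length).
    """

    w_min: int = 5
    w_max: int = 19
    min_length: int = 5
    mode: str = "fixed"
    threshold: float = 0.0
    ga_config: Optional[object] = None
    template: Optional[object] = None
    merge_gap: int = 0
    window_weights: Optional[Sequence[float]] = None


def predict(record: ProteinRecord, table: IndexTable, options: Optional[PredictOptions] = None) -> Prediction:
    """Full pipeline: index -> windowed profile -> threshold -> segments."""
    from . import ga_optimizer  # local import to avoid a module cycle

    opts = options or PredictOptions()
    raw = compositional_index(record.sequence, table)
    profile = build_profile(record.id, raw, w_min=opts.w_min, w_max=opts.w_max, weights=opts.window_weights)
    length = len(record)

    if opts.mode == "fixed":
        chromosome = ga_optimizer.ThresholdChromosome(((opts.threshold, length),), length)
    elif opts.mode == "ga":
        if record.reference_segments is None:
            raise ValueError(f"record {record.id!r}: GA mode needs reference segments")
        config = opts.ga_config or ga_optimizer.GAConfig()
        result = ga_optimizer.run_ga(profile, record.reference_segments, config)
        chromosome = result.best_chromosome
    elif opts.mode == "template":
        if opts.template is None:
            raise ValueError("template mode needs a fitted template chromosome")
        chromosome = ga_optimizer.scale_chromosome(opts.template, length)
    else:
        raise ValueError(f"unknown prediction mode {opts.mode!r}")

    labels = call_residues(profile, chromosome)
    segments = labels_to_segments(labels, min_length=opts.min_length)
    if opts.merge_gap > 0:
        segments = merge_segments(segments, opts.merge_gap)
    return Prediction(protein_id=record.id, labels=labels, segments=segments)
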