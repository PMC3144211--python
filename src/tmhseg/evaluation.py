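"""Segment- and residue-level scoring of helix predictions.

Five measures are computed against reference annotations:

* ``Q_htm`` — fraction of known helices correctly predicted, where a known
  helix counts as correct if a predicted helix shares at least
  ``min_overlap`` residues with it (9 by default; 5 corresponds to roughly
  one helical turn).
* ``Q_p`` — fraction of proteins whose every known helix is correct.
* ``Q_AA`` — fraction of residues with the correct label; also the GA's
  fitness function.
* N-score / C-score — for each matched helix pair, the absolute offset (in
  residues) between predicted and known start / end; 0 means exact ends.
* Sensitivity / specificity — residue-level TP/(TP+FN) and TN/(TN+FP),
  pooled over all proteins by default.

Segment correctness is counted permissively by default (``counting =
"overlap"``): a known helix is correct as soon as *any* predicted segment
overlaps it sufficiently, the convention under which segment recall and
residue-level specificity can legitimately diverge (a prediction that runs
through a short loop still recovers both flanking helices).  The stricter
``counting="paired"`` variant requires a one-to-one greedy pairing by
descending overlap (ties broken toward the leftmost known, then leftmost
predicted helix); that same pairing always underlies the N-/C-scores and
the unmatched-segment counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import Interval
from .segmentation import segments_to_labels

__all__ = [
    "SegmentMatch",
    "ProteinScore",
    "EvaluationReport",
    "match_segments",
    "overlap_length",
    "q_htm",
    "q_p",
    "q_aa",
    "n_c_scores",
    "sensitivity_specificity",
    "evaluate",
]


def overlap_length(a: Interval, b: Interval) -> int:
    """Number of residues shared by two 1-based inclusive intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


@dataclass(frozen=True)
class SegmentMatch:
    pred_index: int
    known_index: int
    overlap: int


def match_segments(
    predicted: Sequence[Interval],
    known: Sequence[Interval],
    min_overlap: int = 9,
) -> List[SegmentMatch]:
    """Greedy one-to-one pairing of predicted and known helices by overlap.

    All pairs with positive overlap are candidates; pairs are accepted in
    order of descending overlap (ties: leftmost known, then leftmost
    predicted) while both members are unused.  ``min_overlap`` does not
    restrict the pairing itself — it is the correctness cut-off applied by
    the callers — but must still be >= 1.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    candidates = []
    for ki, kseg in enumerate(known):
        for pi, pseg in enumerate(predicted):
            ov = overlap_length(pseg, kseg)
            if ov > 0:
                candidates.append((-ov, kseg[0], pseg[0], pi, ki))
    candidates.sort()
    used_pred, used_known = set(), set()
    matches: List[SegmentMatch] = []
    for neg_ov, _, _, pi, ki in candidates:
        if pi in used_pred or ki in used_known:
            continue
        used_pred.add(pi)
        used_known.add(ki)
        matches.append(SegmentMatch(pred_index=pi, known_index=ki, overlap=-neg_ov))
    return sorted(matches, key=lambda m: m.known_index)


def _correct_known(predicted, known, min_overlap, counting: str = "overlap") -> int:
    if counting == "overlap":
        return sum(
            any(overlap_length(pseg, kseg) >= min_overlap for pseg in predicted)
            for kseg in known
        )
    if counting == "paired":
        return sum(m.overlap >= min_overlap for m in match_segments(predicted, known, min_overlap))
    raise ValueError(f"unknown counting mode {counting!r}")


def q_htm(
    predictions: Mapping[str, Sequence[Interval]],
    references: Mapping[str, Sequence[Interval]],
    min_overlap: int = 9,
    counting: str = "overlap",
) -> float:
    """Pooled fraction of known helices correctly predicted."""
    correct = total = 0
    for rid, known in references.items():
        total += len(known)
        correct += _correct_known(predictions.get(rid, ()), known, min_overlap, counting)
    if total == 0:
        raise ValueError("no known segments to score")
    return correct / total


def q_p(
    predictions: Mapping[str, Sequence[Interval]],
    references: Mapping[str, Sequence[Interval]],
    min_overlap: int = 9,
    strict: bool = False,
    counting: str = "overlap",
) -> float:
    """Fraction of proteins whose every known helix is correct.

    A protein with no known helices counts as correct unless ``strict``;
    ``strict`` additionally requires that no predicted helix goes unmatched
    (under the greedy one-to-one pairing).
    """
    if not references:
        raise ValueError("no proteins to score")
    good = 0
    for rid, known in references.items():
        predicted = predictions.get(rid, ())
        all_correct = _correct_known(predicted, known, min_overlap, counting) == len(known)
        if strict:
            matches = match_segments(predicted, known, min_overlap) if known else []
            matched_pred = {m.pred_index for m in matches if m.overlap >= min_overlap}
            all_correct = all_correct and len(matched_pred) == len(predicted)
        good += all_correct
    return good / len(references)


def q_aa(predicted: Sequence[Interval], known: Sequence[Interval], length: int) -> float:
    """Fraction of residues labeled correctly for one protein."""
    pred = segments_to_labels(predicted, length)
    ref = segments_to_labels(known, length)
    return float(np.mean(pred == ref))


def n_c_scores(pred: Interval, known: Interval) -> Tuple[int, int]:
    """Absolute start/end offsets of a matched helix pair, in residues."""
    return abs(pred[0] - known[0]), abs(pred[1] - known[1])


def _confusion(
    predictions: Mapping[str, Sequence[Interval]],
    references: Mapping[str, Sequence[Interval]],
    lengths: Mapping[str, int],
) -> Tuple[int, int, int, int]:
    tp = tn = fp = fn = 0
    for rid, known in references.items():
        length = lengths[rid]
        pred = segments_to_labels(predictions.get(rid, ()), length)
        ref = segments_to_labels(known, length)
        tp += int(np.sum(pred & ref))
        tn += int(np.sum(~pred & ~ref))
        fp += int(np.sum(pred & ~ref))
        fn += int(np.sum(~pred & ref))
    return tp, tn, fp, fn


def sensitivity_specificity(
    predictions: Mapping[str, Sequence[Interval]],
    references: Mapping[str, Sequence[Interval]],
    lengths: Mapping[str, int],
    per_protein: bool = False,
) -> Tuple[Optional[float], Optional[float]]:
    """Residue-level Sn = TP/(TP+FN), Sp = TN/(TN+FP).

    Pooled over all residues by default; with ``per_protein`` the rates are
    averaged over proteins (undefined proteins skipped).  A rate with an
    empty denominator is returned as None.
    """
    if per_protein:
        sns, sps = [], []
        for rid in references:
            sn, sp = sensitivity_specificity(
                {rid: predictions.get(rid, ())}, {rid: references[rid]}, lengths
            )
            if sn is not None:
                sns.append(sn)
            if sp is not None:
                sps.append(sp)
        return (float(np.mean(sns)) if sns else None, float(np.mean(sps)) if sps else None)
    tp, tn, fp, fn = _confusion(predictions, references, lengths)
    sn = tp / (tp + fn) if tp + fn > 0 else None
    sp = tn / (tn + fp) if tn + fp > 0 else None
    return sn, sp


@dataclass
class ProteinScore:
    q_aa: float
    correct_segments: int
    total_segments: int
    n_scores: List[int]
    c_scores: List[int]
    unmatched_known: int
    unmatched_predicted: int


@dataclass
class EvaluationReport:
    """Pooled metrics plus a per-protein breakdown."""

    n_proteins: int
    q_htm: float
    q_p: float
    q_aa: float
    mean_n_score: Optional[float]
    mean_c_score: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    tn: int
    fp: int
    fn: int
    correct_segments: int
    total_segments: int
    unmatched_known: int
    unmatched_predicted: int
    min_overlap: int
    per_protein: Dict[str, ProteinScore] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "n_proteins", "q_htm", "q_p", "q_aa", "mean_n_score", "mean_c_score",
                "sensitivity", "specificity", "tp", "tn", "fp", "fn",
                "correct_segments", "total_segments",
                "unmatched_known", "unmatched_predicted", "min_overlap",
            )
        }
        out["per_protein"] = {rid: vars(ps) for rid, ps in self.per_protein.items()}
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate(
    predictions: Mapping[str, Sequence[Interval]],
    references: Mapping[str, Sequence[Interval]],
    lengths: Mapping[str, int],
    min_overlap: int = 9,
    strict: bool = False,
    counting: str = "overlap",
) -> EvaluationReport:
    """Score a prediction set against references; pooled over residues.

    ``lengths`` maps each reference id to its sequence length (needed for
    residue-level rates).  N/C-scores are averaged over greedily matched
    pairs only; unmatched known helices are counted separately.
    """
    if not references:
        raise ValueError("no proteins to evaluate")
    per_protein: Dict[str, ProteinScore] = {}
    all_n, all_c = [], []
    for rid, known in references.items():
        predicted = list(predictions.get(rid, ()))
        matches = match_segments(predicted, known, min_overlap)
        correct = _correct_known(predicted, known, min_overlap, counting)
        n_scores, c_scores = [], []
        for m in matches:
            n, c = n_c_scores(predicted[m.pred_index], known[m.known_index])
            n_scores.append(n)
            c_scores.append(c)
        matched_pred = {m.pred_index for m in matches}
        per_protein[rid] = ProteinScore(
            q_aa=q_aa(predicted, known, lengths[rid]),
            correct_segments=correct,
            total_segments=len(known),
            n_scores=n_scores,
            c_scores=c_scores,
            unmatched_known=len(known) - len(matches),
            unmatched_predicted=len(predicted) - len(matched_pred),
        )
        all_n.extend(n_scores)
        all_c.extend(c_scores)

    tp, tn, fp, fn = _confusion(predictions, references, lengths)
    total_residues = tp + tn + fp + fn
    total_segments = sum(ps.total_segments for ps in per_protein.values())
    correct_segments = sum(ps.correct_segments for ps in per_protein.values())
    sn, sp = sensitivity_specificity(predictions, references, lengths)
    return EvaluationReport(
        n_proteins=len(references),
        q_htm=correct_segments / total_segments if total_segments else float("nan"),
        q_p=q_p(predictions, references, min_overlap, strict=strict, counting=counting),
        q_aa=(tp + tn) / total_residues if total_residues else float("nan"),
        mean_n_score=float(np.mean(all_n)) if all_n else None,
        mean_c_score=float(np.mean(all_c)) if all_c else None,
        sensitivity=sn,
        specificity=sp,
        tp=tp, tn=tn, fp=fp, fn=fn,
        correct_segments=correct_segments,
        total_segments=total_segments,
        unmatched_known=sum(ps.unmatched_known for ps in per_protein.values()),
        unmatched_predicted=sum(ps.unmatched_predicted for ps in per_protein.values()),
        min_overlap=min_overlap,
        per_protein=per_protein,
    )
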