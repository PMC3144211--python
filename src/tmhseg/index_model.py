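"""Training and application of the per-residue compositional index.

The model contrasts residue usage inside transmembrane helices against the
rest of the chain.  From a pool of annotated proteins two residue pools are
extracted (helix and non-helix); each amino acid *i* gets a log-ratio

    lambda_i = ln(f_non,i / f_tmh,i)

so that helix-enriched residues score negative (the familiar orientation of
linker/propensity indices such as DomCut).  For a query sequence the index
is combined with the query's own amino-acid composition, in percent:

    I_j = AAC(a_j) * lambda_(a_j)

giving one value per residue.  Downstream smoothing and segmentation live
in :mod:`tmhseg.profiling` and :mod:`tmhseg.segmentation`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np

from .io_formats import AMINO_ACIDS, MASK_CHAR, Dataset, FormatError

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class IndexTable:
    """Trained model: pool frequencies and the per-amino-acid index.

    ``f_tmh`` and ``f_non`` are relative frequencies over the 20 standard
    amino acids (each sums to 1); ``lam`` holds lambda_i.  Helix-enriched
    residues have lambda_i < 0.
    """

    f_tmh: Dict[str, float]
    f_non: Dict[str, float]
    lam: Dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (("f_tmh", self.f_tmh), ("f_non", self.f_non), ("lam", self.lam)):
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise FormatError(f"{name}: missing amino acids {sorted(missing)}")
        for name, freqs in (("f_tmh", self.f_tmh), ("f_non", self.f_non)):
            total = sum(freqs[a] for a in AMINO_ACIDS)
            if any(freqs[a] < 0 for a in AMINO_ACIDS) or abs(total - 1.0) > _SUM_TOL:
                raise FormatError(f"{name}: frequencies must be non-negative and sum to 1")
        if not all(math.isfinite(self.lam[a]) for a in AMINO_ACIDS):
            raise FormatError("lambda values must be finite")

    def lambda_array(self) -> np.ndarray:
        return np.array([self.lam[a] for a in AMINO_ACIDS])


def extract_pools(dataset: Dataset) -> Tuple[Counter, Counter]:
    """Split every residue of an annotated dataset into helix / non-helix pools.

    Masked (``X``) positions are excluded from both pools.
    """
    tmh_pool: Counter = Counter()
    non_pool: Counter = Counter()
    missing = [rec.id for rec in dataset if rec.reference_segments is None]
    if missing:
        raise FormatError(f"records without annotations: {missing}")
    for rec in dataset:
        in_helix = np.zeros(len(rec), dtype=bool)
        for start, end in rec.reference_segments:
            in_helix[start - 1 : end] = True
        for ch, flag in zip(rec.sequence, in_helix):
            if ch == MASK_CHAR:
                continue
            (tmh_pool if flag else non_pool)[ch] += 1
    return tmh_pool, non_pool


def train_index(
    tmh_pool: Mapping[str, int],
    non_pool: Mapping[str, int],
    pseudocount: float = 1.0,
) -> IndexTable:
    """Estimate pool frequencies (with an additive pseudocount) and lambda.

    ``pseudocount`` is added to every amino-acid count before normalizing;
    the default of 1 keeps every frequency strictly positive so lambda is
    always finite.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    for name, pool in (("tmh", tmh_pool), ("non", non_pool)):
        if sum(pool.get(a, 0) for a in AMINO_ACIDS) == 0:
            raise ValueError(f"{name} pool is empty")
    if pseudocount == 0:
        for pool in (tmh_pool, non_pool):
            if any(pool.get(a, 0) == 0 for a in AMINO_ACIDS):
                raise ValueError("zero count with pseudocount=0 would give infinite lambda")

    def _freqs(pool: Mapping[str, int]) -> Dict[str, float]:
        counts = {a: pool.get(a, 0) + pseudocount for a in AMINO_ACIDS}
        total = sum(counts.values())
        return {a: counts[a] / total for a in AMINO_ACIDS}

    f_tmh = _freqs(tmh_pool)
    f_non = _freqs(non_pool)
    lam = {a: math.log(f_non[a] / f_tmh[a]) for a in AMINO_ACIDS}
    return IndexTable(f_tmh=f_tmh, f_non=f_non, lam=lam)


def compute_aac(sequence: str) -> Dict[str, float]:
    """Amino-acid composition of one sequence, in percent (0-100).

    Masked positions are excluded from both the numerator and the effective
    length, so the 20 entries still sum to 100.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence)
    effective = len(sequence) - counts.get(MASK_CHAR, 0)
    if effective == 0:
        raise ValueError("sequence contains only masked residues")
    return {a: 100.0 * counts.get(a, 0) / effective for a in AMINO_ACIDS}


def compositional_index(sequence: str, table: IndexTable) -> np.ndarray:
    """Per-residue index values I_j = AAC(a_j) * lambda(a_j).

    The composition is taken from the query sequence itself.  Masked
    positions get 0.
    """
    aac = compute_aac(sequence)
    per_aa = {a: aac[a] * table.lam[a] for a in AMINO_ACIDS}
    per_aa[MASK_CHAR] = 0.0
    return np.array([per_aa[ch] for ch in sequence])


def write_index_table(table: IndexTable, path) -> None:
    """Write the model as plain text: ``aa<TAB>f_tmh<TAB>f_non<TAB>lambda``."""
    path = Path(path)
    lines = ["# amino_acid\tf_tmh\tf_non\tlambda"]
    for a in AMINO_ACIDS:
        lines.append(f"{a}\t{table.f_tmh[a]:.17g}\t{table.f_non[a]:.17g}\t{table.lam[a]:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_index_table(path) -> IndexTable:
    path = Path(path)
    f_tmh: Dict[str, float] = {}
    f_non: Dict[str, float] = {}
    lam: Dict[str, float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
            a = parts[0]
            if a not in AMINO_ACIDS:
                raise FormatError(f"{path}:{lineno}: unknown amino acid {a!r}")
            if a in lam:
                raise FormatError(f"{path}:{lineno}: duplicate row for {a!r}")
            try:
                f_tmh[a], f_non[a], lam[a] = (float(x) for x in parts[1:])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from None
    missing = set(AMINO_ACIDS) - set(lam)
    if missing:
        raise FormatError(f"{path}: missing rows for {sorted(missing)}")
    return IndexTable(f_tmh=f_tmh, f_non=f_non, lam=lam)
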