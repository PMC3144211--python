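"""Seeded generator of annotated membrane-protein-like sequences.

Each protein is an alternation of loop and helix blocks:

    loop - helix - loop - helix - ... - helix - loop

Helix lengths follow a discretized normal (mean 21, sd 5, truncated to
5..40 — the span observed for real transmembrane helices, including short
"half-TM" pore helices); loop lengths are geometric with mean 12 and
minimum 1, so very short inter-helix loops occur naturally.  Residues are
drawn i.i.d. within a block from a helix or loop composition; the defaults
enrich helices in hydrophobic residues (A, I, L, V, F, M, W) and loops in
charged/polar ones (D, E, K, R, N, Q, S, P), with a ``contrast`` knob that
interpolates both toward the uniform composition (0 = indistinguishable).

``hard_mode`` forces a fraction of the inter-helix loops down to 1-3
residues — the regime where a single fixed threshold merges adjacent
helices and a piecewise threshold is needed to split them.

With 1-14 helices per protein the generated chains span roughly 50-500
residues.  The generator makes no attempt at helical periodicity or real
structural physics; it exists to exercise training, optimization and
scoring end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .io_formats import AMINO_ACIDS, Dataset, ProteinRecord

HYDROPHOBIC = "AILVFMW"
CHARGED_POLAR = "DEKRNQSP"


def default_compositions(contrast: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    """Helix and loop residue compositions (aligned with AMINO_ACIDS order).

    At full contrast the helix simplex puts 65% of its mass on the seven
    hydrophobic residues and the loop simplex 60% on the eight
    charged/polar residues; ``contrast`` in [0, 1] linearly interpolates
    toward the uniform distribution, at which point the two are identical.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    uniform = np.full(20, 1 / 20)
    tmh = np.empty(20)
    loop = np.empty(20)
    for i, aa in enumerate(AMINO_ACIDS):
        tmh[i] = 0.65 / len(HYDROPHOBIC) if aa in HYDROPHOBIC else 0.35 / (20 - len(HYDROPHOBIC))
        loop[i] = 0.60 / len(CHARGED_POLAR) if aa in CHARGED_POLAR else 0.40 / (20 - len(CHARGED_POLAR))
    tmh = contrast * tmh + (1 - contrast) * uniform
    loop = contrast * loop + (1 - contrast) * uniform
    return tmh, loop


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 70
    helix_count_range: Tuple[int, int] = (1, 14)
    helix_length_mean: float = 21.0
    helix_length_sd: float = 5.0
    helix_length_bounds: Tuple[int, int] = (5, 40)
    loop_length_mean: float = 12.0
    loop_length_min: int = 1
    contrast: float = 1.0
    tmh_composition: Optional[np.ndarray] = None
    loop_composition: Optional[np.ndarray] = None
    hard_mode: bool = False
    short_loop_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.helix_count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid helix_count_range")
        lo, hi = self.helix_length_bounds
        if lo < 1 or hi < lo:
            raise ValueError("invalid helix_length_bounds")
        if self.loop_length_min < 1 or self.loop_length_mean < self.loop_length_min:
            raise ValueError("invalid loop length parameters")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


def _helix_length(spec: GeneratorSpec, rng: np.random.Generator) -> int:
    lo, hi = spec.helix_length_bounds
    while True:
        value = int(round(rng.normal(spec.helix_length_mean, spec.helix_length_sd)))
        if lo <= value <= hi:
            return value


def _loop_length(spec: GeneratorSpec, rng: np.random.Generator) -> int:
    # Geometric with support {min, min+1, ...} and the requested mean.
    extra_mean = spec.loop_length_mean - spec.loop_length_min + 1
    return spec.loop_length_min - 1 + int(rng.geometric(1.0 / extra_mean))


def generate_dataset(spec: GeneratorSpec, name: str = "synthetic") -> Dataset:
    """Generate an annotated dataset; deterministic for a given seed."""
    rng = np.random.default_rng(spec.rng_seed)
    if spec.tmh_composition is None or spec.loop_composition is None:
        tmh_comp, loop_comp = default_compositions(spec.contrast)
    else:
        tmh_comp = np.asarray(spec.tmh_composition, dtype=float)
        loop_comp = np.asarray(spec.loop_composition, dtype=float)
    for comp in (tmh_comp, loop_comp):
        if comp.shape != (20,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("compositions must be 20-vectors on the probability simplex")
    alphabet = np.array(list(AMINO_ACIDS))

    def _block(n: int, comp: np.ndarray) -> str:
        return "".join(alphabet[rng.choice(20, size=n, p=comp)])

    records = []
    for idx in range(spec.n_proteins):
        k = int(rng.integers(spec.helix_count_range[0], spec.helix_count_range[1] + 1))
        parts = []
        segments = []
        pos = 0
        for h in range(k + 1):
            if spec.hard_mode and 0 < h < k and rng.random() < spec.short_loop_fraction:
                loop_len = int(rng.integers(1, 4))
            else:
                loop_len = _loop_length(spec, rng)
            parts.append(_block(loop_len, loop_comp))
            pos += loop_len
            if h < k:
                helix_len = _helix_length(spec, rng)
                parts.append(_block(helix_len, tmh_comp))
                segments.append((pos + 1, pos + helix_len))
                pos += helix_len
        records.append(
            ProteinRecord(id=f"syn{idx:04d}", sequence="".join(parts), reference_segments=tuple(segments))
        )
    return Dataset(records=records, name=name)
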