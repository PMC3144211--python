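"""Published worked example: the light-harvesting complex beta chain
(PDB 1LGH, chain B).

The original description of this method walks through the first five
positions of the 1LGH:B 45-mer, multiplying each residue's composition (in
percent, from the 45-mer itself) by its trained index value and averaging
with a boundary-truncated window of size 5.  The printed index values cover
the six residue types occurring in positions 1-7 (A, E, R, S, L, G), which
is exactly what the window-5 averages at positions 2-5 need; positions of
other residue types are filled with 0 here and the published averages for
positions 2-5 are the reproducible fixture.

The published value for position 1 is inconsistent with its own printed
three-term formula (the formula evaluates to 3.8553, the printed result
4.1601 equals the position-2 four-term sum divided by 3), so position 1 is
excluded from the fixture.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .index_model import compute_aac
from .profiling import window_average

EXAMPLE_ID = "1LGH:B"
EXAMPLE_SEQUENCE = "AERSLSGLTEEEAIAVHDQFKTTFSAFIILAAVAHVLVWVWKPWF"

#: Trained index values as printed in the worked example.
EXAMPLE_LAMBDA: Dict[str, float] = {
    "A": -0.30841,
    "E": 1.472438,
    "R": 1.473881,
    "S": 0.137164,
    "L": -0.53791,
    "G": -0.07568,
}

#: Composition of the 45-mer, percent, as printed (3 decimals).
EXAMPLE_AAC: Dict[str, float] = {
    "A": 15.556,
    "E": 8.889,
    "R": 2.222,
    "S": 6.667,
    "L": 8.889,
    "G": 2.222,
}

#: Published window-5 averaged values, keyed by 1-based position.
EXAMPLE_WINDOW5: Dict[int, float] = {
    2: 3.120077848,
    3: 1.53976588,
    4: 2.68218555,
    5: 0.030853082,
}


def example_raw_index(use_printed_inputs: bool = True) -> np.ndarray:
    """Per-residue index products AAC x lambda for the example sequence.

    With ``use_printed_inputs`` the printed (rounded) composition values are
    used, matching the published arithmetic; otherwise the composition is
    recomputed from the sequence at full precision.  Residue types without
    a printed index value contribute 0 — positions 1-7 (A,E,R,S,L,S,G) are
    fully covered, which is all the window-5 averages at positions 2-5 see.
    """
    aac = EXAMPLE_AAC if use_printed_inputs else compute_aac(EXAMPLE_SEQUENCE)
    return np.array(
        [aac.get(ch, 0.0) * EXAMPLE_LAMBDA.get(ch, 0.0) for ch in EXAMPLE_SEQUENCE]
    )


def example_window5_profile(use_printed_inputs: bool = True) -> np.ndarray:
    """Window-5 averaged profile of the worked example."""
    return window_average(example_raw_index(use_printed_inputs), 5)
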