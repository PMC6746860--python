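"""A small worked example: three interacting mutations of a fluorescent protein.

In the blue/red FP system, the mutations Y197R, F143S and V45A form a
cooperative unit on top of the reference background L63M/S168G/A174L/N207K
(brightness 0.85).  Y197R alone is strongly deleterious (brightness 0.28,
first-order effect -0.57), but in the F143S background its effect turns
positive (+0.49), a second-order term of 1.06; and that pairwise coupling
is quenched by V45A (residual pairwise effect -0.01), a third-order term
of -1.07.  The sub-landscape here reproduces those measured values; the
brightnesses of the remaining corners are not individually constrained by
the published effects and are set to plausible fill-in values (they do not
enter the three quoted terms).
"""

from __future__ import annotations

import numpy as np

from .genotype_space import PositionMap
from .operators import Landscape

__all__ = ["fp_three_mutation_example", "FP_EXAMPLE_POSITIONS"]

FP_EXAMPLE_POSITIONS = PositionMap(names=("Y197R", "F143S", "V45A"))

# measured brightnesses / effects in the reference background
_Y_REF = 0.85          # reference genotype (L63M/S168G/A174L/N207K)
_Y_Y197R = 0.28        # + Y197R
_EFFECT_IN_F143S = 0.49    # effect of Y197R in the F143S background
_PAIR_IN_V45A = -0.01      # residual Y197R:F143S coupling under V45A
# unconstrained corners (any values leave the three quoted terms unchanged)
_Y_F143S = 0.60
_Y_V45A = 0.70
_Y_Y197R_V45A = 0.40
_Y_F143S_V45A = 0.50


def fp_three_mutation_example() -> Landscape:
    """Complete N=3 landscape over (Y197R, F143S, V45A), bit order as listed.

    Its single-reference transform from the reference corner yields the
    measured interaction chain: first-order Y197R term -0.57, second-order
    Y197R:F143S term 1.06, third-order Y197R:F143S:V45A term -1.07.
    """
    y = np.empty(8)
    y[0b000] = _Y_REF
    y[0b001] = _Y_Y197R
    y[0b010] = _Y_F143S
    y[0b011] = _Y_F143S + _EFFECT_IN_F143S
    y[0b100] = _Y_V45A
    y[0b101] = _Y_Y197R_V45A
    y[0b110] = _Y_F143S_V45A
    y[0b111] = _Y_F143S_V45A + (_Y_Y197R_V45A - _Y_V45A) + _PAIR_IN_V45A
    return Landscape(3, y)
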