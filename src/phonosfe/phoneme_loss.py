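"""The founder-effect mutation schedule.

Every ``loss_time`` generations, every tribe in every cell whose population
is below the loss threshold loses one uniformly chosen phoneme,
independently per tribe.  Saturated cells (behind the advancing front) are
untouched, so the cline is laid down at the front and freezes behind it.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .demography import DemographyParams, GridState

__all__ = ["apply_loss_sweep"]


def apply_loss_sweep(state: GridState, params: DemographyParams,
                     rng: np.random.Generator) -> GridState:
    """Apply one loss sweep (in place; returns the state).

    For each cell with 0 < N < N_thr, each tribe's language loses one
    randomly chosen phoneme (independent draws, so tribes sharing a string
    diverge).  Empty strings are left unchanged.  Cells with N >= N_thr are
    not affected.
    """
    new_bits, src = _kernels.loss_kernel(
        state.lang, state.counts, state.pool_bits, state.pool_pop,
        params.N_thr, state.pool_bits.shape[0], _kernels.kernel_state(rng))
    state._append_pool(new_bits, src)
    return state
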