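"""Lattice population dynamics: dispersal, reproduction, transmission.

One generation is: (i) synchronous dispersal of tribes to von-Neumann
neighbours, (ii) net reproduction capped at the carrying capacity, with each
new tribe a clone of a randomly chosen resident ("vertical transmission"),
and (iii) every ``loss_time`` generations, the phoneme-loss sweep over
below-threshold cells (see :mod:`phonosfe.phoneme_loss`).

The engine state (:class:`GridState`) stores tribes as flat arrays grouped
by cell, with each tribe pointing at a row of an immutable language pool
(copy-on-write: mutation appends rows).  The per-cell operation
:func:`reproduce_and_transmit` is a direct, list-of-strings reference
implementation of the reproduction rule; the engine path is the vectorized
kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .lang_model import AncestralLanguage, LanguageString, PhonemeInventory

__all__ = [
    "DemographyParams",
    "GridState",
    "nearest_int",
    "disperse",
    "reproduce_and_transmit",
    "reproduce_all",
    "step_generation",
]


def nearest_int(x: float) -> int:
    """Nearest integer, rounding halves away from zero (10*0.38 -> 4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class DemographyParams:
    """Demographic and loss-schedule parameters.

    d_km
        node spacing: the characteristic dispersal distance per generation
        of pre-industrial populations (50 km).
    T_years
        generation time (32 y); with net growth rate ``a`` = 0.01/y this
        gives a net fecundity R0 = e^{aT} ~ 1.4.
    persistence
        fraction of a cell's tribes that stays put each generation (0.38).
    R0
        net per-generation multiplication factor below carrying capacity.
    Ns
        saturation density: maximum tribes per cell (10).
    N_thr
        loss threshold: cells with fewer tribes than this lose phonemes.
    loss_time
        generations between loss events (L); ``math.inf`` disables loss.
    """

    d_km: float = 50.0
    T_years: float = 32.0
    persistence: float = 0.38
    R0: float = 1.4
    Ns: int = 10
    N_thr: int = 10
    loss_time: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 < self.persistence < 1.0:
            raise ValueError("persistence must be in (0, 1)")
        if self.R0 <= 1.0:
            raise ValueError("net fecundity R0 must exceed 1")
        if not 1 <= self.N_thr <= self.Ns:
            raise ValueError("need 1 <= N_thr <= Ns")
        if not (self.loss_time == math.inf or self.loss_time >= 1):
            raise ValueError("loss_time must be >= 1 generation (or inf)")
        if self.d_km <= 0 or self.T_years <= 0:
            raise ValueError("d_km and T_years must be positive")

    @classmethod
    def from_growth_rate(cls, a_per_year: float = 0.01, T_years: float = 32.0, **kw) -> "DemographyParams":
        """Build with R0 = e^{a*T} computed from the annual growth rate."""
        return cls(T_years=T_years, R0=math.exp(a_per_year * T_years), **kw)

    @property
    def loss_enabled(self) -> bool:
        return math.isfinite(self.loss_time)


class GridState:
    """Tribes on an n x n lattice, grouped by flattened cell index.

    Attributes
    ----------
    counts : int32[n*n]
        tribes per cell.
    lang : array of pool-row indices, one per tribe, grouped by cell.
    pool_bits : uint8[P, Kmax]
        compact presence bit-strings (ancestor-relative, zero-padded).
    pool_anc : int16[P]
        index into ``ancestors`` per pool row.
    pool_pop : int32[P]
        cached popcount per pool row.
    """

    def __init__(self, n: int, ancestors: Sequence[AncestralLanguage],
                 inventory: PhonemeInventory | None = None) -> None:
        if n < 3:
            raise ValueError("grid side must be at least 3")
        self.n = int(n)
        self.origin = (n // 2, n // 2)
        self.ancestors = list(ancestors)
        self.inventory = inventory
        kmax = max(a.K for a in self.ancestors)
        self.counts = np.zeros(n * n, dtype=np.int32)
        self.lang = np.empty(0, dtype=np.int64)
        # one initial pool row per ancestor: its own (all-ones) string
        self.pool_bits = np.zeros((len(self.ancestors), kmax), dtype=np.uint8)
        for i, a in enumerate(self.ancestors):
            self.pool_bits[i, : a.K] = 1
        self.pool_anc = np.arange(len(self.ancestors), dtype=np.int16)
        self.pool_pop = np.array([a.K for a in self.ancestors], dtype=np.int32)

    @classmethod
    def seeded(cls, n: int, ancestors: Sequence[AncestralLanguage],
               multiplicities: Sequence[int],
               inventory: PhonemeInventory | None = None) -> "GridState":
        """Seed the central cell with the given tribes-per-language counts."""
        if len(multiplicities) != len(ancestors):
            raise ValueError("one multiplicity per ancestral language")
        state = cls(n, ancestors, inventory)
        langs = np.repeat(np.arange(len(ancestors), dtype=np.int64),
                          np.asarray(multiplicities, dtype=np.int64))
        c = state.origin[0] * n + state.origin[1]
        state.counts[c] = langs.size
        state.lang = langs
        return state

    # -- inspection ------------------------------------------------------
    @property
    def total_tribes(self) -> int:
        return int(self.lang.size)

    def counts_grid(self) -> np.ndarray:
        return self.counts.reshape(self.n, self.n)

    def cell_slice(self, row: int, col: int) -> slice:
        c = row * self.n + col
        starts = np.concatenate(([0], np.cumsum(self.counts)))
        return slice(int(starts[c]), int(starts[c + 1]))

    def tribes_in(self, row: int, col: int) -> list[LanguageString]:
        """The cell's tribes as LanguageString objects (analysis/testing)."""
        out = []
        for row_idx in self.lang[self.cell_slice(row, col)]:
            anc = self.ancestors[self.pool_anc[row_idx]]
            out.append(LanguageString(anc.id, self.pool_bits[row_idx, : anc.K]))
        return out

    def tribe_phoneme_counts(self) -> np.ndarray:
        """Phoneme count per tribe, in storage (cell-grouped) order."""
        return self.pool_pop[self.lang]

    def _append_pool(self, new_bits: np.ndarray, src: np.ndarray) -> None:
        if new_bits.shape[0] == 0:
            return
        self.pool_bits = np.concatenate([self.pool_bits, new_bits], axis=0)
        self.pool_anc = np.concatenate([self.pool_anc, self.pool_anc[src]])
        self.pool_pop = np.concatenate([self.pool_pop, self.pool_pop[src] - 1])

    def compact_pool(self) -> None:
        """Drop pool rows no tribe references (keeps the ancestral rows)."""
        n_anc = len(self.ancestors)
        keep = np.union1d(np.arange(n_anc), np.unique(self.lang))
        remap = np.full(self.pool_bits.shape[0], -1, dtype=np.int64)
        remap[keep] = np.arange(keep.size)
        self.pool_bits = self.pool_bits[keep]
        self.pool_anc = self.pool_anc[keep]
        self.pool_pop = self.pool_pop[keep]
        self.lang = remap[self.lang]


# -- per-generation operations ------------------------------------------

def disperse(state: GridState, params: DemographyParams, rng: np.random.Generator) -> GridState:
    """Synchronous dispersal sweep (in place; returns the state).

    Per cell, nearest-int(N*persistence) tribes stay and the rest are dealt
    round-robin to the available neighbours, each of which can receive at
    most nearest-int(N*(1-persistence)/k) tribes; sparse cells (N <= 3 at
    the default persistence) therefore do not emigrate at all.  Conserves
    the total tribe count exactly; the carrying-capacity cap is *not*
    applied here (cells may transiently exceed Ns from in-flow).
    """
    state.lang, state.counts = _kernels.disperse_kernel(
        state.lang, state.counts, state.n, params.persistence,
        _kernels.kernel_state(rng))
    return state


def reproduce_all(state: GridState, params: DemographyParams, rng: np.random.Generator) -> GridState:
    """Reproduction + vertical transmission for every cell (engine path)."""
    state.lang, state.counts = _kernels.reproduce_kernel(
        state.lang, state.counts, params.R0, params.Ns,
        _kernels.kernel_state(rng))
    return state


def reproduce_and_transmit(tribes: Sequence[LanguageString], params: DemographyParams,
                           rng: np.random.Generator) -> list[LanguageString]:
    """Reference single-cell reproduction rule on LanguageString lists.

    target = min(nearest_int(N*R0), Ns).  If target > N, add clones of
    independently uniformly chosen residents; if target < N (possible only
    when in-flow pushed the cell above Ns), remove uniformly random tribes.
    """
    tribes = list(tribes)
    n = len(tribes)
    if n == 0:
        return []
    target = min(nearest_int(n * params.R0), params.Ns)
    if target < n:
        keep = rng.permutation(n)[:target]
        return [tribes[i] for i in sorted(keep)]
    clones = [tribes[int(rng.integers(0, n))] for _ in range(target - n)]
    return tribes + clones


def step_generation(state: GridState, params: DemographyParams, generation_index: int,
                    rng: np.random.Generator) -> GridState:
    """One full generation: dispersal, reproduction, and (on generations
    divisible by the loss time) the phoneme-loss sweep."""
    if generation_index < 1:
        raise ValueError("generation_index starts at 1")
    disperse(state, params, rng)
    reproduce_all(state, params, rng)
    if params.loss_enabled and generation_index % int(params.loss_time) == 0:
        from .phoneme_loss import apply_loss_sweep
        apply_loss_sweep(state, params, rng)
    return state
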