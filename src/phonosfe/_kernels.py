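"""Numba kernels for the lattice engine.

Tribes are stored CSR-style: one flat ``lang`` array of pool-row indices,
grouped by flattened cell index, together with a per-cell ``counts`` array.
Each generation rebuilds these two arrays in O(total tribes).

Randomness: the kernels draw from an inline xorshift128+ stream whose state
is seeded, per call, from the run's ``numpy.random.Generator`` — every run
is reproducible from its single seed.  Bounded draws use a plain modulo
(bias ~ n / 2**64, irrelevant at the bound sizes used here); this keeps the
per-draw cost to a few nanoseconds, which matters because dispersal draws a
handful of random numbers for every cell of the lattice every generation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["disperse_kernel", "reproduce_kernel", "loss_kernel", "kernel_state"]

_U64 = np.uint64


def kernel_state(rng: np.random.Generator) -> np.ndarray:
    """Fresh xorshift128+ state drawn from a numpy Generator."""
    s = rng.integers(0, 2**64, size=2, dtype=np.uint64)
    if s[0] == 0 and s[1] == 0:
        s[0] = 1
    return s


@njit(cache=True, inline="always")
def _next64(s):
    x = s[0]
    y = s[1]
    s[0] = y
    x ^= x << _U64(23)
    x ^= x >> _U64(17)
    x ^= y ^ (y >> _U64(26))
    s[1] = x
    return x + y


@njit(cache=True, inline="always")
def _randint(s, n):
    # uniform int in [0, n); modulo bias negligible for the tiny n used here
    return np.int64(_next64(s) % _U64(n))


@njit(cache=True, inline="always")
def _select_front(seg, m, s):
    """Move a uniformly random m-subset of seg to the front (partial FY)."""
    n = seg.size
    for i in range(m):
        j = i + _randint(s, n - i)
        tmp = seg[i]
        seg[i] = seg[j]
        seg[j] = tmp


@njit(cache=True, inline="always")
def _shuffle(seg, s):
    for i in range(seg.size - 1, 0, -1):
        j = _randint(s, i + 1)
        tmp = seg[i]
        seg[i] = seg[j]
        seg[j] = tmp


@njit(cache=True, inline="always")
def _nearest_int(x):
    # round half away from zero for non-negative x (10*0.38 -> 4)
    return int(np.floor(x + 0.5))


@njit(cache=True)
def disperse_kernel(lang, counts, n, pe, s):
    """One synchronous dispersal sweep.

    Per source cell with N tribes and k available von-Neumann neighbours
    (4 interior, 3 edge, 2 corner): each neighbour can receive up to
    q = nearest-int(N*(1-pe)/k) tribes, and the movers — at most
    N - nearest-int(N*pe) of them, randomly chosen — are dealt round-robin
    over the k neighbours in a random order.  For N = 10, k = 4 this is the
    canonical 4-stay/6-move split with every neighbour receiving at least
    one tribe; for N <= 3 (with pe = 0.38) the quota is zero, so sparse
    cells hold together instead of evaporating — which is what keeps the
    colonization wave coherent at low net fecundity (R0 ~ 1.2).  Tribe
    count is conserved.
    """
    ncells = counts.size
    m_tot = lang.size
    dest = np.empty(m_tot, np.int64)
    new_counts = np.zeros(ncells, np.int32)
    nb = np.empty(4, np.int64)

    start = 0
    for c in range(ncells):
        nc = counts[c]
        if nc == 0:
            continue
        seg = lang[start:start + nc]
        r = c // n
        col = c - r * n
        k = 0
        if r > 0:
            nb[k] = c - n
            k += 1
        if r < n - 1:
            nb[k] = c + n
            k += 1
        if col > 0:
            nb[k] = c - 1
            k += 1
        if col < n - 1:
            nb[k] = c + 1
            k += 1

        stay = _nearest_int(nc * pe)
        if stay > nc:
            stay = nc
        quota = _nearest_int(nc * (1.0 - pe) / k)
        movers = nc - stay
        if movers > k * quota:
            movers = k * quota
        stay = nc - movers
        # randomly partition the segment into seg[:stay] / seg[stay:]
        if stay <= movers:
            _select_front(seg, stay, s)
        else:
            _select_front(seg[::-1], movers, s)

        for t in range(stay):
            dest[start + t] = c
        new_counts[c] += stay

        if movers > 0:
            _shuffle(nb[:k], s)
            for t in range(movers):
                d = nb[t % k]
                dest[start + stay + t] = d
                new_counts[d] += 1
        start += nc

    # counting sort by destination cell
    new_lang = np.empty(m_tot, lang.dtype)
    cursor = np.empty(ncells, np.int64)
    acc = 0
    for c in range(ncells):
        cursor[c] = acc
        acc += new_counts[c]
    for i in range(m_tot):
        d = dest[i]
        new_lang[cursor[d]] = lang[i]
        cursor[d] += 1
    return new_lang, new_counts


@njit(cache=True)
def reproduce_kernel(lang, counts, r0, ns, s):
    """Net reproduction with carrying-capacity cap, plus vertical transmission.

    Per cell: target = min(nearest-int(N*r0), ns).  New tribes are exact
    copies (clones) of independently, uniformly chosen existing tribes of
    the same cell.  Cells pushed above ns by in-flow are trimmed to ns by
    removing uniformly random tribes.
    """
    ncells = counts.size
    new_counts = np.zeros(ncells, np.int32)
    total = 0
    for c in range(ncells):
        nc = counts[c]
        if nc > 0:
            t = _nearest_int(nc * r0)
            if t > ns:
                t = ns
            new_counts[c] = t
            total += t

    out = np.empty(total, lang.dtype)
    start = 0
    w = 0
    for c in range(ncells):
        nc = counts[c]
        if nc == 0:
            continue
        seg = lang[start:start + nc]
        kept = nc if nc < ns else ns
        if kept < nc:
            _select_front(seg, kept, s)  # random trim: keep the first `kept`
        t = new_counts[c]
        for j in range(kept):
            out[w + j] = seg[j]
        for j in range(kept, t):
            out[w + j] = seg[_randint(s, kept)]
        w += t
        start += nc
    return out, new_counts


@njit(cache=True)
def loss_kernel(lang, counts, pool_bits, pool_pop, n_thr, pool_size, s):
    """One phoneme-loss sweep.

    Every tribe in every cell with 0 < N < n_thr loses one uniformly chosen
    phoneme, independently per tribe.  Mutated strings become new pool rows
    (copy-on-write): returns (new_bits, src_rows) where ``src_rows[i]`` is
    the parent pool row of appended row i, and updates ``lang`` in place to
    point at rows ``pool_size + i``.
    """
    ncells = counts.size
    kmax = pool_bits.shape[1]

    # first pass: how many tribes actually mutate
    n_mut = 0
    start = 0
    for c in range(ncells):
        nc = counts[c]
        if nc == 0:
            continue
        if nc < n_thr:
            for i in range(start, start + nc):
                if pool_pop[lang[i]] > 0:
                    n_mut += 1
        start += nc

    new_bits = np.empty((n_mut, kmax), np.uint8)
    src = np.empty(n_mut, np.int64)

    a = 0
    start = 0
    for c in range(ncells):
        nc = counts[c]
        if nc == 0:
            continue
        if nc < n_thr:
            for i in range(start, start + nc):
                row = lang[i]
                p = pool_pop[row]
                if p == 0:
                    continue
                for j in range(kmax):
                    new_bits[a, j] = pool_bits[row, j]
                r = _randint(s, p)
                seen = -1
                for j in range(kmax):
                    if new_bits[a, j] == 1:
                        seen += 1
                        if seen == r:
                            new_bits[a, j] = 0
                            break
                src[a] = row
                lang[i] = pool_size + a
                a += 1
        start += nc
    return new_bits, src
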