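"""Numba kernels for the simulated-annealing inner loop.

The rewiring move, loop rejection and incremental energy update run millions
of times per optimization, so they are compiled.  Energy increments use a
precomputed table of A**gamma for integer areas 0..N, and the affected
pixels are found by stamping the current downstream path of the rewired
pixel and walking the proposed new path until the two merge.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def run_chunk(
    receiver,      # int64 (N,) in/out
    A,             # int64 (N,) in/out
    nbr,           # int64 (N, 8)
    nbr_count,     # int64 (N,)
    candidates,    # int64 (n_non_outlet,)
    pow_tab,       # float64 (N+1,): pow_tab[a] = a ** gamma
    H,             # float64 current energy
    k_start, k_end,  # iteration range [k_start, k_end)
    T0, cooling_rate, k0,  # schedule: T = T0 for k < k0 else exp decay
    n_pixels,
    mark,          # int64 (N,) scratch, zero-initialized on first call
    stamp,         # int64 running stamp value
):
    """Advance the annealing by k_end - k_start iterations in place.

    Returns the updated (H, n_accepted, stamp).  Proposals that would
    create a loop, and uphill moves rejected by the Metropolis rule,
    consume an iteration without changing state.
    """
    n_accepted = 0
    for k in range(k_start, k_end):
        stamp += 1
        if k < k0:
            T = T0
        else:
            T = T0 * np.exp(-cooling_rate * (k - k0) / n_pixels)
        i = candidates[np.random.randint(candidates.shape[0])]
        cnt = nbr_count[i]
        if cnt < 2:
            continue
        r_old = receiver[i]
        # uniform among neighbors excluding the current receiver
        m = np.random.randint(cnt - 1)
        j = np.int64(-1)
        seen = 0
        for t in range(cnt):
            nb = nbr[i, t]
            if nb == r_old:
                continue
            if seen == m:
                j = nb
                break
            seen += 1
        # stamp the current downstream path of i (i inclusive)
        p = i
        while p != -1:
            mark[p] = stamp
            p = receiver[p]
        # walk the proposed path from j until it merges with the old path
        loop = False
        junction = np.int64(-1)
        p = j
        while p != -1:
            if mark[p] == stamp:
                if p == i:
                    loop = True
                junction = p
                break
            p = receiver[p]
        if loop:
            continue
        dA = A[i]
        dH = 0.0
        p = r_old
        while p != junction and p != -1:
            dH += pow_tab[A[p] - dA] - pow_tab[A[p]]
            p = receiver[p]
        p = j
        while p != junction and p != -1:
            dH += pow_tab[A[p] + dA] - pow_tab[A[p]]
            p = receiver[p]
        accept = dH < 0.0
        if not accept and T > 0.0:
            accept = np.random.random() < np.exp(-dH / T)
        if accept:
            p = r_old
            while p != junction and p != -1:
                A[p] -= dA
                p = receiver[p]
            p = j
            while p != junction and p != -1:
                A[p] += dA
                p = receiver[p]
            receiver[i] = j
            H += dH
            n_accepted += 1
    return H, n_accepted, stamp
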