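"""Compiled Monte-Carlo core of the attraction search.

One replicate draws a single uniform per attempt and picks the activated
word by a sequential scan over the candidate set in ascending node-index
order, so the pure-Python reference implementation in :mod:`ratnet.search`
can reproduce every trajectory bit-for-bit by consuming the same legacy
MT19937 stream (numba's ``np.random`` matches ``numpy.random.RandomState``
exactly).  Only the out-neighbourhood of the active words is ever
touched: the stimulus contribution is precomputed once and the current
guess's row is merged in per attempt, keeping each attempt O(active
out-degree) rather than O(n).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_batch"]


@njit(cache=True)
def simulate_batch(
    indptr,
    indices,
    data,
    n,
    stim,
    resp,
    tau,
    t_max,
    seeds,
    renormalize,
):
    """Run one seeded replicate per entry of ``seeds``.

    Returns ``(success_attempt, n_activations)`` per run; a success at
    attempt ``t`` is recorded as ``t`` and a failed run as ``0``.
    """
    n_runs = seeds.shape[0]
    # stimulus contribution, as a sorted sparse vector
    dense = np.zeros(n)
    blocked0 = np.zeros(n, np.uint8)
    for si in stim:
        blocked0[si] = 1
        for e in range(indptr[si], indptr[si + 1]):
            dense[indices[e]] += data[e]
    nb = 0
    for i in range(n):
        if dense[i] > 0.0:
            nb += 1
    base_idx = np.empty(nb, np.int64)
    base_val = np.empty(nb)
    k = 0
    for i in range(n):
        if dense[i] > 0.0:
            base_idx[k] = i
            base_val[k] = dense[i]
            k += 1
    max_deg = 0
    for i in range(n):
        deg = indptr[i + 1] - indptr[i]
        if deg > max_deg:
            max_deg = deg
    cand_idx = np.empty(nb + max_deg, np.int64)
    cand_val = np.empty(nb + max_deg)
    success_attempt = np.zeros(n_runs, np.int64)
    n_activations = np.zeros(n_runs, np.int64)
    blk = np.empty(n, np.uint8)
    for run in range(n_runs):
        np.random.seed(seeds[run])
        blk[:] = blocked0
        guess = -1
        activations = 0
        success = 0
        for t in range(1, t_max + 1):
            # merge the base vector with the guess's out-row (both sorted)
            if guess < 0:
                nc = nb
                for a in range(nb):
                    cand_idx[a] = base_idx[a]
                    cand_val[a] = base_val[a]
            else:
                lo, hi = indptr[guess], indptr[guess + 1]
                a = 0
                b = lo
                nc = 0
                while a < nb and b < hi:
                    ia = base_idx[a]
                    ib = indices[b]
                    if ia < ib:
                        cand_idx[nc] = ia
                        cand_val[nc] = base_val[a]
                        a += 1
                    elif ib < ia:
                        cand_idx[nc] = ib
                        cand_val[nc] = data[b]
                        b += 1
                    else:
                        cand_idx[nc] = ia
                        cand_val[nc] = base_val[a] + data[b]
                        a += 1
                        b += 1
                    nc += 1
                while a < nb:
                    cand_idx[nc] = base_idx[a]
                    cand_val[nc] = base_val[a]
                    a += 1
                    nc += 1
                while b < hi:
                    cand_idx[nc] = indices[b]
                    cand_val[nc] = data[b]
                    b += 1
                    nc += 1
            total_all = 0.0
            total_pass = 0.0
            for c in range(nc):
                if blk[cand_idx[c]] == 0:
                    v = cand_val[c]
                    total_all += v
                    if v >= tau:
                        total_pass += v
            if total_pass <= 0.0:
                break
            x = -1
            if renormalize:
                u = np.random.random() * total_pass
                acc = 0.0
                for c in range(nc):
                    if blk[cand_idx[c]] == 0 and cand_val[c] >= tau:
                        acc += cand_val[c]
                        if acc > u:
                            x = cand_idx[c]
                            break
                if x == -1:  # float round-off at the top of the CDF
                    for c in range(nc - 1, -1, -1):
                        if blk[cand_idx[c]] == 0 and cand_val[c] >= tau:
                            x = cand_idx[c]
                            break
            else:
                # as-printed variant: mass of sub-threshold candidates is
                # left unassigned, so an attempt may activate nothing
                u = np.random.random() * total_all
                acc = 0.0
                for c in range(nc):
                    if blk[cand_idx[c]] == 0:
                        acc += cand_val[c]
                        if acc > u:
                            if cand_val[c] >= tau:
                                x = cand_idx[c]
                            break
            if x == -1:
                continue
            blk[x] = 1
            activations += 1
            if x == resp:
                success = t
                break
            guess = x
        success_attempt[run] = success
        n_activations[run] = activations
    return success_attempt, n_activations
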