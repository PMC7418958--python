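"""Compiled production engine.

``run_iterations_kernel`` advances an esteem matrix in place by a given
number of iterations.  It consumes the caller's ``numpy.random.Generator``
with exactly the same draw sequence as the reference loop in
:mod:`leviathan.dynamics` (see the draw-discipline note there), so both
engines yield bit-identical trajectories from a shared seed.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def run_iterations_kernel(
    a,  # (N, N) float64, modified in place
    sigma,  # (N,) per-agent open-mindedness
    is_large,  # (N,) bool: True for L-group agents
    members_s,  # int64 indices of S-group agents (sorted)
    members_l,  # int64 indices of L-group agents (sorted)
    pos_in_group,  # (N,) index of each agent inside its group array
    n_iterations,
    delta,
    k,
    same_group_prob,
    uniform_pairing,
    lo,
    hi,
    rng,
):
    n = a.shape[0]
    half = n // 2
    for _ in range(n_iterations):
        for _ in range(half):
            i = int(rng.random() * n)

            if uniform_pairing:
                j = int(rng.random() * (n - 1))
                if j >= i:
                    j += 1
            else:
                # partner: own group w.p. same_group_prob, else the other,
                # with degenerate pools falling back to the non-empty one
                own = members_l if is_large[i] else members_s
                other = members_s if is_large[i] else members_l
                same = rng.random() < same_group_prob
                use_own = (own.shape[0] > 1) if same else (other.shape[0] == 0)
                if use_own:
                    r = int(rng.random() * (own.shape[0] - 1))
                    if r >= pos_in_group[i]:
                        r += 1
                    j = own[r]
                else:
                    j = other[int(rng.random() * other.shape[0])]

            # Influence(i, j) then Influence(j, i)
            for step in range(2):
                li = i if step == 0 else j
                sp = j if step == 0 else i
                p = 1.0 / (1.0 + math.exp(-(a[li, sp] - a[li, li]) / sigma[li]))
                u = 2.0 * delta * rng.random() - delta
                v = a[li, li] + p * (a[sp, li] - a[li, li] + u)
                a[li, li] = lo if v < lo else hi if v > hi else v
                u = 2.0 * delta * rng.random() - delta
                v = a[li, sp] + p * (a[sp, sp] - a[li, sp] + u)
                a[li, sp] = lo if v < lo else hi if v > hi else v

            # Gossip(i, j) then Gossip(j, i)
            if k > 0:
                lo_ex = i if i < j else j
                hi_ex = j if i < j else i
                for step in range(2):
                    li = i if step == 0 else j
                    sp = j if step == 0 else i
                    p = 1.0 / (1.0 + math.exp(-(a[li, sp] - a[li, li]) / sigma[li]))
                    for _ in range(k):
                        z = int(rng.random() * (n - 2))
                        if z >= lo_ex:
                            z += 1
                        if z >= hi_ex:
                            z += 1
                        u = 2.0 * delta * rng.random() - delta
                        v = a[li, z] + p * (a[sp, z] - a[li, z] + u)
                        a[li, z] = lo if v < lo else hi if v > hi else v
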