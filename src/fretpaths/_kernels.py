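"""Hot loops of the photon-level HMM: forward likelihood, Viterbi, recoloring.

All kernels operate on concatenated per-burst arrays (photon times in seconds,
acceptor flags) indexed by an offsets array ``starts`` of length n_bursts + 1.
They are compiled with numba when available and fall back to the identical
pure-Python definitions otherwise.
"""

from __future__ import annotations

import numpy as np


def _forward_loglik(times, colors, starts, k12, k21, E1, E2, pi1, pi2):
    k = k12 + k21
    s1 = k21 / k  # stationary prob of state 1
    s2 = k12 / k
    total = 0.0
    n_bursts = starts.shape[0] - 1
    for b in range(n_bursts):
        lo, hi = starts[b], starts[b + 1]
        c = colors[lo]
        b1 = E1 if c == 1 else 1.0 - E1
        b2 = E2 if c == 1 else 1.0 - E2
        a1 = pi1 * b1
        a2 = pi2 * b2
        scale = a1 + a2
        total += np.log(scale)
        a1 /= scale
        a2 /= scale
        for i in range(lo + 1, hi):
            dt = times[i] - times[i - 1]
            e = np.exp(-k * dt)
            A11 = s1 + s2 * e
            A12 = s2 * (1.0 - e)
            A21 = s1 * (1.0 - e)
            A22 = s2 + s1 * e
            c = colors[i]
            b1 = E1 if c == 1 else 1.0 - E1
            b2 = E2 if c == 1 else 1.0 - E2
            n1 = (a1 * A11 + a2 * A21) * b1
            n2 = (a1 * A12 + a2 * A22) * b2
            scale = n1 + n2
            total += np.log(scale)
            a1 = n1 / scale
            a2 = n2 / scale
    return total


def _viterbi(times, colors, starts, k12, k21, E1, E2, pi1, pi2, out):
    k = k12 + k21
    s1 = k21 / k
    s2 = k12 / k
    n_bursts = starts.shape[0] - 1
    n = times.shape[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for b in range(n_bursts):
        lo, hi = starts[b], starts[b + 1]
        c = colors[lo]
        lb1 = np.log(E1 if c == 1 else 1.0 - E1)
        lb2 = np.log(E2 if c == 1 else 1.0 - E2)
        d1 = np.log(pi1) + lb1
        d2 = np.log(pi2) + lb2
        for i in range(lo + 1, hi):
            dt = times[i] - times[i - 1]
            e = np.exp(-k * dt)
            lA11 = np.log(s1 + s2 * e)
            lA12 = np.log(s2 * (1.0 - e))
            lA21 = np.log(s1 * (1.0 - e))
            lA22 = np.log(s2 + s1 * e)
            c = colors[i]
            lb1 = np.log(E1 if c == 1 else 1.0 - E1)
            lb2 = np.log(E2 if c == 1 else 1.0 - E2)
            # ties broken toward state 1 (>=)
            if d1 + lA11 >= d2 + lA21:
                n1 = d1 + lA11 + lb1
                back[i, 0] = 0
            else:
                n1 = d2 + lA21 + lb1
                back[i, 0] = 1
            if d1 + lA12 >= d2 + lA22:
                n2 = d1 + lA12 + lb2
                back[i, 1] = 0
            else:
                n2 = d2 + lA22 + lb2
                back[i, 1] = 1
            d1 = n1
            d2 = n2
        state = 0 if d1 >= d2 else 1
        out[hi - 1] = state + 1
        for i in range(hi - 1, lo, -1):
            state = back[i, state]
            out[i - 1] = state + 1
    return out


def _recolor(times, starts, k12, k21, E1, E2, pi1, pi2, u_init, u_trans, u_color, out):
    k = k12 + k21
    s1 = k21 / k
    s2 = k12 / k
    n_bursts = starts.shape[0] - 1
    for b in range(n_bursts):
        lo, hi = starts[b], starts[b + 1]
        state = 1 if u_init[b] < pi1 else 2
        e_state = E1 if state == 1 else E2
        out[lo] = 1 if u_color[lo] < e_state else 0
        for i in range(lo + 1, hi):
            dt = times[i] - times[i - 1]
            e = np.exp(-k * dt)
            if state == 1:
                p_stay = s1 + s2 * e
            else:
                p_stay = s2 + s1 * e
            if u_trans[i] >= p_stay:
                state = 3 - state
            e_state = E1 if state == 1 else E2
            out[i] = 1 if u_color[i] < e_state else 0
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    forward_loglik = njit(cache=True, fastmath=False)(_forward_loglik)
    viterbi_kernel = njit(cache=True, fastmath=False)(_viterbi)
    recolor_kernel = njit(cache=True, fastmath=False)(_recolor)
except Exception:  # pragma: no cover
    forward_loglik = _forward_loglik
    viterbi_kernel = _viterbi
    recolor_kernel = _recolor
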