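"""Numba-fused likelihood reduction for the hierarchical sampler.

One fused pass computes, for every chain and participant, the summed log
defective density of that participant's trials under the chain's current
parameter block. Equivalent to :func:`lbacomp.lba.defective_logpdf_arrays`
followed by a segment sum (the tests assert agreement); fusing avoids the
~20 large temporaries of the numpy path.
"""

from __future__ import annotations

import math

import numba
import numpy as np

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@numba.njit(inline="always")
def _ndtr(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@numba.njit(inline="always")
def _npdf(x):
    return _INV_SQRT_2PI * math.exp(-0.5 * x * x)


@numba.njit(cache=True)
def loglik_reduce(rt, correct, part_idx, cond_idx, params, s_v, normalize, out):
    """Accumulate per-(chain, participant) trial log likelihoods.

    ``params``: (C, P, 11) participant blocks laid out as
    [A, t0, s, B x 4 conditions, d x 4 conditions]; ``out``: (C, P) zeros
    on entry. Invalid parameter/trial combinations drive the participant's
    total to -inf.
    """
    C = params.shape[0]
    n = rt.shape[0]
    for c in range(C):
        for i in range(n):
            p = part_idx[i]
            k = cond_idx[i]
            A = params[c, p, 0]
            t0 = params[c, p, 1]
            s = params[c, p, 2]
            B = params[c, p, 3 + k]
            d = params[c, p, 7 + k]
            b = A + B
            t = rt[i] - t0
            if t <= 0.0 or A <= 1e-10 or B < 0.0 or s_v <= 0.0:
                out[c, p] = -np.inf
                continue
            v_c = 0.5 * (s + d)
            v_e = 0.5 * (s - d)
            if correct[i]:
                v_win = v_c
                v_lose = v_e
            else:
                v_win = v_e
                v_lose = v_c
            ts = t * s_v
            z1 = (b - A - t * v_win) / ts
            z2 = (b - t * v_win) / ts
            f = (-v_win * _ndtr(z1) + s_v * _npdf(z1)
                 + v_win * _ndtr(z2) - s_v * _npdf(z2)) / A
            z1l = (b - A - t * v_lose) / ts
            z2l = (b - t * v_lose) / ts
            F = (1.0 + (b - A - t * v_lose) / A * _ndtr(z1l)
                 - (b - t * v_lose) / A * _ndtr(z2l)
                 + ts / A * (_npdf(z1l) - _npdf(z2l)))
            if F < 0.0:
                F = 0.0
            elif F > 1.0:
                F = 1.0
            dens = (f if f > 0.0 else 0.0) * (1.0 - F)
            if normalize:
                dens = dens / (1.0 - _ndtr(-v_c / s_v) * _ndtr(-v_e / s_v))
            if dens <= 0.0 or not math.isfinite(dens):
                out[c, p] = -np.inf
            else:
                out[c, p] += math.log(dens)
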