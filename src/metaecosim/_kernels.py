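"""Compiled right-hand side used by the integrator.

The flat parameter layout is
``[I_N, e_N, m_P, m_C, a_P, b_P, a_C, b_C, r_P, r_C, d_N, d_P]``;
the per-patch consumer dispersal rates travel separately so they can be
patch-specific.  Kept in exact correspondence with
:func:`metaecosim.model.derivative` (enforced by tests).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import ModelParams

__all__ = ["pack_params", "rhs_odeint", "rhs"]


def pack_params(params: ModelParams) -> np.ndarray:
    return np.array(
        [
            params.I_N, params.e_N, params.m_P, params.m_C,
            params.a_P, params.b_P, params.a_C, params.b_C,
            params.r_P, params.r_C, params.d_N, params.d_P,
        ]
    )


@njit(cache=True)
def rhs(t, y, par, S_N, S_C, S_P, d_C):  # pragma: no cover - compiled
    n = d_C.shape[0]
    N = y[:n]
    P = y[n : 2 * n]
    C = y[2 * n :]
    out = np.empty(3 * n)
    flowN = S_N @ N
    flowC = S_C @ C
    flowP = S_P @ P
    for i in range(n):
        fP = par[4] * N[i] / (par[5] + N[i])
        fC = par[6] * P[i] / (par[7] + P[i])
        out[i] = (
            par[0]
            - par[1] * N[i]
            + par[2] * par[8] * P[i]
            + par[3] * par[9] * C[i]
            - P[i] * fP
            + par[10] * flowN[i]
        )
        out[n + i] = P[i] * fP - par[2] * P[i] - C[i] * fC + par[11] * flowP[i]
        out[2 * n + i] = C[i] * fC - par[3] * C[i] + d_C[i] * flowC[i]
    return out


@njit(cache=True)
def rhs_odeint(y, t, par, S_N, S_C, S_P, d_C):  # pragma: no cover - compiled
    return rhs(t, y, par, S_N, S_C, S_P, d_C)
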