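"""Jit-compiled hot path for the Monte-Carlo likelihood engine.

Fitting evaluates the model's predicted responses for tens of thousands of
simulated trials at every optimizer step, so the bisensory trial
computation (sensations -> structure posterior -> strategy rule -> final
reports) is fused into one compiled loop here.  The arithmetic mirrors the
reference implementation in :mod:`avloc.model` exactly; a unit test pins
the two paths against each other.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STRATEGY_CODES = {"averaging": 0, "selection": 1, "matching": 2}


@njit(cache=True)
def bisensory_responses(
    s_A: np.ndarray,
    s_V: np.ndarray,
    z_A: np.ndarray,
    z_V: np.ndarray,
    xi: np.ndarray,
    sigma_A: float,
    sigma_V: float,
    sigma_P: float,
    p_common: float,
    criterion: float,
    strategy: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Final (auditory, visual) reports for a (n_cond, mc) block of bisensory trials.

    ``s_A``/``s_V`` are per-condition true locations (length n_cond);
    ``z_A``/``z_V``/``xi`` are fixed standard-normal / uniform draws of
    shape (n_cond, mc).  ``strategy`` uses STRATEGY_CODES.
    """
    n_c, mc = z_A.shape
    out_A = np.empty((n_c, mc))
    out_V = np.empty((n_c, mc))
    va = sigma_A * sigma_A
    vv = sigma_V * sigma_V
    vp = sigma_P * sigma_P
    denom = va * vv + va * vp + vv * vp
    log_norm_c1 = -np.log(2.0 * np.pi) - 0.5 * np.log(denom)
    log_norm_c2 = -0.5 * (np.log(2.0 * np.pi * (va + vp)) + np.log(2.0 * np.pi * (vv + vp)))
    inv_va_vp = 1.0 / (va + vp)
    inv_vv_vp = 1.0 / (vv + vp)
    w_sum = 1.0 / va + 1.0 / vv + 1.0 / vp
    shrink_A = vp * inv_va_vp
    shrink_V = vp * inv_vv_vp
    degenerate = p_common <= 0.0 or p_common >= 1.0
    logit_pc = 0.0 if degenerate else np.log(p_common) - np.log1p(-p_common)
    for i in range(n_c):
        for j in range(mc):
            x_A = s_A[i] + sigma_A * z_A[i, j]
            x_V = s_V[i] + sigma_V * z_V[i, j]
            d = x_A - x_V
            log_l1 = log_norm_c1 - 0.5 * (d * d * vp + x_A * x_A * vv + x_V * x_V * va) / denom
            log_l2 = log_norm_c2 - 0.5 * (x_A * x_A * inv_va_vp + x_V * x_V * inv_vv_vp)
            if degenerate:
                post = p_common
            else:
                post = 1.0 / (1.0 + np.exp(-(log_l1 - log_l2 + logit_pc)))
            c1 = (x_A / va + x_V / vv) / w_sum
            c2_A = x_A * shrink_A
            c2_V = x_V * shrink_V
            if strategy == 0:
                out_A[i, j] = post * c1 + (1.0 - post) * c2_A
                out_V[i, j] = post * c1 + (1.0 - post) * c2_V
            else:
                threshold = criterion if strategy == 1 else xi[i, j]
                if post > threshold:
                    out_A[i, j] = c1
                    out_V[i, j] = c1
                else:
                    out_A[i, j] = c2_A
                    out_V[i, j] = c2_V
    return out_A, out_V
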