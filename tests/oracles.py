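"""Independent reference implementations used to check the estimators."""

import numpy as np
from scipy.optimize import minimize


def brute_force_reversible_mle(C: np.ndarray) -> np.ndarray:
    """Direct numerical maximization of sum c_ij ln T_ij under detailed balance.

    Parametrizes the symmetric flow matrix x (upper triangle, log scale) and
    maximizes the likelihood with a general-purpose optimizer; independent of
    the fixed-point iteration it checks.
    """
    C = np.asarray(C, float)
    n = C.shape[0]
    sym = C + C.T
    iu = [(i, j) for i in range(n) for j in range(i, n) if sym[i, j] > 0]

    def build(params):
        x = np.zeros((n, n))
        for (i, j), p in zip(iu, np.exp(params)):
            x[i, j] = p
            x[j, i] = p
        return x

    def neg_loglik(params):
        x = build(params)
        T = x / x.sum(axis=1, keepdims=True)
        mask = C > 0
        return -np.sum(C[mask] * np.log(T[mask]))

    x0 = np.log([sym[i, j] for i, j in iu])
    best = None
    for x_init in (x0, x0 + 0.3):
        res = minimize(
            neg_loglik, x_init, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 40000, "maxfev": 40000},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = build(best.x)
    return x / x.sum(axis=1, keepdims=True)
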