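"""Small dense OLS helpers used by the scan and mediation code.

All designs here are tiny (a handful of columns); everything is solved
through QR/normal equations directly. Degrees of freedom follow the
n - p convention with p counting the intercept.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["design_with_intercept", "residualizer", "coef_test", "partial_f"]


def design_with_intercept(*blocks, n=None):
    """Column-stack 1 and any non-None blocks (vectors or matrices)."""
    cols = []
    for b in blocks:
        if b is None:
            continue
        b = np.asarray(b, dtype=float)
        cols.append(b[:, None] if b.ndim == 1 else b)
        n = b.shape[0]
    if n is None:
        raise ValueError("cannot infer sample count")
    return np.column_stack([np.ones(n)] + cols)


def residualizer(G):
    """Return ``(Q, project)`` for design G; ``project(v) = v - QQ'v``."""
    Q, _ = np.linalg.qr(G)

    def project(v):
        v = np.asarray(v, dtype=float)
        return v - Q @ (Q.T @ v)

    return Q, project


def coef_test(y, Z, j):
    """OLS of y on Z; return (beta_j, se_j, t_j, two-sided p, df)."""
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    beta = np.linalg.solve(ZtZ, Zty)
    rss = float(y @ y - beta @ Zty)
    df = n - p
    if df <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({df})")
    sigma2 = max(rss, 0.0) / df
    var_j = sigma2 * np.linalg.inv(ZtZ)[j, j]
    se = np.sqrt(max(var_j, 0.0))
    if se == 0:
        t = np.inf if beta[j] != 0 else 0.0
    else:
        t = beta[j] / se
    pval = 2 * stats.t.sf(abs(t), df)
    return float(beta[j]), float(se), float(t), float(pval), df


def partial_f(y, base, x):
    """Single-df F test (and p) for adding column x to design ``base``."""
    Z = np.column_stack([base, np.asarray(x, dtype=float)])
    beta, se, t, pval, df = coef_test(y, Z, Z.shape[1] - 1)
    return t * t, pval, df
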