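"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: everything is
a direct per-site / per-element transcription of the defining formulas, so
agreement is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def fst_wright_brute(fa, fb):
    """Ratio of sums Σ(H_T − H_S)/ΣH_T, site by site."""
    num = 0.0
    den = 0.0
    for p1, p2 in zip(fa, fb):
        pbar = (p1 + p2) / 2
        ht = 2 * pbar * (1 - pbar)
        hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        num += ht - hs
        den += ht
    return num / den if den else float("nan")


def fst_hudson_brute(fa, fb, na, nb):
    """Ratio of averages of the sample-size-corrected per-site terms."""
    nums, dens = [], []
    for p1, p2, n1, n2 in zip(fa, fb, na, nb):
        q1, q2 = 1 - p1, 1 - p2
        nums.append((p1 - p2) ** 2 - p1 * q1 / (n1 - 1) - p2 * q2 / (n2 - 1))
        dens.append(p1 * q2 + p2 * q1)
    if sum(dens) == 0:
        return float("nan")
    return np.mean(nums) / np.mean(dens)


def dxy_per_site_brute(fx, fy):
    vals = [p * (1 - q) + q * (1 - p) for p, q in zip(fx, fy)]
    return float(np.mean(vals))


def dxy_literal_brute(fx, fy):
    sx_maj = sum(fx)
    sx_min = sum(1 - p for p in fx)
    sy_maj = sum(fy)
    sy_min = sum(1 - p for p in fy)
    return sx_maj * sy_min + sy_maj * sx_min


def hp_brute(fmaj):
    s_maj = sum(fmaj)
    s_min = sum(1 - p for p in fmaj)
    return 2 * s_maj * s_min / (s_maj + s_min) ** 2


def ols_brute(y, X):
    """Closed-form OLS via normal equations: returns (beta, se, t, p) per
    column of the design X (which must already include an intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), dof)
    return beta, se, t, p
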