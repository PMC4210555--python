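"""Independent brute-force references used by the tests.

Everything here is written in the most literal way possible (scalar loops,
dense matrix formulas) and never shares code with the package paths it
checks.
"""

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular


def loiselle_bruteforce(dosages: np.ndarray) -> np.ndarray:
    """Scalar-loop Loiselle estimator on a complete dosage matrix."""
    n, m = dosages.shape
    p = dosages / 2.0
    pbar = p.mean(axis=0)
    denom = sum(pbar[l] * (1 - pbar[l]) for l in range(m))
    bias = sum(pbar[l] * (1 - pbar[l]) for l in range(m)) / (n - 1)
    K = np.zeros((n, n))
    for h in range(n):
        for t in range(n):
            num = sum(
                (p[h, l] - pbar[l]) * (p[t, l] - pbar[l]) for l in range(m)
            )
            K[h, t] = (num + bias) / denom
    return K


def group_kinship_bruteforce(K: np.ndarray, labels: np.ndarray, phi: str) -> np.ndarray:
    """Double-loop evaluation of the group-kinship operator."""
    ops = {"average": np.mean, "median": np.median, "maximum": np.max}
    op = ops[phi]
    s = labels.max() + 1
    out = np.zeros((s, s))
    for i in range(s):
        gi = np.where(labels == i)[0]
        for j in range(s):
            gj = np.where(labels == j)[0]
            if i == j:
                vals = [K[h, t] for a, h in enumerate(gi) for t in gi[a:]]
            else:
                vals = [K[h, t] for h in gi for t in gj]
            out[i, j] = op(np.array(vals, dtype=float))
    return out


def reml_neg2ll_dense(y, X, V_lam):
    """-2 restricted log-likelihood with sigma_e^2 profiled out, via the
    textbook dense formula on V(lambda) = lam*H + I."""
    n, q = X.shape
    sign, logdet_V = np.linalg.slogdet(V_lam)
    if sign <= 0:
        return np.inf
    try:
        Vi = np.linalg.inv(V_lam)
    except np.linalg.LinAlgError:
        return np.inf
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    se2 = float(y @ P @ y) / (n - q)
    _, logdet_XtViX = np.linalg.slogdet(XtViX)
    return (
        (n - q) * np.log(2 * np.pi)
        + (n - q) * np.log(se2)
        + logdet_V
        + logdet_XtViX
        + (n - q)
    )


def reml_fit_dense(y, X, H, log10_bounds=(-9.0, 9.0)):
    """Maximize the dense profile REML over lambda; returns (lam, -2LL)."""
    def obj(t):
        return reml_neg2ll_dense(y, X, 10.0**t * H + np.eye(len(y)))

    grid = np.linspace(*log10_bounds, 200)
    vals = [obj(t) for t in grid]
    k = int(np.argmin(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    best = min(res.fun, vals[k])
    lam = 10.0**res.x if res.fun <= vals[k] else 10.0**grid[k]
    return lam, float(best)


def gls_marker_ftest_dense(y, X, marker, V_lam):
    """Whitening (Cholesky) + explicit OLS F-test of the marker coefficient."""
    L = np.linalg.cholesky(V_lam)
    yw = solve_triangular(L, y, lower=True)
    Aw = solve_triangular(L, np.column_stack([X, marker]), lower=True)
    n, k = Aw.shape
    beta, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    r = yw - Aw @ beta
    sse = float(r @ r)
    df2 = n - k
    C = np.linalg.inv(Aw.T @ Aw)
    F = beta[-1] ** 2 / (C[-1, -1] * sse / df2)
    return float(F), float(stats.f.sf(F, 1, df2))
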