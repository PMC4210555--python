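"""REML fitting and marker tests for the (compressed) mixed linear model.

Model: y = X beta + Z u + e, with u ~ N(0, G), G = 2 K sigma_a^2 at the
group level, and e ~ N(0, I sigma_e^2).  Writing lambda = sigma_a^2 /
sigma_e^2 and H = 2 Z K Z', the phenotypic covariance is
V = sigma_e^2 (lambda H + I).

The REML -2 log-likelihood is profiled in lambda through a one-time
spectral decomposition: with Q an orthonormal basis of the complement of
col(X) and A = Q' H Q = W diag(xi) W', eta = W' Q' y,

    -2LL(lambda) = (n-q)(log 2 pi + 1) + log|X'X|
                   + (n-q) log( sum eta_i^2/(1+lambda xi_i) / (n-q) )
                   + sum log(1 + lambda xi_i)

which matches the dense form log|V| + log|X'V^-1 X| + y'Py + (n-q)log 2pi
at the profiled residual variance, and costs O(n-q) per lambda after the
decomposition.  Lambda is maximized on a log grid over [1e-9, 1e9]
followed by bounded scalar refinement.

Marker tests use P3D: variance components are estimated once without
markers and held fixed; each marker enters as a fixed effect and is
tested by a Wald F-test under generalized least squares with covariance
V(lambda_hat), df1 = 1, df2 = n - rank([X | marker]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, qr, solve_triangular

__all__ = [
    "VarianceComponents",
    "MixedModelFit",
    "AssociationResult",
    "REMLWorkspace",
    "neg2_reml_loglik",
    "reml_fit",
    "marker_ftest",
]

LAMBDA_BOUNDS = (1e-9, 1e9)
_GRID_SIZE = 100


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    neg2LL: float

    @property
    def lam(self) -> float:
        """Variance ratio lambda = sigma_a^2 / sigma_e^2."""
        return self.sigma_a2 / self.sigma_e2


@dataclass
class MixedModelFit:
    vc: VarianceComponents
    beta_hat: np.ndarray
    u_hat: np.ndarray


@dataclass
class AssociationResult:
    marker_id: str
    chrom: object
    pos: int
    maf: float
    effect: float
    F: float
    df1: int
    df2: int
    p_value: float
    testable: bool = True


class REMLWorkspace:
    """Caches everything about (y, X) reused across many (Z, K) fits.

    Building the null-space basis of X and log|X'X| once makes a full
    compression-profile search (hundreds of REML fits on the same
    phenotype) cheap: each fit only needs one symmetric eigendecomposition
    of size n - q.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray):
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(y).all():
            raise ValueError("phenotype contains non-finite values")
        n, q = X.shape
        if np.linalg.matrix_rank(X) < q:
            raise ValueError("fixed-effect design X is rank deficient")
        self.y, self.X, self.n, self.q = y, X, n, q
        Qfull, _ = qr(X, mode="full")
        self.Qc = Qfull[:, q:]  # orthonormal basis of col(X)^perp
        _, logdet = np.linalg.slogdet(X.T @ X)
        self.logdet_XtX = float(logdet)
        self.Qc_y = self.Qc.T @ y
        self.const = (n - q) * (np.log(2.0 * np.pi) + 1.0) + self.logdet_XtX

    def spectrum(self, H: np.ndarray):
        """Eigenvalues/rotated data of Q' H Q; returns (xi, eta)."""
        A = self.Qc.T @ H @ self.Qc
        xi, W = np.linalg.eigh(0.5 * (A + A.T))
        xi = np.where(xi < 0.0, 0.0, xi)  # H is PSD up to the ridge tolerance
        return xi, W.T @ self.Qc_y

    def neg2ll_from_spectrum(self, xi, eta, lam: float) -> float:
        if not np.isfinite(lam):
            return np.inf
        w = 1.0 + lam * xi
        if np.any(w <= 0.0):
            return np.inf
        nq = self.n - self.q
        rss = float(np.sum(eta**2 / w))
        if rss <= 0.0:
            return np.inf
        return self.const + nq * np.log(rss / nq) + float(np.sum(np.log(w)))


def _random_cov(Z: np.ndarray, K_group: np.ndarray) -> np.ndarray:
    """H = 2 Z K Z' — covariance of the group effects at unit sigma_a^2."""
    return 2.0 * (Z @ K_group @ Z.T)


def neg2_reml_loglik(y, X, Z, K_group, lam: float) -> float:
    """Profile REML -2 log-likelihood at variance ratio ``lam``.

    Returns +inf (never raises) when V(lam) is singular or indefinite, so
    grid searches can simply skip such points.
    """
    ws = REMLWorkspace(y, X)
    xi, eta = ws.spectrum(_random_cov(np.asarray(Z, float), np.asarray(K_group, float)))
    return ws.neg2ll_from_spectrum(xi, eta, lam)


def _fit_from_spectrum(ws: REMLWorkspace, xi, eta) -> tuple[float, float]:
    """Maximize the profile REML likelihood over lambda; returns (lam, -2LL)."""
    lo, hi = LAMBDA_BOUNDS
    grid = np.logspace(np.log10(lo), np.log10(hi), _GRID_SIZE)
    vals = np.array([ws.neg2ll_from_spectrum(xi, eta, l) for l in grid])
    k = int(np.argmin(vals))
    left = grid[max(k - 1, 0)]
    right = grid[min(k + 1, grid.size - 1)]
    if left == right:
        return float(grid[k]), float(vals[k])
    res = optimize.minimize_scalar(
        lambda t: ws.neg2ll_from_spectrum(xi, eta, 10.0**t),
        bounds=(np.log10(left), np.log10(right)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    lam, val = 10.0**res.x, float(res.fun)
    if vals[k] < val:  # keep the grid point if refinement did not improve
        lam, val = float(grid[k]), float(vals[k])
    return lam, val


def reml_fit(y, X, Z, K_group, workspace: REMLWorkspace | None = None) -> MixedModelFit:
    """REML estimation of (sigma_a^2, sigma_e^2) plus BLUE and group BLUPs."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.asarray(Z, dtype=float)
    K_group = np.asarray(K_group, dtype=float)
    ws = workspace if workspace is not None else REMLWorkspace(y, X)
    xi, eta = ws.spectrum(_random_cov(Z, K_group))
    lam, neg2ll = _fit_from_spectrum(ws, xi, eta)
    w = 1.0 + lam * xi
    sigma_e2 = float(np.sum(eta**2 / w)) / (ws.n - ws.q)
    vc = VarianceComponents(lam * sigma_e2, sigma_e2, neg2ll)
    # BLUE / BLUP at lambda-hat via dense GLS (one n x n solve)
    Vl = lam * _random_cov(Z, K_group) + np.eye(ws.n)
    c = cho_factor(0.5 * (Vl + Vl.T))
    Vi_X = cho_solve(c, X)
    Vi_y = cho_solve(c, y)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    resid = y - X @ beta
    u = 2.0 * lam * (K_group @ (Z.T @ cho_solve(c, resid)))
    return MixedModelFit(vc, beta, u)


def marker_ftest(
    y,
    X,
    marker_dosage,
    Z,
    K_group,
    vc: VarianceComponents,
    marker_meta: dict | None = None,
) -> AssociationResult:
    """P3D F-test of one marker as a fixed effect under V(lambda-hat).

    Individuals missing at the marker are dropped (covariance subset
    accordingly).  A marker collinear with X (e.g. monomorphic in the
    analyzed individuals) is flagged untestable with p = 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = np.asarray(marker_dosage, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    meta = marker_meta or {}
    keep = np.isfinite(m)
    y, X, m, Z = y[keep], X[keep], m[keep], Z[keep]
    n = y.size
    obs = m[np.isfinite(m)]
    maf = float(np.mean(obs) / 2.0) if obs.size else float("nan")
    maf = min(maf, 1.0 - maf)
    lam = vc.lam
    Vl = lam * _random_cov(Z, np.asarray(K_group, float)) + np.eye(n)
    L = np.linalg.cholesky(0.5 * (Vl + Vl.T))
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    mw = solve_triangular(L, m, lower=True)
    return _wald_f(yw, Xw, mw, meta, maf)


def _wald_f(yw, Xw, mw, meta: dict, maf: float) -> AssociationResult:
    """OLS F-test of the marker coefficient on whitened data."""
    n, q = Xw.shape
    Qx, _ = qr(Xw, mode="economic")
    r_m = mw - Qx @ (Qx.T @ mw)
    r_y = yw - Qx @ (Qx.T @ yw)
    mm = float(r_m @ r_m)
    df2 = n - q - 1
    base = dict(
        marker_id=meta.get("id", ""),
        chrom=meta.get("chrom", 0),
        pos=int(meta.get("pos", 0)),
        maf=maf,
        df1=1,
        df2=df2,
    )
    if mm <= 1e-10 * max(float(mw @ mw), 1.0) or df2 <= 0:
        return AssociationResult(
            **base, effect=float("nan"), F=float("nan"), p_value=1.0, testable=False
        )
    beta = float(r_m @ r_y) / mm
    sse = float(r_y @ r_y) - beta**2 * mm
    sse = max(sse, 0.0)
    if sse <= 0.0:
        return AssociationResult(
            **base, effect=beta, F=float("inf"), p_value=np.nextafter(0, 1), testable=True
        )
    F = beta**2 * mm / (sse / df2)
    p = float(stats.f.sf(F, 1, df2))
    return AssociationResult(**base, effect=beta, F=F, p_value=max(p, 5e-324))


def neg2_reml_loglik_dense(y, X, Z, K_group, lam: float) -> float:
    """Direct dense evaluation of log|V| + log|X'V^-1 X| + y'Py + (n-q) log 2pi
    at the profiled residual variance (V = sigma_e^2 (lam H + I)).

    O(n^3) per call; a validation reference for the spectral path.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, q = X.shape
    Vl = lam * _random_cov(np.asarray(Z, float), np.asarray(K_group, float)) + np.eye(n)
    sign, logdet_Vl = np.linalg.slogdet(Vl)
    if sign <= 0:
        return np.inf
    Vi = np.linalg.inv(Vl)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    sigma_e2 = float(y @ P @ y) / (n - q)
    _, logdet_XtViX = np.linalg.slogdet(XtViX)
    # log|V| = n log se2 + log|Vl|; log|X'V^-1 X| = log|X'Vl^-1 X| - q log se2
    # y'Py at the profiled se2 equals (n - q)
    return (
        (n - q) * np.log(2.0 * np.pi)
        + (n - q) * np.log(sigma_e2)
        + logdet_Vl
        + logdet_XtViX
        + (n - q)
    )
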