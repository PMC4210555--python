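"""Empirical power protocol: QTN spiking with per-method empirical thresholds.

A QTN effect of d phenotypic standard deviations is added to the observed
phenotype at each marker in turn; each spiked phenotype is rescanned and
the spiked marker counts as detected when its p-value falls at or below
the method's empirical threshold — the bottom alpha-quantile (default 5%)
of the p-values from a scan of the original, unspiked phenotype.  The
proportion of detected QTNs across markers estimates power; because the
spike is added to a real (or realistically simulated) phenotype, the
simulated trait retains the panel's genetic architecture.

Methods are compression endpoints/searches of the same mixed model:
GLM (one group, s = 1), MLM (singleton groups, s = n), CMLM (UPGMA +
average group kinship, optimized over s) and ECMLM (all 24 linkage x
operator combinations, optimized jointly).

Variance components per method are fitted once on the unspiked phenotype
(P3D) and reused for the null scan and for every spiked scan, which makes
the m spiked rescans a closed-form update of one whitened cross-product
set rather than m model fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compression import LINKAGES
from .datatypes import CovariateTable, GenotypeMatrix, PhenotypeVector, design_matrix
from .kinship import KinshipMatrix, loiselle_kinship
from .mlm import REMLWorkspace, reml_fit
from .optimizer import DEFAULT_LEVELS, CompressionConfig, optimize_compression
from .scan import build_group_model, gram_ftests, whiten

__all__ = [
    "METHODS",
    "PowerSpec",
    "PowerCurve",
    "PowerStudy",
    "spike_qtn",
    "empirical_threshold",
    "estimate_power",
    "variance_explained",
    "power_fdr_curve",
]

METHODS = ("GLM", "MLM", "CMLM", "ECMLM")


@dataclass
class PowerSpec:
    """Settings of one power experiment."""

    d: float = 0.0
    methods: tuple = METHODS
    alpha: float = 0.05
    seeds: int = 1

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("QTN effect d must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PowerCurve:
    """Per-method power against effect size and against FDR."""

    power_by_d: pd.DataFrame  # columns: method, d, power
    power_by_fdr: pd.DataFrame  # columns: method, d, cutoff, fdr, power
    threshold_p: dict = field(default_factory=dict)


def spike_qtn(y: PhenotypeVector, marker_dosage: np.ndarray, d: float) -> PhenotypeVector:
    """Add a QTN of size d phenotypic SDs at one marker: y' = y + d sd_y x."""
    if d < 0:
        raise ValueError("QTN effect d must be >= 0")
    x = np.asarray(marker_dosage, dtype=float).ravel()
    y2 = y.y + d * y.sd_y * x
    return PhenotypeVector(y2, y.trait_name, list(y.individual_ids))


def empirical_threshold(null_pvalues: np.ndarray, alpha: float = 0.05) -> float:
    """Bottom alpha-quantile of the null scan's p-values (type-1 quantile).

    Exactly floor(alpha * m) of the null markers fall at or below the
    returned threshold (barring ties), so the null detection rate is
    floor(alpha * m)/m by construction.
    """
    p = np.sort(np.asarray(null_pvalues, dtype=float).ravel())
    m = p.size
    if m < 20:
        warnings.warn("fewer than 20 markers: empirical quantile is unstable")
    k = int(np.floor(alpha * m))
    if k < 1:
        return 0.0
    return float(p[k - 1])


def variance_explained(p: float, d: float) -> float:
    """Proportion of phenotypic variance explained by a QTN.

    pi = 1 / (1 + 1/(p(1-p)d^2)) for allele frequency p and an allele
    substitution difference of d phenotypic SDs between the two allele
    classes (a {0,1}-coded locus); pi -> 0 as d -> 0.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency p must be in (0, 1)")
    if d < 0:
        raise ValueError("d must be >= 0")
    if d == 0.0:
        return 0.0
    v = p * (1.0 - p) * d * d
    return v / (1.0 + v)


class PowerStudy:
    """Shared state for power estimation across methods and effect sizes.

    Fits each method's compression configuration and variance components
    once on the unspiked phenotype, then answers power queries at any d
    from cached whitened cross-products.
    """

    def __init__(
        self,
        g: GenotypeMatrix,
        y: PhenotypeVector,
        X: CovariateTable | None = None,
        methods=METHODS,
        alpha: float = 0.05,
        levels=DEFAULT_LEVELS,
        K: KinshipMatrix | None = None,
    ):
        self.g, self.y, self.alpha = g, y, alpha
        self.K = K if K is not None else loiselle_kinship(g)
        self.Xd = design_matrix(g.n_individuals, X)
        self.methods = tuple(methods)
        self.configs: dict[str, CompressionConfig] = {}
        self._cache: dict[str, dict] = {}
        ws = REMLWorkspace(y.y, self.Xd)
        for method in self.methods:
            cfg = self._config_for(method, ws, levels)
            self.configs[method] = cfg
            self._cache[method] = self._prepare(cfg)

    def _config_for(self, method: str, ws: REMLWorkspace, levels) -> CompressionConfig:
        n = self.g.n_individuals
        if method in ("GLM", "MLM"):
            s = 1 if method == "GLM" else n
            cfg = CompressionConfig("UPGMA", "average", s, n / s, vc=None)
            gm = build_group_model(self.K, cfg)
            fit = reml_fit(ws.y, ws.X, gm.Z, gm.K_group, workspace=ws)
            cfg.vc = fit.vc
            return cfg
        if method == "CMLM":
            return optimize_compression(
                ws.y, ws.X, self.K, linkages=("UPGMA",), phis=("average",), levels=levels
            )
        if method == "ECMLM":
            return optimize_compression(
                ws.y, ws.X, self.K, linkages=tuple(LINKAGES), levels=levels
            )
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")

    def _prepare(self, cfg: CompressionConfig) -> dict:
        """Whitened cross-products for closed-form spiked rescans."""
        gm = build_group_model(self.K, cfg)
        M = self.g.imputed()
        yw, Xw, Mw = whiten(self.y.y, self.Xd, M, gm.Z, gm.K_group, cfg.vc.lam)
        from scipy.linalg import qr

        n, q = Xw.shape
        Qx, _ = qr(Xw, mode="economic")
        R = Mw - Qx @ (Qx.T @ Mw)
        r_y = yw - Qx @ (Qx.T @ yw)
        G = R.T @ R
        gkk = np.diag(G).copy()
        scale = np.maximum(np.einsum("ij,ij->j", Mw, Mw), 1.0)
        testable = gkk > 1e-10 * scale
        v = R.T @ r_y
        df2 = n - q - 1
        null_p = self._pvals(v, float(r_y @ r_y), gkk, df2, testable)
        thr = empirical_threshold(null_p[testable], self.alpha)
        return dict(
            G=G,
            gkk=gkk,
            v=v,
            yy=float(r_y @ r_y),
            df2=df2,
            testable=testable,
            null_p=null_p,
            threshold=thr,
        )

    @staticmethod
    def _pvals(v, yy, gkk, df2, testable):
        with np.errstate(divide="ignore", invalid="ignore"):
            beta2g = np.where(testable, v**2 / np.where(testable, gkk, 1.0), 0.0)
            sse = np.maximum(yy - beta2g, 0.0)
            F = np.where(sse > 0, beta2g / (sse / df2), np.inf)
            p = stats.f.sf(F, 1, df2)
        return np.where(testable, np.maximum(p, 5e-324), 1.0)

    def threshold(self, method: str) -> float:
        return self._cache[method]["threshold"]

    def spiked_self_pvalues(self, method: str, d: float) -> np.ndarray:
        """p-value of marker j when the QTN of size d is spiked at j."""
        c = self._cache[method]
        amp = d * self.y.sd_y
        v2 = c["v"] + amp * c["gkk"]
        yy2 = c["yy"] + 2.0 * amp * c["v"] + amp**2 * c["gkk"]
        t = c["testable"]
        with np.errstate(divide="ignore", invalid="ignore"):
            beta2g = np.where(t, v2**2 / np.where(t, c["gkk"], 1.0), 0.0)
            sse = np.maximum(yy2 - beta2g, 0.0)
            F = np.where(sse > 0, beta2g / (sse / c["df2"]), np.inf)
            p = stats.f.sf(F, 1, c["df2"])
        return np.where(t, np.maximum(p, 5e-324), 1.0)

    def spiked_pvalue_matrix(self, method: str, d: float) -> np.ndarray:
        """P[j, k]: p-value of marker k under the phenotype spiked at j."""
        c = self._cache[method]
        amp = d * self.y.sd_y
        G, gkk, v, yy, df2, t = (
            c["G"], c["gkk"], c["v"], c["yy"], c["df2"], c["testable"],
        )
        V2 = v[None, :] + amp * G  # row j: spiked at j
        yy2 = yy + 2.0 * amp * v + amp**2 * gkk  # per spike j
        safe = np.where(t, gkk, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta2g = np.where(t[None, :], V2**2 / safe[None, :], 0.0)
            sse = np.maximum(yy2[:, None] - beta2g, 0.0)
            F = np.where(sse > 0, beta2g / (sse / df2), np.inf)
            P = stats.f.sf(F, 1, df2)
        return np.where(t[None, :], np.maximum(P, 5e-324), 1.0)

    def power(self, method: str, d: float) -> float:
        """Fraction of spiked QTNs detected at the method's threshold."""
        c = self._cache[method]
        p = self.spiked_self_pvalues(method, d)
        t = c["testable"]
        return float(np.mean(p[t] <= c["threshold"]))

    def fdr_curve(self, method: str, d: float, n_cut: int = 400) -> pd.DataFrame:
        """Power and empirical FDR over a grid of p-value cutoffs.

        For each cutoff t: power = fraction of spike replicates where the
        spiked marker is detected; FDR = detections of non-spiked markers
        over all detections, pooled across replicates (the spiked marker
        is excluded from the false-positive count).
        """
        P = self.spiked_pvalue_matrix(method, d)
        t = self._cache[method]["testable"]
        P = P[np.ix_(t, t)]
        diag = np.diag(P)
        m = P.shape[0]
        lo = max(P.min() / 2.0, 5e-324)
        cuts = np.unique(
            np.concatenate([np.geomspace(lo, 1.0, n_cut), diag, [1.0]])
        )
        total = np.searchsorted(np.sort(P.ravel()), cuts, side="right")
        true = np.searchsorted(np.sort(diag), cuts, side="right")
        with np.errstate(invalid="ignore", divide="ignore"):
            fdr = np.where(total > 0, (total - true) / total, 0.0)
        return pd.DataFrame(
            {"cutoff": cuts, "fdr": fdr, "power": true / m}
        )

    @staticmethod
    def power_at_fdr(curve: pd.DataFrame, q: float) -> float:
        """Highest power achievable at FDR <= q (sup over cutoffs)."""
        ok = curve["fdr"].to_numpy() <= q
        return float(curve["power"].to_numpy()[ok].max()) if ok.any() else 0.0


def estimate_power(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    X: CovariateTable | None,
    method: str,
    d: float,
    alpha: float = 0.05,
) -> float:
    """Convenience wrapper: power of one method at one effect size."""
    return PowerStudy(g, y, X, methods=(method,), alpha=alpha).power(method, d)


def power_fdr_curve(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    X: CovariateTable | None,
    methods=METHODS,
    d: float = 0.5,
    alpha: float = 0.05,
) -> PowerCurve:
    """Power vs effect size and vs FDR for a set of methods at one d."""
    study = PowerStudy(g, y, X, methods=methods, alpha=alpha)
    rows_d, rows_fdr = [], []
    for method in methods:
        rows_d.append({"method": method, "d": d, "power": study.power(method, d)})
        curve = study.fdr_curve(method, d)
        curve.insert(0, "d", d)
        curve.insert(0, "method", method)
        rows_fdr.append(curve)
    return PowerCurve(
        pd.DataFrame(rows_d),
        pd.concat(rows_fdr, ignore_index=True),
        {m: study.threshold(m) for m in methods},
    )
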