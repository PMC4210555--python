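"""Full association scan: optimize once without markers (P3D), then test
every marker by an F-test with variance components held fixed.

The scan whitens the data once with the Cholesky factor of V(lambda-hat)
and tests all complete markers in a single vectorized pass; markers with
missing calls fall back to the per-marker path, which subsets the
covariance.  Markers monomorphic in the analyzed individuals are
reported untestable (p = 1) rather than dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr, solve_triangular
from statsmodels.stats.multitest import multipletests

from .compression import (
    GroupAssignment,
    GroupModel,
    cut_to_groups,
    group_kinship,
    hierarchical_cluster,
    kinship_to_distance,
)
from .datatypes import CovariateTable, GenotypeMatrix, PhenotypeVector, design_matrix
from .kinship import KinshipMatrix, loiselle_kinship
from .mlm import REMLWorkspace, marker_ftest, reml_fit
from .optimizer import CompressionConfig, optimize_compression

logger = logging.getLogger(__name__)

__all__ = ["scan", "pca_covariates", "build_group_model"]

RESULT_COLUMNS = [
    "marker",
    "chrom",
    "pos",
    "maf",
    "effect",
    "F",
    "df1",
    "df2",
    "p_value",
    "testable",
]


def build_group_model(K: KinshipMatrix, config: CompressionConfig) -> GroupModel:
    """Materialize the (clustering, cut, group kinship) of a config."""
    n = K.n
    if config.s == n:
        a = GroupAssignment(np.arange(n), n)
    elif config.s == 1:
        a = GroupAssignment(np.zeros(n, dtype=int), 1)
    else:
        tree = hierarchical_cluster(kinship_to_distance(K), config.linkage)
        a = cut_to_groups(tree, config.s)
    return group_kinship(K, a, config.phi, config.linkage)


def scan(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    X: CovariateTable | None = None,
    config: CompressionConfig | str = "auto",
    K: KinshipMatrix | None = None,
    qvalues: bool = True,
) -> pd.DataFrame:
    """P3D association scan over all markers.

    Parameters
    ----------
    config
        A fitted :class:`CompressionConfig`, or ``"auto"`` to run the full
        24-combination optimization first.
    K
        Individual kinship; estimated from ``g`` (Loiselle) when omitted.

    Returns
    -------
    DataFrame sorted by (chrom, pos) with one row per marker; includes a
    Benjamini-Hochberg ``q_value`` column when ``qvalues`` is true.
    """
    if K is None:
        K = loiselle_kinship(g)
    Xd = design_matrix(g.n_individuals, X)
    if isinstance(config, str):
        if config != "auto":
            raise ValueError("config must be a CompressionConfig or 'auto'")
        config = optimize_compression(y.y, Xd, K)
    gm = build_group_model(K, config)
    ws = REMLWorkspace(y.y, Xd)
    fit = reml_fit(y.y, Xd, gm.Z, gm.K_group, workspace=ws)
    vc = fit.vc
    logger.info(
        "scan config: linkage=%s phi=%s s=%d level=%.2f -2LL=%.4f sa2=%.4g se2=%.4g",
        config.linkage,
        config.phi,
        config.s,
        config.compression_level,
        vc.neg2LL,
        vc.sigma_a2,
        vc.sigma_e2,
    )
    rows = _scan_markers(g, y.y, Xd, gm, vc)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not table["testable"].any():
        raise ValueError("no testable markers in the analyzed individuals")
    table = table.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    if qvalues:
        q = np.full(len(table), np.nan)
        mask = table["testable"].to_numpy()
        if mask.any():
            q[mask] = multipletests(
                table.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
        table["q_value"] = q
    return table


def _scan_markers(g, y, Xd, gm, vc) -> list[dict]:
    n, q = Xd.shape
    M = g.values
    complete = np.isfinite(M).all(axis=0)
    maf = g.minor_allele_freq
    rows: list[dict] = [None] * g.n_markers  # type: ignore[list-item]

    if complete.any():
        yw, Xw, Mw = whiten(y, Xd, M[:, complete], gm.Z, gm.K_group, vc.lam)
        eff, F, p, df2, ok = gram_ftests(yw, Xw, Mw)
        for out_i, j in enumerate(np.where(complete)[0]):
            rec = g.markers.iloc[j]
            rows[j] = {
                "marker": rec["id"],
                "chrom": rec["chrom"],
                "pos": int(rec["pos"]),
                "maf": float(maf[j]),
                "effect": float(eff[out_i]),
                "F": float(F[out_i]),
                "df1": 1,
                "df2": int(df2),
                "p_value": float(p[out_i]),
                "testable": bool(ok[out_i]),
            }
    for j in np.where(~complete)[0]:
        rec = g.markers.iloc[j]
        res = marker_ftest(
            y,
            Xd,
            M[:, j],
            gm.Z,
            gm.K_group,
            vc,
            marker_meta={"id": rec["id"], "chrom": rec["chrom"], "pos": rec["pos"]},
        )
        rows[j] = {
            "marker": res.marker_id,
            "chrom": res.chrom,
            "pos": res.pos,
            "maf": res.maf,
            "effect": res.effect,
            "F": res.F,
            "df1": res.df1,
            "df2": res.df2,
            "p_value": res.p_value,
            "testable": res.testable,
        }
    return rows


def whiten(y, Xd, M, Z, K_group, lam):
    """Transform (y, X, markers) by the inverse Cholesky of V(lambda)."""
    n = y.size
    Vl = 2.0 * lam * (Z @ K_group @ Z.T) + np.eye(n)
    L = np.linalg.cholesky(0.5 * (Vl + Vl.T))
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, Xd, lower=True)
    Mw = solve_triangular(L, M, lower=True)
    return yw, Xw, Mw


def gram_ftests(yw, Xw, Mw):
    """Vectorized GLS F-tests of each (whitened) marker given X.

    Returns (effect, F, p, df2, testable) arrays; untestable markers
    (collinear with X after whitening) get F = nan, p = 1.
    """
    n, q = Xw.shape
    Qx, _ = qr(Xw, mode="economic")
    R = Mw - Qx @ (Qx.T @ Mw)
    r_y = yw - Qx @ (Qx.T @ yw)
    gkk = np.einsum("ij,ij->j", R, R)
    v = R.T @ r_y
    yy = float(r_y @ r_y)
    df2 = n - q - 1
    scale = np.maximum(np.einsum("ij,ij->j", Mw, Mw), 1.0)
    ok = gkk > 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, v / np.where(ok, gkk, 1.0), np.nan)
        sse = np.maximum(yy - beta**2 * gkk, 0.0)
        F = np.where(sse > 0, beta**2 * gkk / (sse / df2), np.inf)
        p = stats.f.sf(F, 1, df2)
    p = np.where(ok, np.maximum(p, 5e-324), 1.0)
    F = np.where(ok, F, np.nan)
    return beta, F, p, df2, ok


def pca_covariates(g: GenotypeMatrix, k: int) -> CovariateTable:
    """First k principal components of the column-centered dosage matrix.

    Deterministic up to machine precision: each component's sign is fixed
    so that its largest-magnitude marker loading is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= g.n_individuals:
        raise ValueError("k must be smaller than the number of individuals")
    Xc = g.imputed()
    Xc = Xc - Xc.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = (U * S)[:, :k] * signs[:k]
    return CovariateTable(
        scores, [f"PC{i + 1}" for i in range(k)], list(g.individual_ids)
    )
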