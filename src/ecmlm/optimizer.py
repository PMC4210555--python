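"""Joint optimization over clustering algorithm, compression level and
group-kinship operator.

The likelihood of the compressed model depends on three extra parameters:
the clustering algorithm g (8 linkages), the number of groups s, and the
group-kinship operator phi (average/median/maximum).  The search
evaluates the REML -2LL of every combination — 24 (g, phi) pairs by a
grid of compression levels (up to 16 individuals per group by default) —
and returns the best-fitting configuration.  Each linkage's merge tree is
built once and cut repeatedly, so the whole search is a few hundred REML
fits sharing one spectral workspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compression import (
    LINKAGES,
    PHI_OPERATORS,
    cut_all,
    group_kinship,
    hierarchical_cluster,
    kinship_to_distance,
)
from .kinship import KinshipMatrix
from .mlm import REMLWorkspace, VarianceComponents, reml_fit

__all__ = ["DEFAULT_LEVELS", "CompressionConfig", "compression_profile", "optimize_compression"]

# target average group sizes, mirroring profiles up to 16 individuals/group
DEFAULT_LEVELS = (1, 1.5, 2, 2.5, 3, 4, 5, 6, 8, 10, 12, 14, 16)


@dataclass
class CompressionConfig:
    """A point in the (g, s, phi) space with its fitted variance components."""

    linkage: str
    phi: str
    s: int
    compression_level: float
    vc: VarianceComponents
    search_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def neg2LL(self) -> float:
        return self.vc.neg2LL


def _levels_to_s(n: int, levels) -> list[int]:
    s_vals = {min(max(int(round(n / lv)), 1), n) for lv in levels}
    # both endpoints always evaluated: s=n is the standard MLM and s=1 the
    # GLM, so the optimized fit can never be worse than either
    s_vals |= {1, n}
    return sorted(s_vals, reverse=True)


def compression_profile(
    y,
    X,
    K: KinshipMatrix,
    linkage: str,
    phi: str,
    levels=DEFAULT_LEVELS,
    workspace: REMLWorkspace | None = None,
    tree: np.ndarray | None = None,
) -> pd.DataFrame:
    """REML fit at every compression level for one (linkage, phi) pair.

    Returns a table with one row per distinct group count s, sorted by
    compression level n/s ascending.
    """
    ws = workspace if workspace is not None else REMLWorkspace(y, np.atleast_2d(X))
    if tree is None:
        tree = hierarchical_cluster(kinship_to_distance(K), linkage)
    n = K.n
    s_vals = _levels_to_s(n, levels)
    cuts = cut_all(tree, s_vals)
    rows = []
    for s in s_vals:
        gm = group_kinship(K, cuts[s], phi, linkage)
        fit = reml_fit(ws.y, ws.X, gm.Z, gm.K_group, workspace=ws)
        rows.append(
            {
                "linkage": linkage,
                "phi": phi,
                "s": s,
                "compression_level": n / s,
                "neg2LL": fit.vc.neg2LL,
                "sigma_a2": fit.vc.sigma_a2,
                "sigma_e2": fit.vc.sigma_e2,
                "lambda": fit.vc.lam,
                "psd_ridge": gm.psd_ridge,
            }
        )
    return pd.DataFrame(rows).sort_values("compression_level", ignore_index=True)


def optimize_compression(
    y,
    X,
    K: KinshipMatrix,
    linkages=tuple(LINKAGES),
    phis=PHI_OPERATORS,
    levels=DEFAULT_LEVELS,
) -> CompressionConfig:
    """Exhaustive search over (linkage, phi, level); returns the best config.

    Ties in -2LL are broken toward the larger compression level (cheaper
    downstream scans), then by linkage order as listed, then by phi order
    average < median < maximum.  The full search table is attached to the
    returned config for reporting.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ws = REMLWorkspace(y, X)
    dist = kinship_to_distance(K)
    tables = []
    for linkage in linkages:
        tree = hierarchical_cluster(dist, linkage)
        for phi in phis:
            tables.append(
                compression_profile(y, X, K, linkage, phi, levels, workspace=ws, tree=tree)
            )
    table = pd.concat(tables, ignore_index=True)
    link_rank = {name: k for k, name in enumerate(linkages)}
    phi_rank = {name: k for k, name in enumerate(PHI_OPERATORS)}
    ranked = table.assign(
        _lr=table["linkage"].map(link_rank),
        _pr=table["phi"].map(phi_rank),
        _neg_level=-table["compression_level"],
    ).sort_values(["neg2LL", "_neg_level", "_lr", "_pr"], kind="stable")
    best = ranked.iloc[0]
    vc = VarianceComponents(best["sigma_a2"], best["sigma_e2"], best["neg2LL"])
    return CompressionConfig(
        linkage=best["linkage"],
        phi=best["phi"],
        s=int(best["s"]),
        compression_level=float(best["compression_level"]),
        vc=vc,
        search_table=table,
    )
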