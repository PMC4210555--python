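"""Marker-based individual kinship (Loiselle moment estimator).

The pairwise coancestry between individuals h and t is estimated from
biallelic dosage codes as

    k_ht = [ sum_l (p_hl - pbar_l)(p_tl - pbar_l) + sum_l pbar_l(1-pbar_l)/(n-1) ]
           / sum_l pbar_l(1 - pbar_l)

where p_hl = dosage/2 is the individual allele frequency at locus l and
pbar_l the panel mean frequency.  Biallelic loci contribute two alleles
whose terms are identical, so the factor of two cancels in the ratio.
The (n-1) term is the standard small-sample bias correction.  Negative
estimates are retained: the compression operators (median, maximum) and
REML accept any symmetric matrix, and truncation would distort their
orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = ["KinshipMatrix", "loiselle_kinship", "kinship_summary"]


@dataclass
class KinshipMatrix:
    """Symmetric n x n relatedness matrix with row/column labels."""

    values: np.ndarray
    individual_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric (tol 1e-12)")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index])


def loiselle_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Estimate pairwise kinship from markers by the Loiselle moment estimator.

    Missing dosages are imputed to the marker mean (kinship only — the
    association tests handle missingness themselves).  Monomorphic markers
    contribute zero to numerator and denominator and are harmless, but at
    least one polymorphic marker is required.

    Raises
    ------
    ValueError
        If fewer than 2 individuals or all markers are monomorphic.
    """
    n = g.n_individuals
    if n < 2:
        raise ValueError("kinship requires at least 2 individuals")
    p = g.imputed() / 2.0  # individual allele frequencies, n x m
    pbar = p.mean(axis=0)
    het = pbar * (1.0 - pbar)
    denom = het.sum()
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic; kinship undefined")
    dev = p - pbar
    bias = het.sum() / (n - 1.0)
    K = (dev @ dev.T + bias) / denom
    K = 0.5 * (K + K.T)
    return KinshipMatrix(K, list(g.individual_ids))


def kinship_summary(K: KinshipMatrix) -> dict:
    """Diagnostics: off-diagonal range/mean and the minimum eigenvalue."""
    v = K.values
    off = v[~np.eye(v.shape[0], dtype=bool)]
    eigmin = float(np.linalg.eigvalsh(v)[0]) if v.shape[0] else float("nan")
    return {
        "n": v.shape[0],
        "offdiag_min": float(off.min()) if off.size else float("nan"),
        "offdiag_max": float(off.max()) if off.size else float("nan"),
        "offdiag_mean": float(off.mean()) if off.size else float("nan"),
        "min_eigenvalue": eigmin,
    }
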