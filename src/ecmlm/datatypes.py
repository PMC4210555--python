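"""Core in-memory containers shared across the package.

Genotypes are held as minor-allele dosage codes in {0, 1, 2} with NaN as the
missing sentinel; all downstream modules (kinship, scanning, power
simulation) consume these containers and never touch files directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """n individuals x m biallelic markers, coded as minor-allele dosage.

    Attributes
    ----------
    values : ndarray, shape (n, m)
        Dosage of the minor allele, {0, 1, 2}; NaN marks missing calls.
    individual_ids : list of str
        Unique individual labels, row order of ``values``.
    markers : DataFrame
        One row per marker with columns ``id``, ``chrom``, ``pos``
        (1-based bp) and ``monomorphic`` (bool flag, set by readers).
    """

    values: np.ndarray
    individual_ids: list
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValueError("individual_ids length does not match rows")
        if len(self.markers) != self.values.shape[1]:
            raise ValueError("marker table length does not match columns")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        if self.markers["id"].duplicated().any():
            raise ValueError("marker ids must be unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if "monomorphic" not in self.markers.columns:
            self.markers = self.markers.assign(
                monomorphic=[self._is_monomorphic(j) for j in range(self.n_markers)]
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def _is_monomorphic(self, j: int) -> bool:
        col = self.values[:, j]
        col = col[np.isfinite(col)]
        return col.size == 0 or np.all(col == col[0])

    @property
    def minor_allele_freq(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing calls (<= 0.5)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.values, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries filled by the marker mean.

        Used for kinship estimation only; association tests drop the
        individuals missing at the tested marker instead.
        """
        out = self.values.copy()
        col_mean = np.nanmean(np.where(np.isfinite(out), out, np.nan), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        idx = np.where(~np.isfinite(out))
        out[idx] = col_mean[idx[1]]
        return out

    def subset(self, row_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[row_idx],
            [self.individual_ids[i] for i in row_idx],
            self.markers.reset_index(drop=True),
        )


@dataclass
class PhenotypeVector:
    """One quantitative trait, aligned to a GenotypeMatrix."""

    y: np.ndarray
    trait_name: str = "trait"
    individual_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.individual_ids and len(self.individual_ids) != self.y.size:
            raise ValueError("individual_ids length does not match y")

    @property
    def sd_y(self) -> float:
        """Phenotypic standard deviation of non-missing values (ddof=1)."""
        obs = self.y[np.isfinite(self.y)]
        return float(np.std(obs, ddof=1))

    def subset(self, row_idx: np.ndarray) -> "PhenotypeVector":
        ids = [self.individual_ids[i] for i in row_idx] if self.individual_ids else []
        return PhenotypeVector(self.y[row_idx], self.trait_name, ids)


@dataclass
class CovariateTable:
    """Fixed-effect covariates (structure fractions or PCs); no intercept.

    The intercept is always added by the model-fitting code and must not
    appear as a column here.
    """

    X_covariates: np.ndarray
    names: list
    individual_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X_covariates = np.atleast_2d(np.asarray(self.X_covariates, dtype=float))
        if self.X_covariates.shape[1] != len(self.names):
            raise ValueError("names length does not match covariate columns")
        if self.individual_ids and len(self.individual_ids) != self.X_covariates.shape[0]:
            raise ValueError("individual_ids length does not match rows")

    def validate(self) -> None:
        if not np.isfinite(self.X_covariates).all():
            raise ValueError("covariates contain missing values after alignment")
        if self.X_covariates.shape[1]:
            if np.any(np.ptp(self.X_covariates, axis=0) == 0):
                raise ValueError(
                    "constant covariate column; the intercept is added separately"
                )

    @classmethod
    def empty(cls, n: int, ids: list | None = None) -> "CovariateTable":
        return cls(np.empty((n, 0)), [], ids or [])

    def subset(self, row_idx: np.ndarray) -> "CovariateTable":
        ids = [self.individual_ids[i] for i in row_idx] if self.individual_ids else []
        return CovariateTable(self.X_covariates[row_idx], list(self.names), ids)


def design_matrix(n: int, covariates: CovariateTable | None) -> np.ndarray:
    """Intercept column prepended to the covariates (if any)."""
    if covariates is None or covariates.X_covariates.shape[1] == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates.X_covariates])
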