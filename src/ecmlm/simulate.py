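"""Synthetic structured genotype/phenotype panels.

The generator emulates the two confounders compressed mixed models
target: broad population structure (Balding-Nichols subpopulation allele
frequencies) and family relatedness (full-sib families gene-dropped from
two unrelated founders per family).  It returns the realized
pedigree-based kinship alongside the genotypes so estimators and model
fits can be checked against a known truth.

All draws come from named substreams of a single seed, so adding markers
never perturbs phenotypes drawn under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PhenotypeVector
from .kinship import KinshipMatrix

__all__ = ["PanelSpec", "simulate_panel", "simulate_phenotype"]

_SIB_KINSHIP = 0.25
_SELF_KINSHIP = 0.5


@dataclass
class PanelSpec:
    """Study-panel dimensions and structure parameters.

    Defaults describe the structured benchmark panel used throughout the
    package: two subpopulations at moderate differentiation (Fst = 0.1),
    ten full-sib families of five per subpopulation, 500 markers.
    """

    n_subpops: int = 2
    n_families: int = 10
    sibship: int = 5
    m: int = 500
    fst: float = 0.1
    h2: float = 0.5
    n_chrom: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        if min(self.n_subpops, self.n_families, self.sibship, self.m) < 1:
            raise ValueError("panel dimensions must be positive")

    @property
    def n(self) -> int:
        return self.n_subpops * self.n_families * self.sibship


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def simulate_panel(spec: PanelSpec) -> tuple[GenotypeMatrix, KinshipMatrix]:
    """Generate genotypes and the realized pedigree kinship.

    Ancestral allele frequencies ~ Uniform(0.1, 0.9); subpopulation
    frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols; F = 0
    means frequencies are ancestral).  Each family has two unrelated
    founders whose alleles are Bernoulli draws at the subpopulation
    frequency; sibs inherit one random allele from each founder, so full
    sibs have pedigree kinship 0.25 and everyone else 0.  Columns are
    oriented to the minor allele.
    """
    rng = _stream(spec.seed, 0)
    m = spec.m
    p_anc = rng.uniform(0.1, 0.9, size=m)
    dosages = np.zeros((spec.n, m), dtype=float)
    row = 0
    for _ in range(spec.n_subpops):
        if spec.fst > 0.0:
            a = p_anc * (1.0 - spec.fst) / spec.fst
            b = (1.0 - p_anc) * (1.0 - spec.fst) / spec.fst
            p_sub = np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)
        else:
            p_sub = p_anc
        for _ in range(spec.n_families):
            founders = (rng.random((2, m, 2)) < p_sub[None, :, None]).astype(np.int8)
            for _ in range(spec.sibship):
                pick = rng.integers(0, 2, size=(2, m))
                child = founders[0, np.arange(m), pick[0]] + founders[
                    1, np.arange(m), pick[1]
                ]
                dosages[row] = child
                row += 1
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]

    per_chrom = int(np.ceil(m / spec.n_chrom))
    markers = pd.DataFrame(
        {
            "id": [f"m{j + 1:05d}" for j in range(m)],
            "chrom": [j // per_chrom + 1 for j in range(m)],
            "pos": [(j % per_chrom + 1) * 1000 for j in range(m)],
        }
    )
    ids = [f"ind{j + 1:04d}" for j in range(spec.n)]
    g = GenotypeMatrix(dosages, ids, markers)

    K_true = np.zeros((spec.n, spec.n))
    fam = spec.sibship
    for start in range(0, spec.n, fam):
        K_true[start : start + fam, start : start + fam] = _SIB_KINSHIP
    np.fill_diagonal(K_true, _SELF_KINSHIP)
    return g, KinshipMatrix(K_true, ids)


def simulate_phenotype(
    g: GenotypeMatrix,
    K_true: KinshipMatrix,
    h2: float,
    n_qtn: int = 0,
    seed: int = 0,
    qtn_effect_sd: float = 0.5,
) -> PhenotypeVector:
    """Polygenic trait with covariance 2 K_true sigma_a^2 plus noise.

    Variances are set on the expected scale so that the REML ratio is
    known exactly: sigma_a^2 = h2 / mean(diag(2 K_true)) and sigma_e^2 =
    1 - h2, giving lambda = h2/(1-h2) when the pedigree diagonal is 0.5.
    Optional explicit QTNs add marker effects of size ``qtn_effect_sd``
    (in residual-SD units) at randomly chosen markers.
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0, 1)")
    n = g.n_individuals
    rng_g = _stream(seed, 1)
    rng_e = _stream(seed, 2)
    G2 = 2.0 * K_true.values
    sigma_a2 = h2 / float(np.mean(np.diag(G2))) if h2 > 0 else 0.0
    sigma_e2 = 1.0 - h2
    y = rng_e.normal(0.0, np.sqrt(sigma_e2), size=n)
    if h2 > 0:
        # eigh is robust to the (PSD) pedigree matrix being rank deficient
        vals, vecs = np.linalg.eigh(G2)
        vals = np.clip(vals, 0.0, None)
        y = y + vecs @ (np.sqrt(vals * sigma_a2) * rng_g.normal(size=n))
    if n_qtn > 0:
        qtn = rng_g.choice(g.n_markers, size=n_qtn, replace=False)
        effects = rng_g.normal(0.0, qtn_effect_sd * np.sqrt(sigma_e2), size=n_qtn)
        y = y + g.imputed()[:, qtn] @ effects
    return PhenotypeVector(y, "sim_trait", list(g.individual_ids))
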