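"""Synthetic multi-environment trials and DH populations.

Two generators close the testing loop for the whole pipeline:

* :func:`simulate_ammi_trial` draws replicate-level observations from the
  AMMI model itself — additive genotype and environment main effects, K
  planted multiplicative interaction axes with known singular values, and
  i.i.d. normal error — so the decomposition and ANOVA can be checked
  against known truth.
* :func:`simulate_dh_population` builds fully homozygous DH lines from
  {-1, +1} allele vectors with per-locus additive effects and pairwise
  additive-by-additive (epistatic) coefficients, the genetic model the
  quantile estimators assume.

Defaults mirror the spring-barley study design this package ships as its
example dataset: 32 genotypes, 6 environments, 3 replicates, grand mean
44.8 g, error variance 26.4 g^2, and interaction axes sized like the
fitted ones (main-effect spreads back-solved from the trial's
sums of squares).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ge_data import ReplicateTable

__all__ = [
    "AMMISimSpec",
    "DHSimSpec",
    "simulate_ammi_trial",
    "simulate_dh_population",
    "random_interaction_scores",
]

# study-scale default interaction singular values: sqrt(SS_axis / r) for the
# three significant axes of the example trial
_DEFAULT_LAMBDAS = (39.3, 26.2, 24.9)


@dataclass(frozen=True)
class AMMISimSpec:
    """Design of a simulated balanced trial drawn from the AMMI model.

    ``genotype_effects`` / ``environment_effects`` may be given explicitly
    (they are centered to zero sum) or drawn as N(0, sd^2) and centered,
    with sd chosen to match the example trial's main-effect spread
    (sigma_g ~ 4.9 g, sigma_e ~ 3.8 g).  ``score_vectors`` optionally fixes
    the unit-norm, zero-sum interaction eigenvectors (gamma, delta);
    otherwise random orthonormal vectors orthogonal to the all-ones vector
    are generated, which makes the planted axes satisfy the
    double-centering identities exactly.
    """

    G: int = 32
    E: int = 6
    r: int = 3
    mu: float = 44.8
    genotype_effects: Optional[Sequence[float]] = None
    environment_effects: Optional[Sequence[float]] = None
    genotype_sd: float = 4.9
    environment_sd: float = 3.8
    lambdas: Sequence[float] = _DEFAULT_LAMBDAS
    score_vectors: Optional[tuple[np.ndarray, np.ndarray]] = None
    error_sd: float = 5.14  # sqrt(26.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.G, self.E) < 3 or self.r < 1:
            raise ValueError("need G >= 3, E >= 3, r >= 1")
        K = len(self.lambdas)
        if K > min(self.G - 1, self.E - 1):
            raise ValueError(
                f"{K} interaction axes exceed min(G-1, E-1) = "
                f"{min(self.G - 1, self.E - 1)}"
            )
        if self.error_sd < 0:
            raise ValueError("error_sd must be nonnegative")
        if self.score_vectors is not None:
            gamma, delta = self.score_vectors
            for mat, n in ((np.asarray(gamma), self.G), (np.asarray(delta), self.E)):
                if mat.shape != (n, K):
                    raise ValueError("score vector shapes must be (G, K) and (E, K)")
                if not np.allclose(mat.T @ mat, np.eye(K), atol=1e-8):
                    raise ValueError("score vectors must be orthonormal")

    @classmethod
    def from_yaml(cls, path) -> "AMMISimSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def random_interaction_scores(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k orthonormal n-vectors orthogonal to the all-ones vector.

    Gaussian draws are QR-orthogonalized against a leading ones column, so
    every returned column is centered — planted interaction terms then obey
    the AMMI double-centering identities exactly.
    """
    if k > n - 1:
        raise ValueError("at most n-1 centered orthonormal vectors exist")
    basis = np.column_stack([np.ones(n), rng.standard_normal((n, k))])
    q, _ = np.linalg.qr(basis)
    return q[:, 1 : k + 1]


def _centered_effects(
    given: Optional[Sequence[float]], n: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    if given is not None:
        eff = np.asarray(given, dtype=float)
        if eff.shape != (n,):
            raise ValueError(f"expected {n} effects, got shape {eff.shape}")
    else:
        eff = rng.normal(0.0, sd, size=n)
    return eff - eff.mean()


def simulate_ammi_trial(spec: AMMISimSpec) -> ReplicateTable:
    """Draw a balanced replicate-level trial from the AMMI model.

    y_ger = mu + alpha_g + beta_e + sum_k lambda_k gamma_gk delta_ek + eps_ger
    with eps ~ N(0, error_sd^2); byte-identical output for identical spec
    and seed.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = _centered_effects(spec.genotype_effects, spec.G, spec.genotype_sd, rng)
    beta = _centered_effects(spec.environment_effects, spec.E, spec.environment_sd, rng)
    K = len(spec.lambdas)
    if spec.score_vectors is not None:
        gamma = np.asarray(spec.score_vectors[0], dtype=float)
        delta = np.asarray(spec.score_vectors[1], dtype=float)
    else:
        gamma = random_interaction_scores(spec.G, K, rng)
        delta = random_interaction_scores(spec.E, K, rng)
    lam = np.asarray(spec.lambdas, dtype=float)
    means = (
        spec.mu
        + alpha[:, None]
        + beta[None, :]
        + (gamma * lam) @ delta.T
    )
    noise = rng.normal(0.0, spec.error_sd, size=(spec.G, spec.E, spec.r))
    y = means[:, :, None] + noise
    g_ids = [f"G{i + 1:02d}" for i in range(spec.G)]
    e_ids = [f"E{j + 1}" for j in range(spec.E)]
    gi, ei, ri = np.meshgrid(
        np.arange(spec.G), np.arange(spec.E), np.arange(spec.r), indexing="ij"
    )
    records = pd.DataFrame(
        {
            "genotype": np.array(g_ids)[gi.ravel()],
            "environment": np.array(e_ids)[ei.ravel()],
            "replicate": ri.ravel() + 1,
            "value": y.ravel(),
        }
    )
    return ReplicateTable(records)


@dataclass(frozen=True)
class DHSimSpec:
    """Design of a simulated doubled-haploid population.

    Each line is an allele vector x in {-1, +1}^n_loci (fully homozygous);
    its genotypic value is

        base + sum_l x_l a_l + sum_{l<m} x_l x_m aa_lm,

    with per-locus additive effects ``a`` (scalar broadcast or length
    ``n_loci``) and a single additive-by-additive coefficient ``aa``
    applied to every interacting pair listed in ``epistatic_pairs``
    (default: none).  ``force_extremes`` replaces the first two lines with
    the all-plus and all-minus genotypes, matching the estimators'
    assumption that lines carrying only increasing / only decreasing
    alleles exist.  Phenotypes add environment effects and N(0, error_sd^2)
    replicate noise as in :class:`AMMISimSpec`.
    """

    n_lines: int = 30
    n_loci: int = 8
    additive: float | Sequence[float] = 1.25  # ~ total a_DH of 10 g at 8 loci
    epistatic_pairs: tuple[tuple[int, int], ...] = ()
    aa: float = 0.0
    base: float = 44.8
    n_environments: int = 6
    r: int = 3
    environment_sd: float = 3.8
    error_sd: float = 5.14
    force_extremes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 3 or self.n_loci < 1:
            raise ValueError("need n_lines >= 3 and n_loci >= 1")
        for l, m in self.epistatic_pairs:
            if not (0 <= l < m < self.n_loci):
                raise ValueError(f"bad epistatic pair ({l}, {m})")

    @property
    def additive_vector(self) -> np.ndarray:
        a = np.asarray(self.additive, dtype=float)
        return np.full(self.n_loci, float(a)) if a.ndim == 0 else a


def simulate_dh_population(spec: DHSimSpec) -> tuple[pd.Series, ReplicateTable]:
    """Simulate DH line genotypic values and a replicate-level trial.

    Returns the true genotypic values (Series indexed by line id) alongside
    the noisy phenotype records, so estimator recovery can be measured
    against truth.
    """
    rng = np.random.default_rng(spec.seed)
    a = spec.additive_vector
    X = rng.choice([-1.0, 1.0], size=(spec.n_lines, spec.n_loci))
    if spec.force_extremes:
        X[0] = 1.0
        X[1] = -1.0
    values = spec.base + X @ a
    for l, m in spec.epistatic_pairs:
        values = values + spec.aa * X[:, l] * X[:, m]
    ids = [f"DH{i + 1:03d}" for i in range(spec.n_lines)]
    genotypic = pd.Series(values, index=ids, name="genotypic_value")

    beta = rng.normal(0.0, spec.environment_sd, size=spec.n_environments)
    beta -= beta.mean()
    noise = rng.normal(
        0.0, spec.error_sd, size=(spec.n_lines, spec.n_environments, spec.r)
    )
    y = values[:, None, None] + beta[None, :, None] + noise
    e_ids = [f"E{j + 1}" for j in range(spec.n_environments)]
    gi, ei, ri = np.meshgrid(
        np.arange(spec.n_lines),
        np.arange(spec.n_environments),
        np.arange(spec.r),
        indexing="ij",
    )
    records = pd.DataFrame(
        {
            "genotype": np.array(ids)[gi.ravel()],
            "environment": np.array(e_ids)[ei.ravel()],
            "replicate": ri.ravel() + 1,
            "value": y.ravel(),
        }
    )
    return genotypic, ReplicateTable(records)
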