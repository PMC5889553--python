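"""BayesC(pi) and BayesB whole-genome regression.

Both fit the variable-selection model

    y = X b + sum_j z_j alpha_j delta_j + e,

where z_j is the coded genotype covariate of variant j (-10/0/10 coding,
centred by the training column mean), delta_j an inclusion indicator with
prior P(delta_j = 0) = pi, and alpha_j the allele-substitution effect.
BayesC(pi) shares one effect variance across included variants and treats pi
as unknown (Beta posterior from the inclusion counts) — used here to
estimate pi. BayesB gives every locus its own scaled-inverse-chi-square
variance and keeps pi fixed. GEBV are the linear combination
GEBV_i = sum_j z_ij alpha_hat_j.

Because the -10/0/10 coding is 10x the usual allele count deviation, effect
estimates are 1/10 of their 0/1/2-coded counterparts; GEBV are invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ._mcmc import bayes_b_kernel, bayes_cpi_kernel
from .containers import GenotypeMatrix

__all__ = ["McmcSettings", "MarkerEffectSet", "BayesCPi", "BayesB", "bayes_cpi", "bayes_b", "gebv"]

CODE_SCALE = 10.0  # dosage d -> 10*(d-1), i.e. the -10/0/10 covariate coding


@dataclass(frozen=True)
class McmcSettings:
    """Chain controls shared by the samplers.

    ``nu`` is the prior degrees of freedom of the locus-variance
    scaled-inverse-chi-square; the prior scale derives from the genetic
    variance as  E[sigma_j^2] = sigma_g2 / ((1 - pi) * sum 2p(1-p) * 100)
    (the 100 reflecting the x10 covariate coding).
    """

    n_iter: int = 3000
    burn_in: int = 600
    thin: int = 10
    seed: int = 0
    nu: float = 4.2

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class MarkerEffectSet:
    """Posterior mean allele-substitution effects on the coded scale."""

    variant_ids: np.ndarray
    alpha_hat: np.ndarray
    inclusion_freq: np.ndarray
    pi_used: float
    coding: str = "ten"  # "ten" = -10/0/10, "dosage" = 0/1/2
    center: np.ndarray | None = None  # training column means of the coded covariates
    chain_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.alpha_hat)):
            raise ValueError("non-finite marker effects")
        if ((self.inclusion_freq < 0) | (self.inclusion_freq > 1)).any():
            raise ValueError("inclusion frequencies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "alpha_hat": self.alpha_hat,
                "inclusion_freq": self.inclusion_freq,
            }
        )


def code_genotypes(
    geno: GenotypeMatrix | np.ndarray, coding: str = "ten", center: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dosages -> model covariates; returns (Z, column centers used)."""
    M = geno.mean_impute() if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    Z = CODE_SCALE * (M - 1.0) if coding == "ten" else M.copy()
    if center is None:
        center = Z.mean(axis=0)
    return Z - center, center


def _fixed_design(fixed, n: int) -> np.ndarray:
    if fixed is None:
        return np.ones((n, 1))
    F = np.atleast_2d(np.asarray(fixed, float))
    return F


class BayesCPi(BaseEstimator):
    """BayesC with unknown pi; primarily a pi estimator.

    Attributes after fit: ``pi_`` (posterior mean of the null fraction),
    ``pi_chain_``, ``alpha_hat_``, ``inclusion_freq_``, ``sigma_e2_``.
    """

    # nu=10: the variance shared by all included markers warrants a firmer
    # prior than BayesB's per-locus nu=4.2; it keeps pi identified on null data
    def __init__(self, n_iter=3000, burn_in=600, seed=0, nu=10.0, pi_init=0.9, coding="ten"):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.seed = seed
        self.nu = nu
        self.pi_init = pi_init
        self.coding = coding

    def fit(self, X, y, fixed=None, sigma_g2=None):
        y = np.asarray(y, float)
        if np.var(y) == 0:
            raise ValueError("zero phenotypic variance")
        Z, center = code_genotypes(X, self.coding)
        n, p = Z.shape
        F = _fixed_design(fixed, n)
        vy = float(np.var(y))
        sg2 = 0.5 * vy if sigma_g2 is None else float(sigma_g2)
        sum2pq_scaled = float(np.sum(np.var(Z, axis=0)))
        # base scale excludes the (1 - pi) factor; the kernel divides by the
        # current pi's non-null fraction every iteration
        S_base = sg2 / max(sum2pq_scaled, 1e-12) * (self.nu - 2) / self.nu
        alpha, incl, pi, se2, sa2, pi_chain = bayes_cpi_kernel(
            y, F, Z, int(self.n_iter), int(self.burn_in), int(self.seed),
            float(self.nu), S_base, 10.0, vy - sg2 if vy > sg2 else 0.5 * vy,
            float(self.pi_init), 1,
        )
        self.pi_ = float(pi)
        self.pi_chain_ = pi_chain
        self.alpha_hat_ = alpha
        self.inclusion_freq_ = incl
        self.sigma_e2_ = float(se2)
        self.sigma_alpha2_ = float(sa2)
        self.center_ = center
        return self

    def effects(self, variant_ids=None) -> MarkerEffectSet:
        vids = np.arange(len(self.alpha_hat_)).astype(object) if variant_ids is None else variant_ids
        return MarkerEffectSet(
            np.asarray(vids, dtype=object), self.alpha_hat_, self.inclusion_freq_,
            self.pi_, self.coding, self.center_,
            {"n_iter": self.n_iter, "burn_in": self.burn_in, "seed": self.seed},
        )


class BayesB(BaseEstimator, RegressorMixin):
    """BayesB with fixed pi and per-locus variances.

    ``fit(X, y, fixed=..., sigma_g2=..., sigma_e2=...)`` runs the Gibbs
    sampler; ``predict(X_new)`` returns GEBV with the training coding.
    """

    def __init__(self, pi=0.99, n_iter=3000, burn_in=600, seed=0, nu=4.2, coding="ten"):
        self.pi = pi
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.seed = seed
        self.nu = nu
        self.coding = coding

    def fit(self, X, y, fixed=None, sigma_g2=None, sigma_e2=None):
        import warnings

        if not (0 <= self.pi <= 1):
            raise ValueError("pi must be in [0, 1]")
        y = np.asarray(y, float)
        Z, center = code_genotypes(X, self.coding)
        n, p = Z.shape
        F = _fixed_design(fixed, n)
        vy = float(np.var(y))
        sg2 = 0.5 * vy if sigma_g2 is None else float(sigma_g2)
        se2 = (vy - sg2 if vy > sg2 else 0.5 * vy) if sigma_e2 is None else float(sigma_e2)
        if self.pi >= 1.0:
            warnings.warn("pi=1: every marker excluded, returning all-zero effects")
            self.alpha_hat_ = np.zeros(p)
            self.inclusion_freq_ = np.zeros(p)
            self.sigma_e2_ = vy
            self.center_ = center
            self._set_effects(X)
            return self
        sum2pq_scaled = float(np.sum(np.var(Z, axis=0)))
        S0 = sg2 / max((1 - self.pi) * sum2pq_scaled, 1e-12)
        S0 *= (self.nu - 2) / self.nu
        alpha, incl, se2_post = bayes_b_kernel(
            y, F, Z, int(self.n_iter), int(self.burn_in), int(self.seed),
            float(self.pi), float(self.nu), S0, 10.0, se2,
        )
        self.alpha_hat_ = alpha
        self.inclusion_freq_ = incl
        self.sigma_e2_ = float(se2_post)
        self.center_ = center
        self._set_effects(X)
        return self

    def _set_effects(self, X) -> None:
        vids = (
            X.variant_ids if isinstance(X, GenotypeMatrix)
            else np.arange(len(self.alpha_hat_)).astype(object)
        )
        self.effects_ = MarkerEffectSet(
            np.asarray(vids, dtype=object), self.alpha_hat_, self.inclusion_freq_,
            float(self.pi), self.coding, self.center_,
            {"n_iter": self.n_iter, "burn_in": self.burn_in, "seed": self.seed},
        )

    def predict(self, X) -> np.ndarray:
        Z, _ = code_genotypes(X, self.coding, center=self.center_)
        return Z @ self.alpha_hat_


def bayes_cpi(geno, y, settings: McmcSettings = McmcSettings(), fixed=None, sigma_g2=None):
    """Functional wrapper: posterior pi distribution and point estimate."""
    est = BayesCPi(settings.n_iter, settings.burn_in, settings.seed).fit(
        geno, y, fixed=fixed, sigma_g2=sigma_g2
    )
    return est.pi_chain_[settings.burn_in:], est.pi_


def bayes_b(
    geno, y, pi: float, settings: McmcSettings = McmcSettings(), fixed=None,
    sigma_g2=None, sigma_e2=None,
) -> MarkerEffectSet:
    """Functional wrapper returning the MarkerEffectSet."""
    est = BayesB(pi, settings.n_iter, settings.burn_in, settings.seed, settings.nu).fit(
        geno, y, fixed=fixed, sigma_g2=sigma_g2, sigma_e2=sigma_e2
    )
    return est.effects_


def gebv(effects: MarkerEffectSet, geno: GenotypeMatrix | np.ndarray) -> pd.Series:
    """GEBV_i = sum_j z_ij alpha_hat_j with the effect set's coding.

    If the effect set carries training centering constants they are applied
    (a per-animal constant shift relative to the raw coding; rankings and
    contrasts are unaffected).
    """
    center = effects.center
    if center is None:
        center = np.zeros(len(effects.alpha_hat))  # raw codes, no training shift
    if isinstance(geno, GenotypeMatrix):
        sub = geno.subset(variant_ids=effects.variant_ids)
        Z, _ = code_genotypes(sub, effects.coding, center=center)
        ids = sub.animal_ids
    else:
        Z, _ = code_genotypes(np.asarray(geno, float), effects.coding, center=center)
        ids = np.arange(Z.shape[0]).astype(object)
    return pd.Series(Z @ effects.alpha_hat, index=ids)
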