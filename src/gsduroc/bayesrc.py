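"""BayesRC: four-component mixture regression with biological variant classes.

The model on training corrected phenotypes is

    y_c = 1 mu + Z a + W v + e,

with a pedigree polygenic term a ~ N(0, A sigma_a2) for genetic variance not
captured by the variants, and per-variant effects v_j drawn from a mixture
of four normals N(0, gamma_k sigma_g2), gamma = (0, 0.0001, 0.001, 0.01),
where sigma_g2 is the trait's additive genetic variance on the full variant
set and is held fixed during sampling. W holds 0/1/2 dosages centred and
standardized to unit variance per column (training constants are reused for
validation). Each biological class (NSC/REG/CHIP) carries its own mixture
proportions under a uniform Dirichlet prior, so classes enriched for QTL can
concentrate mass on the non-null components.

Replicate chains are averaged for the final estimates; the pairwise
correlation of per-chain posterior mean effects is reported as a convergence
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin

from ._mcmc import bayesrc_kernel
from .containers import GenotypeMatrix
from .pedigree import Pedigree, build_A_inverse

__all__ = ["MixtureSpec", "BayesRCResult", "standardize_W", "BayesRC", "bayesrc_sample", "gebv_from_bayesrc"]

CLASS_ORDER = ("NSC", "REG", "CHIP")


@dataclass(frozen=True)
class MixtureSpec:
    """Four-normal mixture: first component exactly null, multipliers increasing."""

    variance_multipliers: tuple = (0.0, 1e-4, 1e-3, 1e-2)
    sigma_g2: float = 1.0
    dirichlet_alpha: float | tuple = 1.0  # scalar or per-component 4-vector

    def __post_init__(self) -> None:
        m = self.variance_multipliers
        if len(m) != 4 or m[0] != 0.0 or any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("need four strictly increasing multipliers starting at 0")
        if self.sigma_g2 <= 0:
            raise ValueError("sigma_g2 must be positive")

    def alpha_vector(self) -> np.ndarray:
        a = self.dirichlet_alpha
        return np.full(4, float(a)) if np.isscalar(a) else np.asarray(a, float)


@dataclass
class BayesRCResult:
    """Across-chain posterior summaries."""

    variant_ids: np.ndarray
    v_hat: np.ndarray                  # posterior mean effects, standardized scale
    component_probs: np.ndarray        # per-variant 4-vector
    class_labels: list
    class_mixture: np.ndarray          # per-class posterior mean proportions (rows sum to 1)
    polygenic_ebv: pd.Series
    mu: float
    sigma_e2: float
    sigma_a2: float
    chain_v: np.ndarray                # per-chain posterior mean effects (n_chains x p)
    chain_correlation: np.ndarray      # pairwise correlation matrix of chain_v
    center: np.ndarray = None
    scale: np.ndarray = None

    @property
    def min_chain_correlation(self) -> float:
        c = self.chain_correlation
        off = c[~np.eye(len(c), dtype=bool)]
        return float(off.min()) if off.size else 1.0

    def class_pi(self) -> pd.Series:
        """Per-class posterior null-component proportion."""
        return pd.Series(self.class_mixture[:, 0], index=self.class_labels)


def standardize_W(
    geno: GenotypeMatrix | np.ndarray,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre and scale dosage columns to mean 0, variance 1.

    Monomorphic columns raise (they must be filtered upstream). Pass training
    ``center``/``scale`` to transform validation genotypes consistently.
    """
    M = geno.mean_impute() if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    if center is None:
        center = M.mean(axis=0)
        scale = M.std(axis=0)
        if (scale == 0).any():
            raise ValueError("monomorphic variant columns; filter before standardizing")
    return (M - center) / scale, center, scale


class BayesRC(BaseEstimator, RegressorMixin):
    """Class-informed Bayesian mixture regression (sklearn-style).

    ``fit(X, y, classes=..., pedigree=..., pheno_ids=...)`` runs
    ``n_chains`` replicate Gibbs chains with distinct seeds and averages
    them. ``predict(X_new)`` returns W_new . v_hat using training
    standardization constants.

    Parameters
    ----------
    mixture : MixtureSpec (sigma_g2 fixed throughout sampling)
    n_iter, burn_in, n_chains, seed : chain controls
    sigma_a2_init : initial polygenic variance (default 0.1 * sigma_g2)
    sigma_e2_init : initial/prior residual variance (default var(y) - sigma_g2)
    """

    def __init__(
        self,
        mixture: MixtureSpec = MixtureSpec(),
        n_iter=3000,
        burn_in=600,
        n_chains=5,
        seed=0,
        sigma_a2_init=None,
        sigma_e2_init=None,
    ):
        self.mixture = mixture
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.seed = seed
        self.sigma_a2_init = sigma_a2_init
        self.sigma_e2_init = sigma_e2_init

    def fit(self, X, y, classes=None, pedigree: Pedigree | None = None, pheno_ids=None):
        import warnings

        y = np.asarray(y, float)
        W, center, scale = standardize_W(X)
        n, p = W.shape
        if classes is None:
            classes = np.array(["CHIP"] * p, dtype=object)
        classes = np.asarray(classes, dtype=object)
        labels = [c for c in CLASS_ORDER if (classes == c).any()]
        labels += sorted(set(classes) - set(CLASS_ORDER) - {None})
        empty = [c for c in CLASS_ORDER if c not in labels]
        if empty:
            warnings.warn(f"classes with zero variants skipped: {empty}")
        cls_idx = np.array([labels.index(c) for c in classes], dtype=np.int64)
        if pedigree is not None:
            Ainv = build_A_inverse(pedigree).tocsr()
            rec_of = np.full(len(pedigree), -1, dtype=np.int64)
            ids = (
                np.asarray(pheno_ids, dtype=object)
                if pheno_ids is not None
                else pedigree.animal[: n]
            )
            rec_of[pedigree.index_of(ids)] = np.arange(n)
            anim_index = pedigree.animal
        else:
            # no pedigree: a degenerate one-animal-per-record identity polygenic term
            Ainv = sp.identity(n, format="csr")
            rec_of = np.arange(n, dtype=np.int64)
            anim_index = (
                np.asarray(pheno_ids, dtype=object) if pheno_ids is not None
                else np.arange(n).astype(object)
            )
        mix = self.mixture
        vy = float(np.var(y))
        se0 = (
            float(self.sigma_e2_init)
            if self.sigma_e2_init is not None
            else max(vy - mix.sigma_g2, 0.3 * vy)
        )
        sa0 = float(self.sigma_a2_init) if self.sigma_a2_init is not None else 0.1 * mix.sigma_g2
        gamma = np.asarray(mix.variance_multipliers, float)
        chain_v = np.zeros((self.n_chains, p))
        comp_probs = np.zeros((p, 4))
        cls_mix = np.zeros((len(labels), 4))
        poly = np.zeros(Ainv.shape[0])
        mu_acc = se_acc = sa_acc = 0.0
        for c in range(self.n_chains):
            seed_c = (int(self.seed) + 7919 * c) % (2**31 - 1)
            v, cp, pm, a, mu, se2, sa2 = bayesrc_kernel(
                y, W, cls_idx, len(labels), gamma, float(mix.sigma_g2),
                Ainv.indptr, Ainv.indices, Ainv.data, rec_of,
                int(self.n_iter), int(self.burn_in), seed_c,
                10.0, se0, 4.0, sa0, mix.alpha_vector(),
            )
            chain_v[c] = v
            comp_probs += cp / self.n_chains
            cls_mix += pm / self.n_chains
            poly += a / self.n_chains
            mu_acc += mu / self.n_chains
            se_acc += se2 / self.n_chains
            sa_acc += sa2 / self.n_chains
        corr = np.corrcoef(chain_v) if self.n_chains > 1 else np.ones((1, 1))
        vids = (
            X.variant_ids if isinstance(X, GenotypeMatrix)
            else np.arange(p).astype(object)
        )
        self.result_ = BayesRCResult(
            np.asarray(vids, dtype=object), chain_v.mean(axis=0), comp_probs,
            labels, cls_mix, pd.Series(poly, index=anim_index), mu_acc,
            se_acc, sa_acc, chain_v, np.atleast_2d(corr), center, scale,
        )
        self.v_hat_ = self.result_.v_hat
        self.center_ = center
        self.scale_ = scale
        return self

    def predict(self, X) -> np.ndarray:
        """GEBV = W_new . v_hat with training standardization constants."""
        W, _, _ = standardize_W(X, center=self.center_, scale=self.scale_)
        return W @ self.v_hat_


def bayesrc_sample(
    yc2_training,
    geno_training,
    classes,
    pedigree: Pedigree | None,
    mixture: MixtureSpec,
    n_iter=3000,
    burn_in=600,
    n_chains=5,
    seed=0,
    pheno_ids=None,
) -> BayesRCResult:
    """Functional wrapper over :class:`BayesRC`."""
    est = BayesRC(mixture, n_iter, burn_in, n_chains, seed).fit(
        geno_training, yc2_training, classes=classes, pedigree=pedigree, pheno_ids=pheno_ids
    )
    return est.result_


def gebv_from_bayesrc(
    result: BayesRCResult,
    geno_validation: GenotypeMatrix | np.ndarray,
    pedigree: Pedigree | None = None,
    add_polygenic: bool = False,
) -> pd.Series:
    """GEBV for validation animals from the across-chain posterior means.

    Standardization constants come from training. With ``add_polygenic`` the
    parent-average polygenic EBV is added for animals whose parents appear in
    the polygenic solutions.
    """
    if isinstance(geno_validation, GenotypeMatrix):
        sub = geno_validation.subset(variant_ids=result.variant_ids)
        W, _, _ = standardize_W(sub, center=result.center, scale=result.scale)
        ids = sub.animal_ids
    else:
        W, _, _ = standardize_W(geno_validation, center=result.center, scale=result.scale)
        ids = np.arange(W.shape[0]).astype(object)
    g = pd.Series(W @ result.v_hat, index=ids)
    if add_polygenic and pedigree is not None:
        pa = result.polygenic_ebv
        for i, animal in enumerate(ids):
            j = pedigree._index.get(animal)
            if j is None:
                continue
            s, d = pedigree.sire[j], pedigree.dam[j]
            g.iloc[i] += 0.5 * (pa.get(s, 0.0) + pa.get(d, 0.0))
    return g
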