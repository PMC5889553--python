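"""Genomic relationship matrix and GBLUP prediction.

G follows VanRaden's first method: dosages centred by twice the observed
allele frequency, G = M M' / sum(2 p (1-p)). GBLUP is the animal model with G
in place of the pedigree relationship matrix; validation animals keep their
row/column of G but have their phenotypes masked, so their GEBV arrive
through the genomic covariance — numerically identical to ridge-regression
SNP-BLUP with lambda = sigma_e2 / (sigma_a2 / sum(2pq)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import GenotypeMatrix
from .pedigree import VarianceComponents

__all__ = ["GMatrix", "build_G", "gblup_predict", "GBLUP"]


@dataclass
class GMatrix:
    """Genomic relationship matrix with the allele frequencies that built it."""

    values: np.ndarray
    animal_ids: np.ndarray
    allele_freqs: np.ndarray
    source_panel: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("G must be square")
        if self.values.shape[0] != len(self.animal_ids):
            raise ValueError("G dimension does not match animal ids")


def build_G(
    geno: GenotypeMatrix | np.ndarray,
    allele_freqs: np.ndarray | None = None,
    source_panel: str = "",
) -> GMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Monomorphic variants are excluded. Missing dosages must already be
    mean-imputed (pass a float matrix, or a GenotypeMatrix whose
    ``mean_impute`` fills them).
    """
    if isinstance(geno, GenotypeMatrix):
        M = geno.mean_impute()
        ids = geno.animal_ids
    else:
        M = np.asarray(geno, float)
        ids = np.arange(M.shape[0]).astype(object)
    p = M.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all variants monomorphic; G undefined")
    Mc = M[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    G = (Mc @ Mc.T) / denom
    return GMatrix(G, np.asarray(ids, dtype=object), p, source_panel)


def gblup_predict(
    y: np.ndarray,
    X: np.ndarray | None,
    G: GMatrix,
    vc: VarianceComponents,
    mask: np.ndarray,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, pd.Series]:
    """Solve the G-based MME with masked phenotypes.

    ``y``/``X`` are aligned with ``G.animal_ids``; records where ``mask`` is
    True are excluded from the equations but their animals still receive GEBV
    through G. Returns (b_hat, GEBV Series over all animals).
    """
    n = len(G.animal_ids)
    y = np.asarray(y, float)
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, float))
    mask = np.asarray(mask, bool)
    use = ~mask
    if vc.sigma_a2 <= 0:
        b = np.linalg.lstsq(X[use], y[use], rcond=None)[0]
        return b, pd.Series(np.zeros(n), index=G.animal_ids)
    Ginv = np.linalg.inv(G.values + ridge * np.eye(n))
    lam = vc.lam
    nu = int(use.sum())
    Z = np.zeros((nu, n))
    Z[np.arange(nu), np.flatnonzero(use)] = 1.0
    Xu, yu = X[use], y[use]
    f = Xu.shape[1]
    XtX = Xu.T @ Xu
    # pin effects of factor levels absent from the unmasked records to zero
    if f:
        empty = np.diag(XtX) <= 1e-12 * max(float(np.max(np.diag(XtX))), 1.0)
        XtX = XtX + np.diag(np.where(empty, 1.0, 0.0))
    C = np.block(
        [
            [XtX, Xu.T @ Z],
            [Z.T @ Xu, Z.T @ Z + lam * Ginv],
        ]
    )
    rhs = np.concatenate([Xu.T @ yu, Z.T @ yu])
    sol = np.linalg.solve(C, rhs)
    return sol[:f], pd.Series(sol[f:], index=G.animal_ids)


class GBLUP(BaseEstimator, RegressorMixin):
    """Genomic BLUP estimator on dosage matrices.

    ``fit(X, y)`` takes the training dosage matrix (n x p, 0/1/2 scale,
    missing mean-imputed upstream) and phenotypes; fixed effects may be
    passed as a design matrix via ``fixed``. ``predict(X_new)`` returns GEBV
    for new animals using the training allele frequencies and the
    SNP-BLUP equivalence (marker effects backsolved from the training fit).

    Parameters
    ----------
    sigma_a2, sigma_e2 : float
        Genetic and residual variance on the phenotype scale. Both required
        (estimate them with pedigree EM-REML or supply h2 via ``from_h2``).
    ridge : float
        Diagonal stabiliser added to G before inversion.

    Attributes
    ----------
    gebv_ : training-animal GEBV
    beta_ : per-variant marker effects (0/1/2 dosage scale)
    b_hat_ : fixed-effect solutions
    G_ : the training GMatrix
    """

    def __init__(self, sigma_a2=1.0, sigma_e2=1.0, ridge=1e-8):
        self.sigma_a2 = sigma_a2
        self.sigma_e2 = sigma_e2
        self.ridge = ridge

    @classmethod
    def from_h2(cls, h2: float, var_y: float = 1.0, **kw) -> "GBLUP":
        return cls(sigma_a2=h2 * var_y, sigma_e2=(1 - h2) * var_y, **kw)

    def fit(self, X, y, fixed=None):
        if isinstance(X, GenotypeMatrix):
            M = X.mean_impute()
        else:
            M = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = M.shape
        vc = VarianceComponents(float(self.sigma_a2), float(self.sigma_e2))
        self.p_ = M.mean(axis=0) / 2.0
        self.poly_ = (self.p_ > 0) & (self.p_ < 1)
        if not self.poly_.any():
            raise ValueError("all variants monomorphic")
        G = build_G(M, allele_freqs=self.p_)
        self.G_ = G
        F = np.ones((n, 1)) if fixed is None else np.atleast_2d(np.asarray(fixed, float))
        b, g = gblup_predict(y, F, G, vc, mask=np.zeros(n, bool), ridge=self.ridge)
        self.b_hat_ = b
        self.gebv_ = g.to_numpy()
        # backsolve marker effects: beta = M_c' (M_c M_c')^+ g_hat * ... via ridge identity
        Mc = M[:, self.poly_] - 2 * self.p_[self.poly_]
        denom = float(np.sum(2 * self.p_[self.poly_] * (1 - self.p_[self.poly_])))
        lam_snp = vc.sigma_e2 / (vc.sigma_a2 / denom)
        r = y - F @ b
        self.beta_ = Mc.T @ np.linalg.solve(Mc @ Mc.T + lam_snp * np.eye(n), r)
        self._denom = denom
        return self

    def predict(self, X) -> np.ndarray:
        """GEBV for new animals (genetic merit only, centred on training)."""
        M = X.mean_impute() if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
        Mc = M[:, self.poly_] - 2 * self.p_[self.poly_]
        return Mc @ self.beta_
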