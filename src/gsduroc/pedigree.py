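"""Pedigree-based animal model.

Implements the numerator-relationship machinery (tabular A with inbreeding,
Meuwissen–Luo sparse inverse), single-trait EM-REML variance-component
estimation, Henderson mixed-model-equation (MME) solutions with optional
phenotype masking, corrected phenotypes, and the birthdate-based
training/validation split used throughout the package.

The model is the standard univariate animal model

    y = X b + Z a + e,   a ~ N(0, A sigma_a2),  e ~ N(0, I sigma_e2),

where ``A`` is the additive (numerator) relationship matrix from pedigree.
Corrected phenotypes are ``y_c = EBV + residual = y - X b_hat`` and serve as
pseudo-phenotypes / validation targets for the genomic models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator

__all__ = [
    "Pedigree",
    "FixedEffectsSpec",
    "VarianceComponents",
    "build_A",
    "build_A_inverse",
    "em_reml",
    "solve_mme",
    "BlupSolution",
    "PedigreeBLUP",
    "corrected_phenotypes",
    "split_train_validation",
]

UNKNOWN = "0"


@dataclass
class Pedigree:
    """Animal/sire/dam triples in topological order (parents first).

    Unknown parents are coded ``"0"``. ``birthdate`` is an optional
    per-animal sortable value (int day number or ISO date string).
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birthdate: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        self.dam = np.asarray(self.dam, dtype=object)
        if len(set(self.animal)) != len(self.animal):
            raise ValueError("duplicate animal ids in pedigree")
        self._index = {a: i for i, a in enumerate(self.animal)}
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            for p in (s, d):
                if p != UNKNOWN:
                    j = self._index.get(p)
                    if j is None:
                        raise ValueError(f"parent {p!r} of {self.animal[i]!r} not in pedigree")
                    if j >= i:
                        raise ValueError(
                            "pedigree not topologically sorted (or cyclic): "
                            f"parent {p!r} listed at or after offspring {self.animal[i]!r}"
                        )

    def __len__(self) -> int:
        return len(self.animal)

    def index_of(self, ids) -> np.ndarray:
        return np.array([self._index[a] for a in np.asarray(ids, dtype=object)])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns animal, sire, dam[, birthdate].

        Rows are re-sorted topologically if needed (stable, by generation depth).
        """
        df = df.copy()
        for c in ("animal", "sire", "dam"):
            df[c] = df[c].astype(str)
        known = set(df["animal"])
        depth: dict[str, int] = {}

        def _depth(a: str, seen: frozenset = frozenset()) -> int:
            if a == UNKNOWN or a not in known:
                return -1
            if a in depth:
                return depth[a]
            if a in seen:
                raise ValueError(f"cyclic pedigree at animal {a!r}")
            row = df.loc[df["animal"] == a].iloc[0]
            d = 1 + max(_depth(row["sire"], seen | {a}), _depth(row["dam"], seen | {a}))
            depth[a] = d
            return d

        for a in df["animal"]:
            _depth(a)
        df = df.iloc[np.argsort([depth[a] for a in df["animal"]], kind="stable")]
        # parents absent from the animal column are treated as unknown founders
        sire = np.where(np.isin(df["sire"], list(known)), df["sire"], UNKNOWN)
        dam = np.where(np.isin(df["dam"], list(known)), df["dam"], UNKNOWN)
        bd = df["birthdate"].to_numpy() if "birthdate" in df.columns else None
        return cls(df["animal"].to_numpy(), sire, dam, bd)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"animal": self.animal, "sire": self.sire, "dam": self.dam})
        if self.birthdate is not None:
            out["birthdate"] = self.birthdate
        return out

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer parent indices, -1 for unknown."""
        n = len(self)
        si = np.full(n, -1, dtype=np.int64)
        di = np.full(n, -1, dtype=np.int64)
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            if s != UNKNOWN:
                si[i] = self._index[s]
            if d != UNKNOWN:
                di[i] = self._index[d]
        return si, di


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method (with inbreeding)."""
    si, di = pedigree.parent_indices()
    n = len(pedigree)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (diag(A) - 1)."""
    return np.diag(build_A(pedigree)) - 1.0


def build_A_inverse(pedigree: Pedigree, inbreeding_coefs: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by the Meuwissen–Luo rules, accounting for inbreeding.

    Mendelian-sampling variance d_i = 0.5 - 0.25 (F_s + F_d) with F = -1 for
    an unknown parent, contributing the classic 1 / 0.75-F/4 / 0.5-... cases.
    """
    si, di = pedigree.parent_indices()
    n = len(pedigree)
    F = inbreeding(pedigree) if inbreeding_coefs is None else np.asarray(inbreeding_coefs, float)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = si[i], di[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        b = 1.0 / (0.5 - 0.25 * (Fs + Fd))
        add(i, i, b)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * b)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


@dataclass(frozen=True)
class FixedEffectsSpec:
    """Fixed-effect layout for the animal model.

    ``factors`` are categorical columns (first level constrained to zero);
    ``covariates`` enter centred. The design always carries an intercept.
    """

    factors: tuple = ("cg",)
    covariates: tuple = ("age",)

    def build_design(self, pheno: pd.DataFrame) -> tuple[np.ndarray, dict[str, slice]]:
        """Design matrix plus per-term column slices (for Wald screening)."""
        cols = [np.ones((len(pheno), 1))]
        slices: dict[str, slice] = {}
        start = 1
        for f in self.factors:
            d = pd.get_dummies(pheno[f], drop_first=True).to_numpy(float)
            cols.append(d)
            slices[f] = slice(start, start + d.shape[1])
            start += d.shape[1]
        for c in self.covariates:
            x = pheno[c].to_numpy(float)
            cols.append((x - x.mean())[:, None])
            slices[c] = slice(start, start + 1)
            start += 1
        X = np.hstack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effects design is rank deficient after constraints")
        return X, slices


@dataclass
class VarianceComponents:
    """Additive and residual variances with derived heritability."""

    sigma_a2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")

    @property
    def h2(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else 0.0

    @property
    def lam(self) -> float:
        """MME shrinkage ratio sigma_e2 / sigma_a2."""
        return self.sigma_e2 / self.sigma_a2


class _Spectral:
    """REML working quantities in the eigenbasis of A restricted to phenotyped animals.

    With one record per phenotyped animal, V = sigma_a2 * A_pp + sigma_e2 * I, and
    A_pp = U diag(w) U' makes every REML quantity O(n f^2) per evaluation.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, A_pp: np.ndarray):
        self.n, self.f = X.shape
        w, U = np.linalg.eigh(A_pp)
        self.w = np.clip(w, 1e-10, None)
        self.ys = U.T @ y
        self.Xs = U.T @ X
        self.U = U

    def loglik_reml(self, sigma_a2: float, sigma_e2: float) -> float:
        v = sigma_a2 * self.w + sigma_e2
        Xv = self.Xs / v[:, None]
        XtVX = self.Xs.T @ Xv
        XtVy = Xv.T @ self.ys
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        beta = np.linalg.solve(XtVX, XtVy)
        r = self.ys - self.Xs @ beta
        quad = np.sum(r * r / v)
        return -0.5 * (np.sum(np.log(v)) + logdet_XtVX + quad)

    def profile_loglik(self, h2: float) -> float:
        """REML log-likelihood profiled over the total variance, at ratio h2."""
        k = h2 * self.w + (1.0 - h2)
        Xk = self.Xs / k[:, None]
        XtKX = self.Xs.T @ Xk
        beta = np.linalg.solve(XtKX, Xk.T @ self.ys)
        r = self.ys - self.Xs @ beta
        quad = float(np.sum(r * r / k))
        s2 = quad / (self.n - self.f)
        _, logdet = np.linalg.slogdet(XtKX)
        return -0.5 * (np.sum(np.log(k)) + logdet + (self.n - self.f) * (1.0 + np.log(s2)))

    def profile_total_variance(self, h2: float) -> float:
        k = h2 * self.w + (1.0 - h2)
        Xk = self.Xs / k[:, None]
        beta = np.linalg.solve(self.Xs.T @ Xk, Xk.T @ self.ys)
        r = self.ys - self.Xs @ beta
        return float(np.sum(r * r / k)) / (self.n - self.f)

    def gls(self, sigma_a2: float, sigma_e2: float):
        v = sigma_a2 * self.w + sigma_e2
        Xv = self.Xs / v[:, None]
        XtVX = self.Xs.T @ Xv
        beta = np.linalg.solve(XtVX, Xv.T @ self.ys)
        return beta, v, XtVX


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    A_pp: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-8,
    start_h2: float = 0.5,
) -> VarianceComponents:
    """EM-REML for the single-trait animal model with one record per animal.

    Parameters
    ----------
    y : phenotypes of the n phenotyped animals.
    X : full-rank fixed-effects design (n x f), including the intercept.
    A_pp : numerator relationship matrix restricted to the phenotyped animals.
    tol : relative-change convergence threshold on both components.

    A profile-likelihood line search over h2 provides the starting point;
    EM updates — the classical MME-based ones,

        sigma_a2 <- (a_hat' A^-1 a_hat + sigma_e2 tr(A^-1 C^aa)) / n
        sigma_e2 <- (y' (y - X b_hat - a_hat)) / (n - f)

    — then run to their fixed point. Everything is evaluated in the
    eigenbasis of ``A_pp``, where each step is closed-form.

    Raises
    ------
    RuntimeError
        If not converged within ``max_iter`` (last iterates attached).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, f = X.shape
    if n < 2:
        raise ValueError("need at least 2 phenotyped animals")
    if np.linalg.matrix_rank(X) < f:
        raise ValueError("fixed-effects design X is rank deficient")
    sp_ = _Spectral(y, X, A_pp)
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("zero phenotypic variance")
    # profile-likelihood search over h2 to land near the optimum, then EM
    # iterations to the EM fixed point (same stationary equations)
    from scipy.optimize import minimize_scalar

    def neg_profile(h2: float) -> float:
        return -sp_.profile_loglik(h2)

    opt = minimize_scalar(neg_profile, bounds=(1e-6, 1 - 1e-6), method="bounded",
                          options={"xatol": 1e-10})
    h2_hat = float(opt.x) if opt.success else start_h2
    s2_hat = sp_.profile_total_variance(h2_hat)
    sa = max(h2_hat * s2_hat, 1e-10 * vary)
    se = max((1 - h2_hat) * s2_hat, 1e-10 * vary)
    w = sp_.w
    for _ in range(max_iter):
        lam = se / sa
        # MME for alpha = U'a: (I + lam*D^-1) alpha + (U'X) b = U'y
        S = 1.0 + lam / w  # diagonal of alpha block
        Xs, ys = sp_.Xs, sp_.ys
        XtSX = Xs.T @ (Xs / S[:, None])
        M = Xs.T @ Xs - XtSX  # X*' (I - S^-1) X*
        rhs = Xs.T @ ys - Xs.T @ (ys / S)
        beta = np.linalg.solve(M + 1e-12 * np.eye(f), rhs) if f else np.zeros(0)
        alpha = (ys - Xs @ beta) / S
        # tr(A^-1 C^aa): C^alpha,alpha = S^-1 + S^-1 X* M^-1 X*' S^-1 (in units of se)
        Sinv = 1.0 / S
        tr1 = np.sum(Sinv / w)
        B = (Xs * Sinv[:, None]) / np.sqrt(w)[:, None]  # rows of S^-1 X* scaled by w^-1/2
        Minv = np.linalg.inv(M + 1e-12 * np.eye(f)) if f else np.zeros((0, 0))
        tr2 = np.einsum("ij,jk,ik->", B, Minv, B) if f else 0.0
        trAinvCaa = (tr1 + tr2) * se
        aAa = np.sum(alpha * alpha / w)
        sa_new = (aAa + trAinvCaa) / n
        resid = ys - Xs @ beta - alpha
        se_new = float(np.dot(ys, resid)) / (n - f)
        # boundary clamp: a component collapsing toward zero is pinned at a
        # small floor so the iteration registers as converged there
        floor = 1e-8 * vary
        se_new = max(se_new, floor)
        sa_new = max(sa_new, floor)
        tiny = 1e-5 * (sa_new + se_new)  # component effectively at the boundary
        conv_a = abs(sa_new - sa) <= tol * max(sa, 1e-12) or sa_new < tiny
        conv_e = abs(se_new - se) <= tol * max(se, 1e-12) or se_new < tiny
        if conv_a and conv_e:
            return VarianceComponents(sa_new, se_new)
        sa, se = sa_new, se_new
    err = RuntimeError(
        f"EM-REML did not converge in {max_iter} iterations "
        f"(last sigma_a2={sa:.6g}, sigma_e2={se:.6g})"
    )
    err.last = VarianceComponents(sa, se)  # type: ignore[attr-defined]
    raise err


@dataclass
class BlupSolution:
    """Solved mixed-model equations for one trait.

    ``ebv`` covers every pedigree animal; ``residuals`` and fitted values only
    the animals whose phenotypes entered the equations.
    """

    b_hat: np.ndarray
    ebv: pd.Series
    residuals: pd.Series
    vc: VarianceComponents
    which: str = "full"  # "full" or "reduced"
    b_cov: np.ndarray | None = None  # Cov(b_hat) for Wald screening

    def corrected(self) -> pd.Series:
        """Corrected phenotypes y_c = EBV + residual for phenotyped animals."""
        return self.ebv.loc[self.residuals.index] + self.residuals


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    pheno_ids: np.ndarray,
    pedigree: Pedigree,
    vc: VarianceComponents,
    A_inv: sp.spmatrix | None = None,
    mask: np.ndarray | None = None,
    which: str = "full",
) -> BlupSolution:
    """Solve Henderson's MME; masked animals still receive EBV through A.

    Parameters
    ----------
    y, X, pheno_ids : records, fixed design and animal id per record.
    mask : boolean per record; True hides that record from the equations
        (the reduced model used for validation-animal EBV).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    pheno_ids = np.asarray(pheno_ids, dtype=object)
    if mask is None:
        mask = np.zeros(len(y), dtype=bool)
    use = ~np.asarray(mask, bool)
    if use.sum() == 0:
        raise ValueError("all phenotypes masked")
    if A_inv is None:
        A_inv = build_A_inverse(pedigree)
    n_anim = len(pedigree)
    yu, Xu = y[use], X[use]
    idx = pedigree.index_of(pheno_ids[use])
    f = Xu.shape[1]
    Z = sp.csr_matrix((np.ones(use.sum()), (np.arange(use.sum()), idx)), shape=(use.sum(), n_anim))
    lam = vc.lam if vc.sigma_a2 > 0 else None
    if lam is None:
        # no genetic variance: GLS fixed effects only, EBV identically zero
        b = np.linalg.lstsq(Xu, yu, rcond=None)[0]
        ebv = pd.Series(np.zeros(n_anim), index=pedigree.animal)
        resid = pd.Series(y - X @ b, index=pheno_ids)
        return BlupSolution(b, ebv, resid, vc, which)
    XtX = Xu.T @ Xu
    # pin the effect of any factor level with no unmasked records to zero,
    # keeping the equations solvable without perturbing well-posed systems
    if f:
        empty = np.diag(XtX) <= 1e-12 * max(float(np.max(np.diag(XtX))), 1.0)
        XtX = XtX + np.diag(np.where(empty, 1.0, 0.0))
    XtZ = Xu.T @ Z
    C = sp.bmat(
        [
            [sp.csr_matrix(XtX), XtZ],
            [XtZ.T, Z.T @ Z + lam * A_inv],
        ],
        format="csc",
    )
    rhs = np.concatenate([Xu.T @ yu, Z.T @ yu])
    lu = spla.splu(C)
    sol = lu.solve(rhs)
    b, a = sol[:f], sol[f:]
    # Cov(b_hat) = sigma_e2 * C^bb (solve for the first f columns)
    if f:
        Cbb = np.column_stack(
            [lu.solve(np.eye(C.shape[0], 1, -i).ravel()) for i in range(f)]
        )[:f]
    else:
        Cbb = np.zeros((0, 0))
    ebv = pd.Series(a, index=pedigree.animal)
    fitted_idx = pedigree.index_of(pheno_ids)
    resid_vals = y - X @ b - a[fitted_idx]
    resid = pd.Series(resid_vals, index=pheno_ids)
    return BlupSolution(b, ebv, resid, vc, which, b_cov=vc.sigma_e2 * Cbb)


def corrected_phenotypes(solution: BlupSolution) -> pd.Series:
    """y_c = EBV + residual; equals y - X b_hat for phenotyped animals."""
    return solution.corrected()


def split_train_validation(pedigree: Pedigree, cutoff_date) -> tuple[np.ndarray, np.ndarray]:
    """Partition animals by birthdate: before cutoff -> training, on/after -> validation."""
    if pedigree.birthdate is None:
        raise ValueError("pedigree has no birthdates")
    bd = pedigree.birthdate
    is_val = np.array([b >= cutoff_date for b in bd])
    return pedigree.animal[~is_val], pedigree.animal[is_val]


class PedigreeBLUP(BaseEstimator):
    """Single-trait pedigree animal model (BLUP) estimator.

    Fits ``y = X b + a + e`` with ``a ~ N(0, A sigma_a2)`` where ``A`` comes
    from a pedigree supplied at fit time. Variance components are estimated by
    EM-REML unless provided.

    Parameters
    ----------
    sigma_a2, sigma_e2 : float or None
        Known variance components; both None triggers EM-REML.
    em_max_iter, tol : EM-REML controls.

    Attributes
    ----------
    vc_ : VarianceComponents
    h2_ : float
    b_hat_ : fixed-effect solutions
    ebv_ : pandas Series of EBV for every pedigree animal
    residuals_ : Series for phenotyped (unmasked) records
    solution_ : the underlying BlupSolution
    """

    def __init__(self, sigma_a2=None, sigma_e2=None, em_max_iter=2000, tol=1e-8):
        self.sigma_a2 = sigma_a2
        self.sigma_e2 = sigma_e2
        self.em_max_iter = em_max_iter
        self.tol = tol

    def fit(self, X, y, *, pedigree: Pedigree, pheno_ids, mask=None):
        y = np.asarray(y, float)
        X = np.ones((len(y), 1)) if X is None else np.atleast_2d(np.asarray(X, float))
        pheno_ids = np.asarray(pheno_ids, dtype=object)
        if mask is None:
            mask = np.zeros(len(y), dtype=bool)
        mask = np.asarray(mask, bool)
        if self.sigma_a2 is not None and self.sigma_e2 is not None:
            vc = VarianceComponents(float(self.sigma_a2), float(self.sigma_e2))
        else:
            A = build_A(pedigree)
            idx = pedigree.index_of(pheno_ids[~mask])
            vc = em_reml(
                y[~mask], X[~mask], A[np.ix_(idx, idx)],
                max_iter=self.em_max_iter, tol=self.tol,
            )
        sol = solve_mme(
            y, X, pheno_ids, pedigree, vc, mask=mask,
            which="reduced" if mask.any() else "full",
        )
        self.vc_ = vc
        self.h2_ = vc.h2
        self.b_hat_ = sol.b_hat
        self.ebv_ = sol.ebv
        self.residuals_ = sol.residuals
        self.solution_ = sol
        return self

    def predict(self, ids) -> np.ndarray:
        """EBV for the requested animal ids."""
        return self.ebv_.loc[np.asarray(ids, dtype=object)].to_numpy()


def wald_screen_fixed_effects(
    solution: BlupSolution, term_slices: dict[str, slice], alpha: float = 0.01
) -> dict[str, dict]:
    """Wald chi-square test per fixed-effect term against a P threshold.

    ``term_slices`` maps a term name to its columns in the design matrix
    (the intercept is never screened). Returns per-term statistic, df, p-value
    and keep flag (p < alpha).
    """
    from scipy.stats import chi2

    if solution.b_cov is None:
        raise ValueError("solution carries no Cov(b_hat); fit through solve_mme")
    out = {}
    for name, sl in term_slices.items():
        b = solution.b_hat[sl]
        V = solution.b_cov[sl, sl]
        stat = float(b @ np.linalg.solve(V, b))
        df = len(b)
        p = float(chi2.sf(stat, df))
        out[name] = {"stat": stat, "df": df, "p": p, "keep": p < alpha}
    return out
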