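"""Compiled Gibbs-sampler kernels for the Bayesian-alphabet models.

Each kernel maintains the residual vector incrementally, seeds numba's
internal RNG explicitly, and returns post-burn-in posterior summaries.
Scaled-inverse-chi-square draws use nu*S / chi2(nu) via the gamma sampler.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["bayes_cpi_kernel", "bayes_b_kernel", "bayesrc_kernel"]


@njit(cache=True, fastmath=False)
def _sinv_chi2(nu: float, S: float) -> float:
    """Draw from a scaled-inverse-chi-square(nu, S) distribution."""
    chi2 = 2.0 * np.random.gamma(nu / 2.0, 1.0)
    return nu * S / max(chi2, 1e-300)


@njit(cache=True)
def _update_fixed(X, b, e, sigma_e2):
    """Flat-prior Gibbs update of fixed effects; e kept in sync."""
    n, f = X.shape
    for k in range(f):
        xk = X[:, k]
        xx = 0.0
        xe = 0.0
        for i in range(n):
            xx += xk[i] * xk[i]
            xe += xk[i] * (e[i] + xk[i] * b[k])
        if xx <= 0.0:
            continue
        new = np.random.normal(xe / xx, np.sqrt(sigma_e2 / xx))
        diff = new - b[k]
        for i in range(n):
            e[i] -= diff * xk[i]
        b[k] = new


@njit(cache=True)
def bayes_cpi_kernel(
    y, X, Z, n_iter, burn_in, seed,
    nu_alpha, S_alpha_base, nu_e, S_e, pi_init, estimate_pi,
):
    """BayesC(pi): common marker variance, pi ~ Beta from inclusion counts.

    Z columns are the (centred) genotype covariates. The prior scale of the
    common marker variance tracks the current pi — scale =
    ``S_alpha_base / (1 - pi)`` — so the implied genetic variance of the
    included fraction stays constant as pi moves. Returns posterior means of
    (alpha, inclusion, pi, sigma_e2, sigma_alpha2) and the pi chain.
    """
    np.random.seed(seed)
    n, p = Z.shape
    f = X.shape[1]
    zz = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s
    b = np.zeros(f)
    alpha = np.zeros(p)
    delta = np.zeros(p, dtype=np.int64)
    e = y.copy()
    pi = pi_init
    sigma_e2 = S_e
    sigma_a2 = S_alpha_base / max(1.0 - pi, 1.0 / p)
    mean_alpha = np.zeros(p)
    mean_incl = np.zeros(p)
    pi_chain = np.zeros(n_iter)
    mean_pi = 0.0
    mean_se = 0.0
    mean_sa = 0.0
    kept = 0
    for it in range(n_iter):
        _update_fixed(X, b, e, sigma_e2)
        n_in = 0
        sum_a2 = 0.0
        log_pi = np.log(max(pi, 1e-300))
        log_1mpi = np.log(max(1.0 - pi, 1e-300))
        for j in range(p):
            if zz[j] <= 0.0:
                continue
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * e[i]
            old = alpha[j] if delta[j] == 1 else 0.0
            rhs += zz[j] * old
            c = zz[j] * sigma_a2 + sigma_e2
            l1 = -0.5 * np.log(c / sigma_e2) + 0.5 * rhs * rhs * sigma_a2 / (sigma_e2 * c)
            # P(delta=1 | rest)
            lodds = log_1mpi - log_pi + l1
            prob1 = 1.0 / (1.0 + np.exp(-lodds))
            new_delta = 1 if np.random.random() < prob1 else 0
            new_alpha = 0.0
            if new_delta == 1:
                prec = zz[j] + sigma_e2 / sigma_a2
                new_alpha = np.random.normal(rhs / prec, np.sqrt(sigma_e2 / prec))
                n_in += 1
                sum_a2 += new_alpha * new_alpha
            diff = new_alpha - old
            if diff != 0.0:
                for i in range(n):
                    e[i] -= diff * Z[i, j]
            alpha[j] = new_alpha
            delta[j] = new_delta
        # common marker variance; prior scale follows the current pi
        S_alpha = S_alpha_base / max(1.0 - pi, 1.0 / p)
        sigma_a2 = _sinv_chi2(nu_alpha + n_in, (nu_alpha * S_alpha + sum_a2) / (nu_alpha + n_in))
        if estimate_pi == 1:
            a_beta = np.random.gamma(p - n_in + 1.0, 1.0)
            b_beta = np.random.gamma(n_in + 1.0, 1.0)
            pi = a_beta / (a_beta + b_beta)
        ee = 0.0
        for i in range(n):
            ee += e[i] * e[i]
        sigma_e2 = _sinv_chi2(nu_e + n, (nu_e * S_e + ee) / (nu_e + n))
        pi_chain[it] = pi
        if it >= burn_in:
            kept += 1
            mean_pi += pi
            mean_se += sigma_e2
            mean_sa += sigma_a2
            for j in range(p):
                if delta[j] == 1:
                    mean_alpha[j] += alpha[j]
                    mean_incl[j] += 1.0
    mean_alpha /= kept
    mean_incl /= kept
    return mean_alpha, mean_incl, mean_pi / kept, mean_se / kept, mean_sa / kept, pi_chain


@njit(cache=True)
def bayes_b_kernel(
    y, X, Z, n_iter, burn_in, seed,
    pi, nu_loc, S_loc, nu_e, S_e,
):
    """BayesB: per-locus variances with scaled-inverse-chi-square prior.

    delta_j sampled from the marginal likelihood ratio given the current
    locus variance; sigma_j^2 redrawn from its conditional (the prior when
    the locus is excluded). pi is fixed.
    """
    np.random.seed(seed)
    n, p = Z.shape
    zz = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s
    b = np.zeros(X.shape[1])
    alpha = np.zeros(p)
    delta = np.zeros(p, dtype=np.int64)
    sig_j = np.empty(p)
    for j in range(p):
        sig_j[j] = _sinv_chi2(nu_loc, S_loc)
    e = y.copy()
    sigma_e2 = S_e
    mean_alpha = np.zeros(p)
    mean_incl = np.zeros(p)
    mean_se = 0.0
    kept = 0
    log_pi = np.log(max(pi, 1e-300))
    log_1mpi = np.log(max(1.0 - pi, 1e-300))
    for it in range(n_iter):
        _update_fixed(X, b, e, sigma_e2)
        for j in range(p):
            if zz[j] <= 0.0:
                continue
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * e[i]
            old = alpha[j] if delta[j] == 1 else 0.0
            rhs += zz[j] * old
            if pi >= 1.0:
                new_delta = 0
            else:
                c = zz[j] * sig_j[j] + sigma_e2
                l1 = -0.5 * np.log(c / sigma_e2) + 0.5 * rhs * rhs * sig_j[j] / (sigma_e2 * c)
                lodds = log_1mpi - log_pi + l1
                prob1 = 1.0 / (1.0 + np.exp(-lodds))
                new_delta = 1 if np.random.random() < prob1 else 0
            new_alpha = 0.0
            if new_delta == 1:
                prec = zz[j] + sigma_e2 / sig_j[j]
                new_alpha = np.random.normal(rhs / prec, np.sqrt(sigma_e2 / prec))
                sig_j[j] = _sinv_chi2(nu_loc + 1.0, (nu_loc * S_loc + new_alpha * new_alpha) / (nu_loc + 1.0))
            else:
                sig_j[j] = _sinv_chi2(nu_loc, S_loc)
            diff = new_alpha - old
            if diff != 0.0:
                for i in range(n):
                    e[i] -= diff * Z[i, j]
            alpha[j] = new_alpha
            delta[j] = new_delta
        ee = 0.0
        for i in range(n):
            ee += e[i] * e[i]
        sigma_e2 = _sinv_chi2(nu_e + n, (nu_e * S_e + ee) / (nu_e + n))
        if it >= burn_in:
            kept += 1
            mean_se += sigma_e2
            for j in range(p):
                if delta[j] == 1:
                    mean_alpha[j] += alpha[j]
                    mean_incl[j] += 1.0
    mean_alpha /= kept
    mean_incl /= kept
    return mean_alpha, mean_incl, mean_se / kept


@njit(cache=True)
def bayesrc_kernel(
    y, W, classes, n_classes, gamma, sigma_g2,
    Ainv_indptr, Ainv_indices, Ainv_data, rec_of_animal,
    n_iter, burn_in, seed,
    nu_e, S_e, nu_a, S_a, dirichlet_alpha,
):
    """BayesRC: four-normal mixture on standardized covariates with
    class-specific Dirichlet mixture proportions and a pedigree polygenic term.

    Parameters
    ----------
    y : training corrected phenotypes (length n records, one per animal).
    W : standardized covariates (n x p).
    classes : int class index per variant (0..n_classes-1).
    gamma : the 4 variance multipliers (first exactly 0).
    Ainv_* : CSR of the pedigree A-inverse over n_anim animals.
    rec_of_animal : record index per pedigree animal, -1 if unphenotyped.

    Returns posterior means: v (standardized scale), per-variant component
    probabilities, per-class mixture proportions, polygenic values, mu,
    sigma_e2, sigma_a2.
    """
    np.random.seed(seed)
    n, p = W.shape
    n_comp = gamma.shape[0]
    n_anim = rec_of_animal.shape[0]
    ww = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        ww[j] = s
    v = np.zeros(p)
    comp = np.zeros(p, dtype=np.int64)
    a = np.zeros(n_anim)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu
    sigma_e2 = S_e
    sigma_a2 = S_a
    # per-class mixture proportions
    pi_cls = np.full((n_classes, n_comp), 1.0 / n_comp)
    sv = np.empty(n_comp)
    logl = np.empty(n_comp)
    mean_v = np.zeros(p)
    mean_comp = np.zeros((p, n_comp))
    mean_pi = np.zeros((n_classes, n_comp))
    mean_a = np.zeros(n_anim)
    mean_mu = 0.0
    mean_se = 0.0
    mean_sa = 0.0
    kept = 0
    for k in range(n_comp):
        sv[k] = gamma[k] * sigma_g2
    counts = np.zeros((n_classes, n_comp))
    for it in range(n_iter):
        # mu (flat prior)
        s = 0.0
        for i in range(n):
            s += e[i] + mu
        new_mu = np.random.normal(s / n, np.sqrt(sigma_e2 / n))
        dmu = new_mu - mu
        for i in range(n):
            e[i] -= dmu
        mu = new_mu
        # variant effects: enumerate the mixture components
        for c in range(n_classes):
            for k in range(n_comp):
                counts[c, k] = 0.0
        collect = it >= burn_in
        for j in range(p):
            rhs = 0.0
            for i in range(n):
                rhs += W[i, j] * e[i]
            old = v[j]
            rhs += ww[j] * old
            c = classes[j]
            maxl = -1.0e300
            for k in range(n_comp):
                if sv[k] <= 0.0:
                    lk = np.log(max(pi_cls[c, k], 1e-300))
                else:
                    cc = ww[j] * sv[k] + sigma_e2
                    lk = (
                        np.log(max(pi_cls[c, k], 1e-300))
                        - 0.5 * np.log(cc / sigma_e2)
                        + 0.5 * rhs * rhs * sv[k] / (sigma_e2 * cc)
                    )
                logl[k] = lk
                if lk > maxl:
                    maxl = lk
            tot = 0.0
            for k in range(n_comp):
                logl[k] = np.exp(logl[k] - maxl)
                tot += logl[k]
            u = np.random.random() * tot
            acc = 0.0
            kk = n_comp - 1
            for k in range(n_comp):
                acc += logl[k]
                if u <= acc:
                    kk = k
                    break
            new_v = 0.0
            if sv[kk] > 0.0:
                prec = ww[j] + sigma_e2 / sv[kk]
                new_v = np.random.normal(rhs / prec, np.sqrt(sigma_e2 / prec))
            diff = new_v - old
            if diff != 0.0:
                for i in range(n):
                    e[i] -= diff * W[i, j]
            v[j] = new_v
            comp[j] = kk
            counts[c, kk] += 1.0
            if collect:
                # Rao-Blackwellised accumulation: conditional mean over the
                # mixture instead of the sampled draw (lower MC variance)
                ev = 0.0
                for k in range(1, n_comp):
                    prec = ww[j] + sigma_e2 / sv[k]
                    ev += (logl[k] / tot) * rhs / prec
                mean_v[j] += ev
                for k in range(n_comp):
                    mean_comp[j, k] += logl[k] / tot
        # class mixture proportions ~ Dirichlet(alpha + counts)
        for c in range(n_classes):
            tot = 0.0
            for k in range(n_comp):
                g = np.random.gamma(dirichlet_alpha[k] + counts[c, k], 1.0)
                pi_cls[c, k] = g
                tot += g
            for k in range(n_comp):
                pi_cls[c, k] /= tot
        # polygenic effects: single-site Gibbs with sparse A-inverse
        for ia in range(n_anim):
            dii = 0.0
            off = 0.0
            for ptr in range(Ainv_indptr[ia], Ainv_indptr[ia + 1]):
                jj = Ainv_indices[ptr]
                if jj == ia:
                    dii += Ainv_data[ptr]
                else:
                    off += Ainv_data[ptr] * a[jj]
            prec = dii / sigma_a2
            mean_num = -off / sigma_a2
            r = rec_of_animal[ia]
            if r >= 0:
                prec += 1.0 / sigma_e2
                mean_num += (e[r] + a[ia]) / sigma_e2
            new_a = np.random.normal(mean_num / prec, np.sqrt(1.0 / prec))
            if r >= 0:
                e[r] -= new_a - a[ia]
            a[ia] = new_a
        # polygenic variance: a' Ainv a
        qf = 0.0
        for ia in range(n_anim):
            for ptr in range(Ainv_indptr[ia], Ainv_indptr[ia + 1]):
                qf += a[ia] * Ainv_data[ptr] * a[Ainv_indices[ptr]]
        sigma_a2 = _sinv_chi2(nu_a + n_anim, (nu_a * S_a + qf) / (nu_a + n_anim))
        ee = 0.0
        for i in range(n):
            ee += e[i] * e[i]
        sigma_e2 = _sinv_chi2(nu_e + n, (nu_e * S_e + ee) / (nu_e + n))
        if it >= burn_in:
            kept += 1
            mean_mu += mu
            mean_se += sigma_e2
            mean_sa += sigma_a2
            for c in range(n_classes):
                for k in range(n_comp):
                    mean_pi[c, k] += pi_cls[c, k]
            for ia in range(n_anim):
                mean_a[ia] += a[ia]
    mean_v /= kept
    mean_comp /= kept
    mean_pi /= kept
    mean_a /= kept
    return (
        mean_v,
        mean_comp,
        mean_pi,
        mean_a,
        mean_mu / kept,
        mean_se / kept,
        mean_sa / kept,
    )
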