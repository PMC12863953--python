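"""Numba Gibbs kernel for the linear and threshold animal models.

Single-site updates throughout:

* contemporary-group effects beta_j from normal full conditionals with a
  vague N(0, sigma2_b) prior (sigma2_b = 1e10 by default, effectively flat);
* animal effects a_k from normal full conditionals whose prior precision
  contribution is Hinv[k, :] / sigma2_a;
* variance components from scaled inverse chi-square full conditionals;
* for the threshold model, each latent liability from a normal full
  conditional truncated at t = 0 on the side dictated by its category
  (category 1: l <= 0, category 2: l > 0), with sigma2_e fixed at 1.

A running vector w = Hinv @ a is maintained incrementally (and refreshed
periodically against drift) so one sweep costs O(n_records + n_animals^2).

The inverse normal CDF (Acklam's rational approximation) and a
tail-robust truncated-normal sampler are hand-coded here because the
kernel cannot call scipy.
"""

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _ndtri(p):
    """Inverse standard normal CDF (Acklam's rational approximation).

    Absolute error below 1.2e-9 over (0, 1); adequate for sampling.
    """
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    a = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
         1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
         6.680131188771972e+01, -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
         -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
         3.754408661907416e+00)
    p_low = 0.02425
    if p < p_low:
        q = math.sqrt(-2.0 * math.log(p))
        return (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
               ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    if p > 1.0 - p_low:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        return -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
                ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    q = p - 0.5
    r = q * q
    return (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / \
           (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / SQRT2)


@njit(cache=True)
def _sample_trunc_std_lower(a):
    """Standard normal truncated to (a, inf).

    Inverse-CDF for moderate a; Robert's shifted-exponential rejection
    for a > 4 where the CDF saturates.
    """
    if a > 4.0:
        lam = 0.5 * (a + math.sqrt(a * a + 4.0))
        while True:
            z = a + np.random.exponential(1.0 / lam)
            rho = math.exp(-0.5 * (z - lam) ** 2)
            if np.random.random() <= rho:
                return z
    cdf_a = _norm_cdf(a)
    u = cdf_a + np.random.random() * (1.0 - cdf_a)
    return _ndtri(u)


@njit(cache=True)
def sample_truncated_normal(mu, sd, bound, lower_tail):
    """Normal(mu, sd) truncated below ``bound`` (lower_tail) or above it."""
    if lower_tail:
        # X <= bound: reflect
        return mu - sd * _sample_trunc_std_lower((mu - bound) / sd)
    return mu + sd * _sample_trunc_std_lower((bound - mu) / sd)


@njit(cache=True)
def gibbs_kernel(
    y,            # float64[n_rec]: observed 0/1
    rec_animal,   # int64[n_rec]: animal index per record
    rec_cg,       # int64[n_rec]: CG index per record
    hinv,         # float64[n_anim, n_anim]
    n_cg,
    n_iter,
    burn_in,
    thin,
    threshold_model,  # bool
    fix_variances,    # bool
    s2a_init,
    s2e_init,
    cg_prior_var,
    nu_a, scale_a, nu_e, scale_e,
    seed,
):
    np.random.seed(seed)
    n_rec = y.shape[0]
    n_anim = hinv.shape[0]

    # CSR-style record lists per CG and per animal
    cg_count = np.zeros(n_cg, dtype=np.int64)
    an_count = np.zeros(n_anim, dtype=np.int64)
    for r in range(n_rec):
        cg_count[rec_cg[r]] += 1
        an_count[rec_animal[r]] += 1
    cg_ptr = np.zeros(n_cg + 1, dtype=np.int64)
    an_ptr = np.zeros(n_anim + 1, dtype=np.int64)
    for j in range(n_cg):
        cg_ptr[j + 1] = cg_ptr[j] + cg_count[j]
    for k in range(n_anim):
        an_ptr[k + 1] = an_ptr[k] + an_count[k]
    cg_idx = np.zeros(n_rec, dtype=np.int64)
    an_idx = np.zeros(n_rec, dtype=np.int64)
    cg_fill = cg_ptr[:-1].copy()
    an_fill = an_ptr[:-1].copy()
    for r in range(n_rec):
        j = rec_cg[r]
        cg_idx[cg_fill[j]] = r
        cg_fill[j] += 1
        k = rec_animal[r]
        an_idx[an_fill[k]] = r
        an_fill[k] += 1

    beta = np.zeros(n_cg)
    a = np.zeros(n_anim)
    s2a = s2a_init
    s2e = 1.0 if threshold_model else s2e_init

    # working response: latent liability (threshold) or the record itself
    if threshold_model:
        work = np.empty(n_rec)
        for r in range(n_rec):
            work[r] = 0.5 if y[r] > 0.5 else -0.5
    else:
        work = y.copy()
    resid = work.copy()  # beta = a = 0 initially

    w = np.zeros(n_anim)  # Hinv @ a, maintained incrementally

    n_keep = (n_iter - burn_in) // thin
    keep_s2a = np.zeros(n_keep)
    keep_s2e = np.zeros(n_keep)
    keep_a = np.zeros((n_keep, n_anim))
    kept = 0

    for it in range(n_iter):
        # --- latent liabilities (threshold model) ---
        if threshold_model:
            sde = math.sqrt(s2e)
            for r in range(n_rec):
                mu = work[r] - resid[r]  # current Xb + Za for this record
                lower_tail = y[r] < 0.5  # category 1: l <= 0
                new = sample_truncated_normal(mu, sde, 0.0, lower_tail)
                resid[r] += new - work[r]
                work[r] = new

        # --- CG effects ---
        for j in range(n_cg):
            nj = cg_ptr[j + 1] - cg_ptr[j]
            if nj == 0:
                continue
            ssum = 0.0
            for q in range(cg_ptr[j], cg_ptr[j + 1]):
                r = cg_idx[q]
                resid[r] += beta[j]
                ssum += resid[r]
            prec = nj / s2e + 1.0 / cg_prior_var
            mean = (ssum / s2e) / prec
            beta[j] = mean + np.random.standard_normal() / math.sqrt(prec)
            for q in range(cg_ptr[j], cg_ptr[j + 1]):
                resid[cg_idx[q]] -= beta[j]

        # --- animal effects ---
        for k in range(n_anim):
            nk = an_ptr[k + 1] - an_ptr[k]
            ssum = 0.0
            for q in range(an_ptr[k], an_ptr[k + 1]):
                r = an_idx[q]
                resid[r] += a[k]
                ssum += resid[r]
            hkk = hinv[k, k]
            prior_rhs = (w[k] - hkk * a[k]) / s2a  # sum_{j != k} Hinv_kj a_j / s2a
            prec = nk / s2e + hkk / s2a
            mean = (ssum / s2e - prior_rhs) / prec
            new = mean + np.random.standard_normal() / math.sqrt(prec)
            delta = new - a[k]
            a[k] = new
            # incremental update of w = Hinv @ a; row access exploits symmetry
            for m in range(n_anim):
                w[m] += hinv[k, m] * delta
            for q in range(an_ptr[k], an_ptr[k + 1]):
                resid[an_idx[q]] -= a[k]

        # periodic refresh of w against floating-point drift
        if (it + 1) % 1000 == 0:
            w = hinv @ a

        # --- variance components ---
        if not fix_variances:
            ssa = 0.0
            for m in range(n_anim):
                ssa += a[m] * w[m]
            df_a = n_anim + nu_a
            s2a = (ssa + nu_a * scale_a) / np.random.chisquare(df_a)
            if not threshold_model:
                sse = 0.0
                for r in range(n_rec):
                    sse += resid[r] * resid[r]
                df_e = n_rec + nu_e
                s2e = (sse + nu_e * scale_e) / np.random.chisquare(df_e)

        # --- storage ---
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            keep_s2a[kept] = s2a
            keep_s2e[kept] = s2e
            for m in range(n_anim):
                keep_a[kept, m] = a[m]
            kept += 1

    return keep_s2a, keep_s2e, keep_a
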