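"""Compiled inner loops for the joint log density and gradient.

The observation model's density is a sum over three row blocks (one per
gaze measure).  Each block shares the same algebra: the weighting kernel
applied to D_KL, a hierarchical linear predictor, and either a
Bernoulli-logit or Gaussian likelihood.  This module provides a single-pass
row loop per block, compiled with numba when available; the pure-numpy
implementation in :mod:`metagaze.inference.model` produces identical values
and serves as the uncompiled fallback.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=False)
def block_logp_grad(
    bernoulli,      # bool: Bernoulli-logit block (else Gaussian)
    comb,           # per-row index into the unique (sequence, trial) combos
    u_s, u_t, u_d,  # unique combo data: sequence, trial, scaled D_KL
    inf, t_c, s_c, y,            # per-row data
    lam0, lam1, beta0, beta1,    # weighting kernel
    a, b, c, dd,                 # block regression params
    sigma, tau, z,               # noise scale, subject sd, subject z-scores
    grad_z,                      # out: per-subject gradient accumulator
):
    """Log likelihood of one block and its gradient components.

    The weighting kernel and D_KL depend only on the (sequence, trial)
    combination, so they are evaluated once per unique combo and gathered
    per row.  Returns ``(logp, g_a, g_b, g_c, g_d, g_sigma, g_tau, g_lam0,
    g_lam1, g_beta0, g_beta1)`` with kernel gradients on the natural scale
    and ``g_sigma``/``g_tau`` with respect to ``sigma``/``tau`` directly.
    ``grad_z`` accumulates the per-subject score contributions.
    """
    n_comb = u_s.shape[0]
    u_lam = np.empty(n_comb)
    u_ig = np.empty(n_comb)
    for k in range(n_comb):
        u_lam[k] = lam0 + lam1 * u_s[k]
        rate = beta0 + beta1 * u_s[k]
        u_ig[k] = u_lam[k] * np.exp(-u_t[k] * rate) * u_d[k]

    n = comb.shape[0]
    logp = 0.0
    g_a = 0.0
    g_b = 0.0
    g_c = 0.0
    g_d = 0.0
    g_sigma = 0.0
    g_tau = 0.0
    acc = np.zeros(n_comb)  # sum of dmu * coef per combo
    inv_sig2 = 1.0 / (sigma * sigma)
    for i in range(n):
        k = comb[i]
        ig = u_ig[k]
        zi = z[inf[i]]
        coef = b + tau * zi
        mu = a + coef * ig + c * t_c[i] + dd * s_c[i]
        if bernoulli:
            if mu > 30.0:
                log1pexp = mu
            else:
                log1pexp = np.log1p(np.exp(mu))
            logp += y[i] * mu - log1pexp
            p = 1.0 / (1.0 + np.exp(-mu))
            dmu = y[i] - p
        else:
            r = y[i] - mu
            logp += -0.5 * r * r * inv_sig2
            dmu = r * inv_sig2
            g_sigma += r * r
        g_a += dmu
        g_b += dmu * ig
        g_c += dmu * t_c[i]
        g_d += dmu * s_c[i]
        grad_z[inf[i]] += tau * dmu * ig
        g_tau += dmu * ig * zi
        acc[k] += dmu * coef
    g_lam0 = 0.0
    g_lam1 = 0.0
    g_beta0 = 0.0
    g_beta1 = 0.0
    for k in range(n_comb):
        t1 = acc[k] * u_ig[k]
        g_lam0 += t1 / u_lam[k]
        g_lam1 += t1 * u_s[k] / u_lam[k]
        g_beta0 -= t1 * u_t[k]
        g_beta1 -= t1 * u_t[k] * u_s[k]
    if not bernoulli:
        logp += -n * np.log(sigma)
        # d/dsigma: -n/sigma + sum r^2 / sigma^3
        g_sigma = -n / sigma + g_sigma / (sigma * sigma * sigma)
    return (
        logp, g_a, g_b, g_c, g_d, g_sigma, g_tau,
        g_lam0, g_lam1, g_beta0, g_beta1,
    )
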