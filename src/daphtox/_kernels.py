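"""Compiled evaluation kernel for the unconstrained log-posterior.

A numba-jitted mirror of ``UnconstrainedPosterior.logp_and_grad``; the
pure-numpy implementation in :mod:`daphtox.model` remains the reference
(the two are cross-checked in the test suite) and the automatic fallback
when numba is unavailable.
"""

from __future__ import annotations

import math


try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # noqa: D103
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def _digamma(x: float) -> float:
    # recurrence to x >= 6, then the asymptotic series
    result = 0.0
    while x < 6.0:
        result -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    result += (
        math.log(x)
        - 0.5 * inv
        - inv2 * (1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0))
    )
    return result


@njit(cache=True)
def _logp_grad_kernel(
    q,
    X,
    cpf,
    pop_idx,
    clone_idx,
    N,
    y,
    log_binom_sum,
    n_pop,
    n_clone,
    beta_df,
    beta_loc,
    beta_scale,
    sd_df,
    sd_scale,
    nu_shape,
    nu_rate,
    grad,
):
    n_beta = X.shape[1]
    n_units = X.shape[0]
    i_pop0 = n_beta
    i_clone0 = n_beta + n_pop
    i_lsp = n_beta + n_pop + n_clone
    i_lsc = i_lsp + 1
    i_lnu = i_lsp + 2

    s_pop = math.exp(q[i_lsp])
    s_clone = math.exp(q[i_lsc])
    nu = math.exp(q[i_lnu])

    for i in range(grad.shape[0]):
        grad[i] = 0.0

    logp = log_binom_sum
    d_lsp_lik = 0.0
    d_lsc_lik = 0.0
    for i in range(n_units):
        eta = 0.0
        for j in range(n_beta):
            eta += X[i, j] * q[j]
        zp = q[i_pop0 + pop_idx[i]]
        zc = q[i_clone0 + clone_idx[i]]
        eta += cpf[i] * (s_pop * zp + s_clone * zc)
        # y*eta - N*log(1+exp(eta)), stable
        if eta > 0.0:
            log1pe = eta + math.log1p(math.exp(-eta))
        else:
            log1pe = math.log1p(math.exp(eta))
        logp += y[i] * eta - N[i] * log1pe
        p = 1.0 / (1.0 + math.exp(-eta))
        r = y[i] - N[i] * p
        for j in range(n_beta):
            grad[j] += X[i, j] * r
        cr = cpf[i] * r
        grad[i_pop0 + pop_idx[i]] += s_pop * cr
        grad[i_clone0 + clone_idx[i]] += s_clone * cr
        d_lsp_lik += zp * cr
        d_lsc_lik += zc * cr

    # StudentT(beta_df, beta_loc, beta_scale) prior on each coefficient
    bss = beta_df * beta_scale * beta_scale
    beta_const = (
        math.lgamma((beta_df + 1.0) / 2.0)
        - math.lgamma(beta_df / 2.0)
        - 0.5 * math.log(beta_df * math.pi * beta_scale * beta_scale)
    )
    for j in range(n_beta):
        bc = q[j] - beta_loc
        logp += beta_const - (beta_df + 1.0) / 2.0 * math.log1p(bc * bc / bss)
        grad[j] += -(beta_df + 1.0) * bc / (bss + bc * bc)

    # standard normal on z_pop
    for k in range(n_pop):
        zp = q[i_pop0 + k]
        logp += -0.5 * zp * zp - 0.5 * math.log(2.0 * math.pi)
        grad[i_pop0 + k] -= zp

    # standard StudentT(nu) on z_clone
    t_const = (
        math.lgamma((nu + 1.0) / 2.0)
        - math.lgamma(nu / 2.0)
        - 0.5 * math.log(nu * math.pi)
    )
    sum_log1p = 0.0
    sum_frac = 0.0
    for c in range(n_clone):
        zc = q[i_clone0 + c]
        z2 = zc * zc
        sum_log1p += math.log1p(z2 / nu)
        sum_frac += z2 / (nu + z2)
        grad[i_clone0 + c] += -(nu + 1.0) * zc / (nu + z2)
    logp += n_clone * t_const - (nu + 1.0) / 2.0 * sum_log1p

    # half-StudentT(sd_df, 0, sd_scale) priors on the scales + Jacobians
    sss = sd_df * sd_scale * sd_scale
    half_t_const = (
        math.log(2.0)
        + math.lgamma((sd_df + 1.0) / 2.0)
        - math.lgamma(sd_df / 2.0)
        - 0.5 * math.log(sd_df * math.pi * sd_scale * sd_scale)
    )
    logp += (
        half_t_const
        - (sd_df + 1.0) / 2.0 * math.log1p(s_pop * s_pop / sss)
        + math.log(s_pop)
    )
    grad[i_lsp] = (
        s_pop * d_lsp_lik
        - (sd_df + 1.0) * s_pop * s_pop / (sss + s_pop * s_pop)
        + 1.0
    )
    logp += (
        half_t_const
        - (sd_df + 1.0) / 2.0 * math.log1p(s_clone * s_clone / sss)
        + math.log(s_clone)
    )
    grad[i_lsc] = (
        s_clone * d_lsc_lik
        - (sd_df + 1.0) * s_clone * s_clone / (sss + s_clone * s_clone)
        + 1.0
    )

    # Gamma(shape, rate) prior on nu (+ log-Jacobian of nu = exp(l_nu))
    logp += (
        nu_shape * math.log(nu_rate)
        - math.lgamma(nu_shape)
        + (nu_shape - 1.0) * q[i_lnu]
        - nu_rate * nu
        + q[i_lnu]
    )
    dlogt_dnu = (
        0.5 * n_clone * (_digamma((nu + 1.0) / 2.0) - _digamma(nu / 2.0) - 1.0 / nu)
        - 0.5 * sum_log1p
        + (nu + 1.0) / (2.0 * nu) * sum_frac
    )
    grad[i_lnu] = nu * dlogt_dnu + (nu_shape - 1.0) - nu_rate * nu + 1.0
    return logp
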