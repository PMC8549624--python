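"""Robust Bayesian binomial GLMM: exact densities and reparameterization.

The observation model for unit i with N_i individuals at start and y_i
survivors at 48 h is

    y_i ~ Binomial(N_i, p_i),
    logit(p_i) = x_i' β + CPF_i · b_pop(i) + CPF_i · b_clone(i),

where x_i holds the intercept, the three ±0.5-coded main effects (CPF,
URB, T), the three two-way products and the triple product; b_pop ~
Normal(0, σ_pop) and b_clone ~ StudentT(ν, 0, σ_clone). Both random
effects are multiplied by the signed pesticide code, so a clone's effect
raises survival in one treatment arm and lowers it in the other by equal
logit amounts; an optional 0/1-indicator reading is available but off by
default. Weakly informative priors: β_j ~ StudentT(3, 0, 5), σ ~
half-StudentT(3, 0, 5), ν ~ Gamma(shape 2, rate 0.1).

Gradient-based sampling works on an unconstrained vector

    q = (β, z_pop, z_clone, log σ_pop, log σ_clone, log ν),

with non-centered random effects b = σ·z (z_pop standard normal,
z_clone standard Student-t) and log-transformed positive parameters with
the corresponding Jacobian terms. :func:`make_posterior` returns the
log-density and its analytic gradient on that space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import digamma, expit, gammaln
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist

from .design import ExperimentalUnit, encode_unit
from .simulate import FIXED_EFFECT_NAMES

__all__ = [
    "ModelData",
    "ModelParameters",
    "PriorSpec",
    "UnconstrainedPosterior",
    "inverse_logit",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "make_posterior",
]


def inverse_logit(eta):
    """Numerically stable logistic function p = 1/(1+exp(−η))."""
    return expit(eta)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of every prior; swappable for sensitivity analysis.

    Defaults are the weakly informative choices of the analysis:
    StudentT(3, 0, 5) on each regression coefficient (the intercept
    included), half-StudentT(3, 0, 5) on both random-effect scales, and
    Gamma(shape 2, rate 0.1) — mean 20 — on the Student-t degrees of
    freedom. The Gamma is shape–rate; shape–scale would silently change
    the prior.
    """

    beta_df: float = 3.0
    beta_loc: float = 0.0
    beta_scale: float = 5.0
    sd_df: float = 3.0
    sd_loc: float = 0.0
    sd_scale: float = 5.0
    nu_shape: float = 2.0
    nu_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("beta_df", "beta_scale", "sd_df", "sd_scale", "nu_shape", "nu_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sd_loc != 0.0:
            raise ValueError("half-StudentT scale priors require sd_loc = 0")

    def to_dict(self) -> dict[str, float]:
        return dict(vars(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


class ModelData:
    """Vectorized view of a validated dataset, ready for the likelihood.

    Holds the n×8 design matrix, the per-unit signed pesticide code, the
    population/clone index vectors (deterministic first-appearance order)
    and the outcome vectors. ``scale_by_cpf=False`` selects the
    0/1-indicator reading of the random-effect multiplier instead of the
    ±0.5 code.
    """

    def __init__(self, units: Sequence[ExperimentalUnit], scale_by_cpf: bool = True):
        if any(u.n_surviving is None for u in units):
            raise ValueError("all units must carry outcomes to build ModelData")
        self.units = list(units)
        rows, cpf = [], []
        for u in units:
            codes = encode_unit(u)
            rows.append(codes.as_row())
            cpf.append(codes.cpf)
        self.X = np.asarray(rows, dtype=float)
        cpf = np.asarray(cpf)
        self.cpf = cpf if scale_by_cpf else (cpf > 0).astype(float)
        self.scale_by_cpf = scale_by_cpf
        self.populations = list(dict.fromkeys(u.population_id for u in units))
        self.clones = list(dict.fromkeys(u.clone_id for u in units))
        pop_idx = {p: i for i, p in enumerate(self.populations)}
        clone_idx = {c: i for i, c in enumerate(self.clones)}
        self.pop_index = np.array([pop_idx[u.population_id] for u in units])
        self.clone_index = np.array([clone_idx[u.clone_id] for u in units])
        self.N = np.array([u.n_start for u in units], dtype=float)
        self.y = np.array([u.n_surviving for u in units], dtype=float)
        # binomial coefficient: constant in the parameters, kept so the
        # likelihood matches closed forms exactly
        self.log_binom = (
            gammaln(self.N + 1) - gammaln(self.y + 1) - gammaln(self.N - self.y + 1)
        )

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_clones(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector on the constrained (natural) scale."""

    beta: np.ndarray
    b_pop: np.ndarray
    b_clone: np.ndarray
    sigma_pop: float
    sigma_clone: float
    nu: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "b_pop", np.asarray(self.b_pop, dtype=float))
        object.__setattr__(self, "b_clone", np.asarray(self.b_clone, dtype=float))
        if self.beta.shape != (len(FIXED_EFFECT_NAMES),):
            raise ValueError("beta must be an 8-vector")
        if self.sigma_pop <= 0 or self.sigma_clone <= 0 or self.nu <= 0:
            raise ValueError("sigma_pop, sigma_clone and nu must be > 0")


def linear_predictor(params: ModelParameters, data: ModelData) -> np.ndarray:
    """η_i on the logit scale for every unit.

    The random effects enter multiplied by the signed pesticide code
    (or the 0/1 indicator when ``data.scale_by_cpf`` is off).
    """
    if params.b_pop.shape != (data.n_populations,):
        raise IndexError("b_pop length does not match the number of populations")
    if params.b_clone.shape != (data.n_clones,):
        raise IndexError("b_clone length does not match the number of clones")
    return data.X @ params.beta + data.cpf * (
        params.b_pop[data.pop_index] + params.b_clone[data.clone_index]
    )


def _binom_loglik(eta: np.ndarray, data: ModelData) -> float:
    # y·η − N·log(1+e^η) is the stable log-space form of y·log p + (N−y)·log(1−p)
    return float(
        np.sum(data.log_binom + data.y * eta - data.N * np.logaddexp(0.0, eta))
    )


def log_likelihood(params: ModelParameters, data: ModelData) -> float:
    """Binomial log-likelihood, combinatorial constant included."""
    return _binom_loglik(linear_predictor(params, data), data)


def _t_logpdf(x, df, scale):
    return t_dist.logpdf(x, df, loc=0.0, scale=scale)


def log_prior(params: ModelParameters, priors: PriorSpec = PriorSpec()) -> float:
    """Joint log-density of priors and random-effect distributions.

    Covers the StudentT coefficient priors, the half-StudentT scale
    priors, the Gamma prior on ν, plus Normal(0, σ_pop) for each
    population effect and StudentT(ν, 0, σ_clone) for each clone effect.
    Returns −inf outside the support.
    """
    if params.sigma_pop <= 0 or params.sigma_clone <= 0 or params.nu <= 0:
        return -np.inf
    lp = float(
        np.sum(
            t_dist.logpdf(
                params.beta, priors.beta_df, loc=priors.beta_loc, scale=priors.beta_scale
            )
        )
    )
    # half-StudentT: t density folded onto [0, inf) → + log 2
    lp += float(
        np.log(2.0)
        + _t_logpdf(params.sigma_pop, priors.sd_df, priors.sd_scale)
        + np.log(2.0)
        + _t_logpdf(params.sigma_clone, priors.sd_df, priors.sd_scale)
    )
    lp += float(gamma_dist.logpdf(params.nu, priors.nu_shape, scale=1.0 / priors.nu_rate))
    lp += float(
        np.sum(
            -0.5 * (params.b_pop / params.sigma_pop) ** 2
            - 0.5 * np.log(2.0 * np.pi)
            - np.log(params.sigma_pop)
        )
    )
    lp += float(np.sum(_t_logpdf(params.b_clone, params.nu, params.sigma_clone)))
    return lp


def log_posterior(
    params: ModelParameters, data: ModelData, priors: PriorSpec = PriorSpec()
) -> float:
    """Unnormalized log-posterior on the constrained scale."""
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return lp
    return log_likelihood(params, data) + lp


# ---------------------------------------------------------------------------
# Unconstrained reparameterization


class UnconstrainedPosterior:
    """Log-density and analytic gradient on the unconstrained space.

    Layout of the unconstrained vector q (dimension 8 + P + C + 3):
    β (8) | z_pop (P) | z_clone (C) | log σ_pop | log σ_clone | log ν.
    Random effects are non-centered (b = σ·z) and the positive parameters
    are log-transformed with their Jacobian terms included, so the density
    is the correct pushforward of the constrained posterior.
    """

    def __init__(self, data: ModelData, priors: PriorSpec = PriorSpec()):
        self.data = data
        self.priors = priors
        self.n_beta = len(FIXED_EFFECT_NAMES)
        self.n_pop = data.n_populations
        self.n_clone = data.n_clones
        self.n_dim = self.n_beta + self.n_pop + self.n_clone + 3
        self._sl_beta = slice(0, self.n_beta)
        self._sl_pop = slice(self.n_beta, self.n_beta + self.n_pop)
        self._sl_clone = slice(self.n_beta + self.n_pop, self.n_beta + self.n_pop + self.n_clone)
        self._Xt = np.ascontiguousarray(data.X.T)

    # -- packing -----------------------------------------------------------
    def transform(self, params: ModelParameters) -> np.ndarray:
        """Constrained parameters → unconstrained vector."""
        q = np.empty(self.n_dim)
        q[self._sl_beta] = params.beta
        q[self._sl_pop] = params.b_pop / params.sigma_pop
        q[self._sl_clone] = params.b_clone / params.sigma_clone
        q[-3] = np.log(params.sigma_pop)
        q[-2] = np.log(params.sigma_clone)
        q[-1] = np.log(params.nu)
        return q

    def untransform(self, q: np.ndarray) -> ModelParameters:
        """Unconstrained vector → constrained parameters."""
        q = np.asarray(q, dtype=float)
        sigma_pop, sigma_clone, nu = np.exp(q[-3]), np.exp(q[-2]), np.exp(q[-1])
        return ModelParameters(
            beta=q[self._sl_beta].copy(),
            b_pop=sigma_pop * q[self._sl_pop],
            b_clone=sigma_clone * q[self._sl_clone],
            sigma_pop=float(sigma_pop),
            sigma_clone=float(sigma_clone),
            nu=float(nu),
        )

    # -- density -----------------------------------------------------------
    def logp_and_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-density (up to a constant) and its gradient at q."""
        if not np.all(np.isfinite(q)):
            raise ValueError("non-finite unconstrained parameter vector")
        data, priors = self.data, self.priors
        beta = q[self._sl_beta]
        z_pop = q[self._sl_pop]
        z_clone = q[self._sl_clone]
        ls_pop, ls_clone, l_nu = q[-3], q[-2], q[-1]
        s_pop, s_clone, nu = np.exp(ls_pop), np.exp(ls_clone), np.exp(l_nu)

        eta = data.X @ beta + data.cpf * (
            s_pop * z_pop[data.pop_index] + s_clone * z_clone[data.clone_index]
        )
        p = expit(eta)
        logp = float(np.sum(data.log_binom + data.y * eta - data.N * np.logaddexp(0.0, eta)))
        r = data.y - data.N * p  # d loglik / d eta

        grad = np.empty_like(q)

        # fixed effects: likelihood score + StudentT(df,0,s) prior score
        bdf, bs = priors.beta_df, priors.beta_scale
        bc = beta - priors.beta_loc
        logp += float(
            np.sum(
                gammaln((bdf + 1) / 2)
                - gammaln(bdf / 2)
                - 0.5 * np.log(bdf * np.pi * bs**2)
                - (bdf + 1) / 2 * np.log1p(bc**2 / (bdf * bs**2))
            )
        )
        grad[self._sl_beta] = self._Xt @ r - (bdf + 1) * bc / (bdf * bs**2 + bc**2)

        # population effects: standard normal on z_pop
        cr = data.cpf * r
        pop_score = np.bincount(data.pop_index, weights=cr, minlength=self.n_pop)
        logp += float(np.sum(-0.5 * z_pop**2 - 0.5 * np.log(2 * np.pi)))
        grad[self._sl_pop] = s_pop * pop_score - z_pop

        # clone effects: standard StudentT(nu) on z_clone
        clone_score = np.bincount(data.clone_index, weights=cr, minlength=self.n_clone)
        z2 = z_clone**2
        log1p_term = np.log1p(z2 / nu)
        logp += float(
            self.n_clone
            * (gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi))
            - (nu + 1) / 2 * np.sum(log1p_term)
        )
        grad[self._sl_clone] = s_clone * clone_score - (nu + 1) * z_clone / (nu + z2)

        # scale parameters: half-StudentT(df,0,s) prior + log Jacobian
        sdf, ss = priors.sd_df, priors.sd_scale
        half_t_const = (
            np.log(2.0)
            + gammaln((sdf + 1) / 2)
            - gammaln(sdf / 2)
            - 0.5 * np.log(sdf * np.pi * ss**2)
        )
        for pos, sigma, z, score in (
            (-3, s_pop, z_pop, pop_score),
            (-2, s_clone, z_clone, clone_score),
        ):
            logp += float(
                half_t_const
                - (sdf + 1) / 2 * np.log1p(sigma**2 / (sdf * ss**2))
                + np.log(sigma)  # Jacobian of sigma = exp(ls)
            )
            grad[pos] = (
                sigma * float(z @ score)
                - (sdf + 1) * sigma**2 / (sdf * ss**2 + sigma**2)
                + 1.0
            )

        # degrees of freedom: Gamma(shape, rate) prior + z_clone density + Jacobian
        a, b = priors.nu_shape, priors.nu_rate
        logp += float(a * np.log(b) - gammaln(a) + (a - 1) * l_nu - b * nu + l_nu)
        dlogt_dnu = (
            0.5 * self.n_clone * (digamma((nu + 1) / 2) - digamma(nu / 2) - 1.0 / nu)
            - 0.5 * np.sum(log1p_term)
            + (nu + 1) / (2 * nu) * np.sum(z2 / (nu + z2))
        )
        grad[-1] = nu * (dlogt_dnu + (a - 1) / nu - b) + 1.0
        return logp, grad

    def logp(self, q: np.ndarray) -> float:
        return self.logp_and_grad(q)[0]

    def fast_logp_and_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        """Compiled-kernel evaluation; identical to :meth:`logp_and_grad`.

        Falls back to the numpy reference path when numba is missing.
        The two paths are cross-checked against each other in the test
        suite.
        """
        from ._kernels import HAVE_NUMBA, _logp_grad_kernel

        if not HAVE_NUMBA:  # pragma: no cover - numba is installed normally
            return self.logp_and_grad(q)
        if not np.all(np.isfinite(q)):
            raise ValueError("non-finite unconstrained parameter vector")
        data, priors = self.data, self.priors
        if not hasattr(self, "_log_binom_sum"):
            self._log_binom_sum = float(np.sum(data.log_binom))
            self._pop_idx64 = data.pop_index.astype(np.int64)
            self._clone_idx64 = data.clone_index.astype(np.int64)
        grad = np.empty(self.n_dim)
        logp = _logp_grad_kernel(
            np.asarray(q, dtype=float),
            data.X,
            data.cpf,
            self._pop_idx64,
            self._clone_idx64,
            data.N,
            data.y,
            self._log_binom_sum,
            self.n_pop,
            self.n_clone,
            priors.beta_df,
            priors.beta_loc,
            priors.beta_scale,
            priors.sd_df,
            priors.sd_scale,
            priors.nu_shape,
            priors.nu_rate,
            grad,
        )
        return float(logp), grad


def make_posterior(
    data: ModelData, priors: PriorSpec = PriorSpec()
) -> UnconstrainedPosterior:
    """Build the unconstrained posterior for a validated dataset."""
    return UnconstrainedPosterior(data, priors)


def intercept_only_logp_and_grad(y: int, n: int, priors: PriorSpec = PriorSpec()):
    """1-D reduced model: intercept-only binomial-logit with the β prior.

    Posterior density of β0 given a single unit with ``y`` of ``n``
    survivors, no random effects. Used to validate the sampler against
    low-dimensional quadrature.
    """
    df, loc, scale = priors.beta_df, priors.beta_loc, priors.beta_scale
    const = float(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1))

    def logp_and_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        b = float(q[0])
        c = b - loc
        logp = (
            const
            + y * b
            - n * np.logaddexp(0.0, b)
            + float(t_dist.logpdf(b, df, loc=loc, scale=scale))
        )
        grad = np.array([y - n * expit(b) - (df + 1) * c / (df * scale**2 + c**2)])
        return logp, grad

    return logp_and_grad
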