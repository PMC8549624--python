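"""Dynamic Hamiltonian Monte Carlo (NUTS) posterior sampling.

Implements the sampling scheme of the analysis: a gradient-based dynamic
HMC sampler with multinomial state selection along the trajectory, a
no-U-turn termination criterion, dual-averaging step-size adaptation and
windowed diagonal mass-matrix (metric) adaptation during warmup. Warmup
draws are discarded; adaptation never runs after warmup. Divergent
transitions (energy error > 1000 along a trajectory) are flagged per
retained draw.

Default settings follow the analysis: 4 chains × 10,000 iterations of
which the first 5,000 are warmup, leaving 20,000 retained posterior
draws. Chain c uses an independent, individually reproducible substream
derived from (seed, c).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import ModelData, PriorSpec, make_posterior

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "InitializationError",
    "initialize",
    "sample_nuts",
    "sample_posterior",
]

_DIVERGENCE_THRESHOLD = 1000.0  # energy error treated as a divergence
_LOG_EPS = -1e300


class InitializationError(RuntimeError):
    """No finite-density initial point found within the retry budget."""


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler settings; defaults reproduce the reported scheme."""

    n_chains: int = 4
    n_iterations: int = 10_000
    n_warmup: int = 5_000
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10
    init_strategy: str = "random"

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iterations:
            raise ValueError("n_warmup must be smaller than n_iterations")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if not (0 < self.target_accept < 1):
            raise ValueError("target_accept must lie in (0, 1)")

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_warmup

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class PosteriorDraws:
    """Retained draws indexed by (chain, iteration, parameter name).

    ``values`` has shape (n_chains, n_retained, n_params) on the
    constrained scale; ``divergent`` flags per retained draw are ``None``
    when the generating algorithm defines no divergence notion (e.g.
    draws restored from a source without flags).
    """

    names: list[str]
    values: np.ndarray
    divergent: np.ndarray | None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != len(self.names):
            raise ValueError("values must have shape (chains, draws, params)")
        if np.any(np.char.startswith(np.array(self.names), "sigma")) or "nu" in self.names:
            for name in ("sigma_pop", "sigma_clone", "nu"):
                if name in self.names and np.any(self.get(name) <= 0):
                    raise ValueError(f"{name} draws must be strictly positive")

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_draws)."""
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.values[:, :, j]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-draw export (one row per chain × iteration)."""
        n_c, n_d, _ = self.values.shape
        df = pd.DataFrame(
            self.values.reshape(n_c * n_d, -1), columns=self.names
        )
        df.insert(0, "chain", np.repeat(np.arange(n_c), n_d))
        df.insert(1, "draw", np.tile(np.arange(n_d), n_c))
        df.insert(
            2,
            "divergent",
            self.divergent.reshape(-1) if self.divergent is not None else False,
        )
        return df

    def to_inference_data(self):
        """arviz InferenceData view (posterior + sample_stats)."""
        import arviz as az

        posterior = {
            name: self.values[:, :, j] for j, name in enumerate(self.names)
        }
        sample_stats = None
        if self.divergent is not None:
            sample_stats = {"diverging": self.divergent}
        return az.from_dict(posterior=posterior, sample_stats=sample_stats)

    def save(self, path: str | Path) -> None:
        """Persist losslessly as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        meta = {
            "names": self.names,
            "n_chains": int(self.n_chains),
            "n_draws": int(self.n_draws),
            "has_divergent": self.divergent is not None,
            "config": self.config,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorDraws":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text(encoding="utf-8")
        )
        df = pd.read_csv(path, float_precision="round_trip")
        n_c, n_d = meta["n_chains"], meta["n_draws"]
        values = df[meta["names"]].to_numpy().reshape(n_c, n_d, -1)
        divergent = (
            df["divergent"].to_numpy().astype(bool).reshape(n_c, n_d)
            if meta["has_divergent"]
            else None
        )
        return cls(
            names=list(meta["names"]),
            values=values,
            divergent=divergent,
            config=meta.get("config", {}),
        )


def initialize(
    strategy: str,
    seed_or_rng: int | np.random.Generator,
    n_dim: int,
    n_random_effects: slice | None = None,
) -> np.ndarray:
    """Initial unconstrained vector.

    ``random`` draws every coordinate uniformly in [−2, 2]; ``zero``
    additionally pins the random-effect coordinates at 0.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if strategy not in ("random", "zero"):
        raise ValueError(f"unknown initialization strategy {strategy!r}")
    q = rng.uniform(-2.0, 2.0, size=n_dim)
    if strategy == "zero" and n_random_effects is not None:
        q[n_random_effects] = 0.0
    return q


# ---------------------------------------------------------------------------
# NUTS internals


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "logp_prop", "g_prop", "log_w", "sum_accept", "n_leapfrog",
        "divergent", "turning",
    )


def _leapfrog(q, p, grad, eps, inv_mass, logp_and_grad):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_and_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, grad, logp


def _no_uturn(q_plus, q_minus, p_plus, p_minus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (dq @ (inv_mass * p_minus)) > 0 and (dq @ (inv_mass * p_plus)) > 0


def _build_tree(depth, q, p, grad, direction, eps, inv_mass, H0, logp_and_grad, rng):
    t = _Tree()
    if depth == 0:
        try:
            q1, p1, g1, logp1 = _leapfrog(
                q, p, grad, direction * eps, inv_mass, logp_and_grad
            )
            H1 = -logp1 + 0.5 * float((inv_mass * p1) @ p1)
        except (FloatingPointError, OverflowError, ValueError):
            H1, logp1 = np.inf, -np.inf
            q1, p1, g1 = q, p, grad
        energy_error = H1 - H0
        t.q_minus = t.q_plus = t.q_prop = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.logp_prop = logp1
        t.log_w = -energy_error if np.isfinite(energy_error) else _LOG_EPS
        t.sum_accept = min(1.0, math.exp(min(0.0, -energy_error)))
        t.n_leapfrog = 1
        t.divergent = not np.isfinite(energy_error) or energy_error > _DIVERGENCE_THRESHOLD
        t.turning = False
        return t

    first = _build_tree(
        depth - 1, q, p, grad, direction, eps, inv_mass, H0, logp_and_grad, rng
    )
    if first.divergent or first.turning:
        return first
    if direction > 0:
        q_edge, p_edge, g_edge = first.q_plus, first.p_plus, first.g_plus
    else:
        q_edge, p_edge, g_edge = first.q_minus, first.p_minus, first.g_minus
    second = _build_tree(
        depth - 1, q_edge, p_edge, g_edge, direction, eps, inv_mass, H0, logp_and_grad, rng
    )
    t.sum_accept = first.sum_accept + second.sum_accept
    t.n_leapfrog = first.n_leapfrog + second.n_leapfrog
    t.divergent = second.divergent
    if direction > 0:
        t.q_minus, t.p_minus, t.g_minus = first.q_minus, first.p_minus, first.g_minus
        t.q_plus, t.p_plus, t.g_plus = second.q_plus, second.p_plus, second.g_plus
    else:
        t.q_minus, t.p_minus, t.g_minus = second.q_minus, second.p_minus, second.g_minus
        t.q_plus, t.p_plus, t.g_plus = first.q_plus, first.p_plus, first.g_plus
    t.log_w = np.logaddexp(first.log_w, second.log_w)
    # multinomial sampling within the subtree
    if math.log(rng.uniform()) < second.log_w - t.log_w:
        t.q_prop, t.logp_prop, t.g_prop = second.q_prop, second.logp_prop, second.g_prop
    else:
        t.q_prop, t.logp_prop, t.g_prop = first.q_prop, first.logp_prop, first.g_prop
    t.turning = second.turning or not _no_uturn(
        t.q_plus, t.q_minus, t.p_plus, t.p_minus, inv_mass
    )
    return t


def _nuts_transition(q, logp, grad, eps, inv_mass, max_treedepth, logp_and_grad, rng):
    p0 = rng.standard_normal(q.shape[0]) / np.sqrt(inv_mass)
    H0 = -logp + 0.5 * float((inv_mass * p0) @ p0)
    q_minus = q_plus = q
    p_minus = p_plus = p0
    g_minus = g_plus = grad
    q_sample, logp_sample, g_sample = q, logp, grad
    log_w_total = 0.0
    sum_accept, n_leapfrog = 0.0, 0
    divergent = False
    for depth in range(max_treedepth):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction > 0:
            tree = _build_tree(
                depth, q_plus, p_plus, g_plus, 1, eps, inv_mass, H0,
                logp_and_grad, rng,
            )
        else:
            tree = _build_tree(
                depth, q_minus, p_minus, g_minus, -1, eps, inv_mass, H0,
                logp_and_grad, rng,
            )
        sum_accept += tree.sum_accept
        n_leapfrog += tree.n_leapfrog
        if tree.divergent:
            divergent = True
            break
        if tree.turning:
            break
        # biased progressive sampling: favor the fresh subtree
        if math.log(rng.uniform()) < tree.log_w - log_w_total:
            q_sample, logp_sample, g_sample = tree.q_prop, tree.logp_prop, tree.g_prop
        log_w_total = np.logaddexp(log_w_total, tree.log_w)
        if direction > 0:
            q_plus, p_plus, g_plus = tree.q_plus, tree.p_plus, tree.g_plus
        else:
            q_minus, p_minus, g_minus = tree.q_minus, tree.p_minus, tree.g_minus
        if not _no_uturn(q_plus, q_minus, p_plus, p_minus, inv_mass):
            break
    accept_stat = sum_accept / max(n_leapfrog, 1)
    return q_sample, logp_sample, g_sample, divergent, accept_stat


def _find_reasonable_epsilon(q, logp, grad, inv_mass, logp_and_grad, rng):
    eps = 1.0
    p0 = rng.standard_normal(q.shape[0]) / np.sqrt(inv_mass)
    H0 = -logp + 0.5 * float((inv_mass * p0) @ p0)

    def accept_logprob(eps):
        try:
            _, p1, _, logp1 = _leapfrog(q, p0, grad, eps, inv_mass, logp_and_grad)
            H1 = -logp1 + 0.5 * float((inv_mass * p1) @ p1)
            return H0 - H1 if np.isfinite(H1) else -np.inf
        except (FloatingPointError, OverflowError, ValueError):
            return -np.inf

    direction = 1.0 if accept_logprob(eps) > math.log(0.5) else -1.0
    for _ in range(50):
        eps_try = eps * (2.0 if direction > 0 else 0.5)
        if direction > 0 and accept_logprob(eps_try) <= math.log(0.5):
            break
        if direction < 0 and accept_logprob(eps_try) > math.log(0.5):
            eps = eps_try
            break
        eps = eps_try
    return eps


def _adaptation_windows(n_warmup: int) -> list[tuple[int, int]]:
    """Metric-estimation windows (start, end) within warmup, Stan-style."""
    if n_warmup < 60:
        return []
    init_buffer = max(15, int(0.15 * n_warmup)) if n_warmup < 500 else 75
    term_buffer = max(10, int(0.10 * n_warmup)) if n_warmup < 500 else 50
    base = 25
    windows = []
    start = init_buffer
    size = base
    while start + size < n_warmup - term_buffer:
        if start + 3 * size >= n_warmup - term_buffer:
            size = n_warmup - term_buffer - start
        windows.append((start, start + size))
        start += size
        size *= 2
    if not windows and n_warmup - term_buffer > init_buffer:
        windows.append((init_buffer, n_warmup - term_buffer))
    return windows


def _run_chain(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    n_dim: int,
    config: SamplerConfig,
    rng: np.random.Generator,
    init_slice: slice | None,
) -> tuple[np.ndarray, np.ndarray]:
    # initialization with bounded retries
    q = None
    for _ in range(100):
        cand = initialize(config.init_strategy, rng, n_dim, init_slice)
        try:
            logp, grad = logp_and_grad(cand)
        except ValueError:
            continue
        if np.isfinite(logp) and np.all(np.isfinite(grad)):
            q = cand
            break
    if q is None:
        raise InitializationError(
            "no finite log-posterior initialization found in 100 attempts"
        )

    inv_mass = np.ones(n_dim)
    eps = _find_reasonable_epsilon(q, logp, grad, inv_mass, logp_and_grad, rng)

    # dual averaging state
    gamma_da, t0, kappa = 0.05, 10.0, 0.75
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0

    windows = _adaptation_windows(config.n_warmup)
    welford_n = 0
    welford_mean = np.zeros(n_dim)
    welford_m2 = np.zeros(n_dim)
    window_idx = 0

    draws = np.empty((config.n_retained, n_dim))
    divergent = np.zeros(config.n_retained, dtype=bool)

    for it in range(config.n_iterations):
        q, logp, grad, div, accept_stat = _nuts_transition(
            q, logp, grad, eps, inv_mass, config.max_treedepth, logp_and_grad, rng
        )
        if it < config.n_warmup:
            m_adapt += 1
            h_bar = (1 - 1 / (m_adapt + t0)) * h_bar + (
                config.target_accept - accept_stat
            ) / (m_adapt + t0)
            log_eps = mu - math.sqrt(m_adapt) / gamma_da * h_bar
            eta = m_adapt ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            if window_idx < len(windows):
                w_start, w_end = windows[window_idx]
                if w_start <= it < w_end:
                    welford_n += 1
                    delta = q - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (q - welford_mean)
                if it == w_end - 1:
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        inv_mass = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                            5.0 / (welford_n + 5.0)
                        )
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    window_idx += 1
                    # restart step-size adaptation on the new metric
                    eps = _find_reasonable_epsilon(
                        q, logp, grad, inv_mass, logp_and_grad, rng
                    )
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
            if it == config.n_warmup - 1:
                eps = math.exp(log_eps_bar) if m_adapt > 0 else eps
        else:
            j = it - config.n_warmup
            draws[j] = q
            divergent[j] = div
    return draws, divergent


def sample_nuts(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    n_dim: int,
    config: SamplerConfig,
    param_names: Sequence[str] | None = None,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
    init_slice: slice | None = None,
) -> PosteriorDraws:
    """Run NUTS chains on an arbitrary differentiable log-density.

    ``transform`` optionally maps each unconstrained draw to the reported
    (constrained) parameter vector; ``param_names`` labels its output.
    """
    names = (
        list(param_names)
        if param_names is not None
        else [f"q[{i}]" for i in range(n_dim)]
    )
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, all_div = [], []
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        draws, divergent = _run_chain(logp_and_grad, n_dim, config, rng, init_slice)
        if transform is not None:
            draws = np.apply_along_axis(transform, 1, draws)
        all_draws.append(draws)
        all_div.append(divergent)
    return PosteriorDraws(
        names=names,
        values=np.stack(all_draws),
        divergent=np.stack(all_div),
        config=config.to_dict(),
    )


def sample_posterior(
    data: ModelData,
    priors: PriorSpec = PriorSpec(),
    config: SamplerConfig = SamplerConfig(),
) -> PosteriorDraws:
    """Sample the robust binomial GLMM posterior for a dataset.

    Draws target the unconstrained reparameterized posterior and are
    reported back-transformed to the constrained scale with parameter
    names ``beta[...]``, ``b_pop[...]``, ``b_clone[...]``, ``sigma_pop``,
    ``sigma_clone`` and ``nu``.
    """
    post = make_posterior(data, priors)
    from .simulate import FIXED_EFFECT_NAMES

    names = (
        [f"beta[{n}]" for n in FIXED_EFFECT_NAMES]
        + [f"b_pop[{p}]" for p in data.populations]
        + [f"b_clone[{c}]" for c in data.clones]
        + ["sigma_pop", "sigma_clone", "nu"]
    )

    def to_constrained(q: np.ndarray) -> np.ndarray:
        params = post.untransform(q)
        return np.concatenate(
            [
                params.beta,
                params.b_pop,
                params.b_clone,
                [params.sigma_pop, params.sigma_clone, params.nu],
            ]
        )

    re_slice = slice(post.n_beta, post.n_beta + post.n_pop + post.n_clone)
    return sample_nuts(
        post.fast_logp_and_grad,
        post.n_dim,
        config,
        param_names=names,
        transform=to_constrained,
        init_slice=re_slice,
    )
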