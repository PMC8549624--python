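"""Convergence assessment and posterior predictive checking.

R-hat is the rank-normalized split potential scale reduction factor and
ESS the rank-normalized bulk effective sample size (the formulation of
Vehtari et al. that the convergence criterion R-hat < 1.01 refers to);
both are delegated to arviz. A parameter whose draws are constant across
all chains raises a labelled error instead of silently reporting 1.0.

Posterior predictive checks resimulate the binomial outcomes under
retained posterior draws (each draw's own fixed and random effects) and
compare observed vs. replicated discrepancy statistics: the per-arm
(control vs. chlorpyrifos) mean and variance of the unit-level survival
fractions, reported as tail probabilities Pr(T(y_rep) >= T(y_obs)).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from .model import ModelData
from .sampler import PosteriorDraws

__all__ = [
    "DegenerateParameterError",
    "split_rhat",
    "effective_sample_size",
    "divergence_count",
    "NOT_APPLICABLE",
    "PPCResult",
    "posterior_predictive",
    "convergence_report",
]

NOT_APPLICABLE = "not applicable"

RHAT_THRESHOLD = 1.01


class DegenerateParameterError(ValueError):
    """Raised when a parameter has zero variance across all draws."""


def _chains(draws: PosteriorDraws | np.ndarray, parameter: str | None) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required")
        x = draws.get(parameter)
    else:
        x = np.asarray(draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected draws with shape (chains, iterations)")
    if x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains and >= 4 draws per chain")
    if np.ptp(x) == 0:
        raise DegenerateParameterError(
            f"parameter {parameter or ''!r} has zero variance across all draws"
        )
    return x


def split_rhat(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Rank-normalized split R-hat for one parameter."""
    x = _chains(draws, parameter)
    return float(az.rhat(az.convert_to_dataset(x[None] if x.ndim == 1 else x), method="rank")["x"])


def effective_sample_size(
    draws: PosteriorDraws | np.ndarray, parameter: str | None = None
) -> float:
    """Rank-normalized bulk effective sample size for one parameter."""
    x = _chains(draws, parameter)
    return float(az.ess(az.convert_to_dataset(x), method="bulk")["x"])


def divergence_count(draws: PosteriorDraws) -> tuple[int, ...] | str:
    """Divergent-transition count per chain.

    Returns the string ``"not applicable"`` when the draws carry no
    divergence flags (an algorithm without that notion), never a silent 0.
    """
    if draws.divergent is None:
        return NOT_APPLICABLE
    return tuple(int(c) for c in draws.divergent.sum(axis=1))


def convergence_report(
    draws: PosteriorDraws, parameters: list[str] | None = None
) -> pd.DataFrame:
    """Per-parameter R-hat and bulk ESS table with a pass flag.

    Parameters that are degenerate (zero variance) are reported with NaN
    diagnostics and ``passed=False`` rather than aborting the report.
    """
    names = parameters if parameters is not None else draws.names
    rows = []
    for name in names:
        try:
            r = split_rhat(draws, name)
            e = effective_sample_size(draws, name)
            rows.append({"parameter": name, "rhat": r, "ess_bulk": e,
                         "passed": bool(r < RHAT_THRESHOLD)})
        except DegenerateParameterError:
            rows.append({"parameter": name, "rhat": np.nan, "ess_bulk": np.nan,
                         "passed": False})
    return pd.DataFrame(rows)


@dataclass
class PPCResult:
    """Replicated outcomes and discrepancy summary of one check."""

    replicated: np.ndarray  # (n_replicates, n_units) survivor counts
    observed: np.ndarray  # (n_units,) survivor counts
    summary: pd.DataFrame  # per-statistic observed value and tail probability
    count_table: pd.DataFrame  # distribution of per-unit survivor counts


def _arm_stats(y: np.ndarray, n: np.ndarray, cpf_mask: np.ndarray) -> dict[str, float]:
    frac = y / n
    return {
        "mean_survival[control]": float(frac[~cpf_mask].mean()),
        "mean_survival[chlorpyrifos]": float(frac[cpf_mask].mean()),
        "var_survival[control]": float(frac[~cpf_mask].var()),
        "var_survival[chlorpyrifos]": float(frac[cpf_mask].var()),
    }


def posterior_predictive(
    draws: PosteriorDraws,
    data: ModelData,
    n_replicates: int = 500,
    seed: int = 0,
) -> PPCResult:
    """Simulate replicated datasets under thinned posterior draws.

    Each replicate uses one retained draw's full parameter vector
    (fixed effects plus that draw's population and clone effects) to
    resimulate y ~ Binomial(N, p) for every unit of the fitted design.
    """
    total = draws.n_chains * draws.n_draws
    if n_replicates > total:
        raise ValueError(
            f"n_replicates={n_replicates} exceeds the {total} retained draws"
        )
    cpf_mask = data.cpf > 0 if data.scale_by_cpf else data.cpf == 1.0
    obs = data.y.astype(int)
    obs_stats = _arm_stats(data.y, data.N, cpf_mask)

    if n_replicates == 0:
        empty = pd.DataFrame(columns=["statistic", "observed", "tail_probability"])
        counts = pd.DataFrame(columns=["survivors", "observed", "replicated_mean"])
        return PPCResult(
            replicated=np.zeros((0, data.n_units), dtype=int),
            observed=obs, summary=empty, count_table=counts,
        )

    rng = np.random.default_rng(seed)
    idx = np.linspace(0, total - 1, n_replicates).astype(int)  # even thinning
    flat = draws.values.reshape(total, -1)
    name_pos = {n: j for j, n in enumerate(draws.names)}
    beta_cols = [name_pos[n] for n in draws.names if n.startswith("beta[")]
    pop_cols = [name_pos[f"b_pop[{p}]"] for p in data.populations]
    clone_cols = [name_pos[f"b_clone[{c}]"] for c in data.clones]

    rep = np.empty((n_replicates, data.n_units), dtype=int)
    rep_stats = {k: np.empty(n_replicates) for k in obs_stats}
    for r, i in enumerate(idx):
        row = flat[i]
        eta = data.X @ row[beta_cols] + data.cpf * (
            row[pop_cols][data.pop_index] + row[clone_cols][data.clone_index]
        )
        y_rep = rng.binomial(data.N.astype(int), expit(eta))
        rep[r] = y_rep
        for k, v in _arm_stats(y_rep, data.N, cpf_mask).items():
            rep_stats[k][r] = v

    summary = pd.DataFrame(
        {
            "statistic": list(obs_stats),
            "observed": [obs_stats[k] for k in obs_stats],
            "tail_probability": [
                float(np.mean(rep_stats[k] >= obs_stats[k])) for k in obs_stats
            ],
        }
    )
    max_n = int(data.N.max())
    counts = pd.DataFrame(
        {
            "survivors": np.arange(max_n + 1),
            "observed": [int(np.sum(obs == k)) for k in range(max_n + 1)],
            "replicated_mean": [
                float(np.mean(np.sum(rep == k, axis=1))) for k in range(max_n + 1)
            ],
        }
    )
    return PPCResult(replicated=rep, observed=obs, summary=summary, count_table=counts)
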