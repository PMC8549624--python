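"""End-to-end orchestration: simulate → fit → diagnose → summarize → PPC
→ prior sensitivity, with reproducible configuration and a run manifest.

A single YAML/JSON config document with sections mirroring the library
modules (design, truth, priors, sampler, summaries, ppc, sensitivity)
drives the full analysis; defaults reproduce the reported analysis
settings (4 chains × 10,000 iterations, 5,000 warmup, the weakly
informative priors, the 392-unit design). Every random draw is traceable
to the single top-level seed recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignSpec, ExperimentalUnit, read_dataset, write_dataset
from .diagnostics import (
    RHAT_THRESHOLD,
    convergence_report,
    divergence_count,
    posterior_predictive,
)
from .model import ModelData, PriorSpec
from .sampler import PosteriorDraws, SamplerConfig, sample_posterior
from .simulate import SimulationTruth, make_truth_preset, simulate_dataset
from .summaries import (
    marginal_effect_pp,
    marginal_survival,
    prior_sensitivity,
    sample_fixed_effect_names,
    summarize_parameters,
)

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "recovery_experiment",
]

log = logging.getLogger("daphtox")


class ConfigError(ValueError):
    """Configuration schema violation; message names the field path."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring)."""

    seed: int = 0
    design: DesignSpec = field(default_factory=DesignSpec.study)
    truth: SimulationTruth | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    summary_levels: tuple[float, float] = (0.8, 0.95)
    ppc_replicates: int = 500
    sensitivity_beta_scales: tuple[float, ...] = ()
    rhat_threshold: float = RHAT_THRESHOLD
    fail_on_rhat: bool = True

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "PipelineConfig":
        doc = dict(doc or {})
        seed = int(doc.pop("seed", 0))

        design_doc = dict(doc.pop("design", {}))
        try:
            if not design_doc:
                design = DesignSpec.study()
            else:
                n_oversized = design_doc.pop("n_oversized", None)
                if n_oversized is not None:
                    design_doc["oversized_units"] = tuple(range(int(n_oversized)))
                for key in ("excluded_clones", "oversized_units"):
                    if key in design_doc:
                        design_doc[key] = tuple(design_doc[key])
                design = DesignSpec(**design_doc)
        except TypeError as exc:
            raise ConfigError(f"design: {exc}") from exc

        truth_doc = doc.pop("truth", None)
        truth = None
        if truth_doc is not None:
            truth_doc = dict(truth_doc)
            preset = truth_doc.pop("preset", None)
            try:
                if preset is not None:
                    if truth_doc:
                        raise ConfigError(
                            "truth: give either 'preset' or explicit values, not both"
                        )
                    truth = make_truth_preset(preset, seed=seed)
                else:
                    truth_doc.setdefault("seed", seed)
                    truth_doc["beta"] = tuple(truth_doc["beta"])
                    truth = SimulationTruth(**truth_doc)
            except (TypeError, KeyError, ValueError) as exc:
                if isinstance(exc, ConfigError):
                    raise
                raise ConfigError(f"truth: {exc}") from exc

        try:
            priors = PriorSpec(**doc.pop("priors", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"priors: {exc}") from exc

        sampler_doc = dict(doc.pop("sampler", {}))
        sampler_doc.setdefault("seed", seed)
        if sampler_doc.get("n_warmup", SamplerConfig.n_warmup) >= sampler_doc.get(
            "n_iterations", SamplerConfig.n_iterations
        ):
            raise ConfigError(
                "sampler.n_warmup must be smaller than sampler.n_iterations"
            )
        try:
            sampler = SamplerConfig(**sampler_doc)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"sampler: {exc}") from exc

        summaries_doc = dict(doc.pop("summaries", {}))
        levels = tuple(summaries_doc.pop("levels", (0.8, 0.95)))
        if len(levels) != 2 or not all(0 < l < 1 for l in levels):
            raise ConfigError("summaries.levels must be two values in (0, 1)")
        ppc_doc = dict(doc.pop("ppc", {}))
        ppc_replicates = int(ppc_doc.pop("n_replicates", 500))
        sens_doc = dict(doc.pop("sensitivity", {}))
        beta_scales = tuple(float(s) for s in sens_doc.pop("beta_scales", ()))
        rhat_threshold = float(doc.pop("rhat_threshold", RHAT_THRESHOLD))
        fail_on_rhat = bool(doc.pop("fail_on_rhat", True))
        if doc:
            raise ConfigError(f"unknown top-level config key(s): {sorted(doc)}")
        return cls(
            seed=seed,
            design=design,
            truth=truth,
            priors=priors,
            sampler=sampler,
            summary_levels=levels,  # type: ignore[arg-type]
            ppc_replicates=ppc_replicates,
            sensitivity_beta_scales=beta_scales,
            rhat_threshold=rhat_threshold,
            fail_on_rhat=fail_on_rhat,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(doc or {})

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "design": {
                "n_populations_per_class": self.design.n_populations_per_class,
                "n_clones_per_population": self.design.n_clones_per_population,
                "n_replicates": self.design.n_replicates,
                "excluded_clones": list(self.design.excluded_clones),
                "oversized_units": list(self.design.oversized_units),
            },
            "truth": None
            if self.truth is None
            else {
                "beta": list(self.truth.beta),
                "sigma_pop": self.truth.sigma_pop,
                "sigma_clone": self.truth.sigma_clone,
                "nu": self.truth.nu,
                "seed": self.truth.seed,
            },
            "priors": self.priors.to_dict(),
            "sampler": self.sampler.to_dict(),
            "summary_levels": list(self.summary_levels),
            "ppc_replicates": self.ppc_replicates,
            "sensitivity_beta_scales": list(self.sensitivity_beta_scales),
            "rhat_threshold": self.rhat_threshold,
            "fail_on_rhat": self.fail_on_rhat,
        }


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    draws: PosteriorDraws | None = None
    rhat_ok: bool | None = None


_MARGINAL_CONDITIONS: dict[str, dict[str, float]] = {
    "control": {"cpf": -0.5},
    "chlorpyrifos": {"cpf": +0.5},
    "chlorpyrifos_urban": {"cpf": +0.5, "urb": +0.5},
    "chlorpyrifos_rural": {"cpf": +0.5, "urb": -0.5},
}


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    data: Sequence[ExperimentalUnit] | str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    ``data`` may be a dataset path or in-memory units; when absent, a
    synthetic dataset is generated from ``config.truth`` (required then).
    Raises :class:`RuntimeError` at the end if any reported parameter has
    R-hat at or above the threshold and ``fail_on_rhat`` is set; all
    artifacts are still written first.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": config.canonical(),
        "config_hash": hashlib.sha256(
            json.dumps(config.canonical(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": [],
        "outputs": [],
        "timestamps": {"started": time.time()},
    }

    def stage(name: str) -> None:
        log.info("stage=%s seed=%s", name, config.seed)
        manifest["stages"].append({"name": name, "status": "started"})

    def done(*outputs: Path) -> None:
        manifest["stages"][-1]["status"] = "completed"
        manifest["outputs"].extend(str(p.relative_to(out)) for p in outputs)

    result = PipelineResult(out_dir=out, manifest=manifest)
    try:
        # -- data ----------------------------------------------------------
        if data is None:
            if config.truth is None:
                raise ConfigError("truth: required when no dataset is supplied")
            stage("simulate")
            units = simulate_dataset(config.truth, config.design)
        else:
            stage("load")
            units = (
                read_dataset(data) if isinstance(data, (str, Path)) else list(data)
            )
        data_path = out / "dataset.csv"
        write_dataset(units, data_path)
        done(data_path)
        model_data = ModelData(units)
        log.info(
            "data: %d units, %d populations, %d clones",
            model_data.n_units, model_data.n_populations, model_data.n_clones,
        )

        # -- fit -----------------------------------------------------------
        stage("fit")
        draws = sample_posterior(model_data, config.priors, config.sampler)
        result.draws = draws
        draws_path = out / "draws.csv"
        draws.save(draws_path)
        done(draws_path)

        # -- diagnose ------------------------------------------------------
        stage("diagnose")
        core = sample_fixed_effect_names() + ["sigma_pop", "sigma_clone", "nu"]
        report = convergence_report(draws, core)
        diag = {
            "rhat_threshold": config.rhat_threshold,
            "max_rhat": float(report["rhat"].max()),
            "min_ess_bulk": float(report["ess_bulk"].min()),
            "divergences": divergence_count(draws),
            "parameters": report.to_dict(orient="records"),
            "all_passed": bool((report["rhat"] < config.rhat_threshold).all()),
        }
        diag_path = out / "diagnostics.json"
        diag_path.write_text(json.dumps(diag, indent=2), encoding="utf-8")
        done(diag_path)
        result.rhat_ok = diag["all_passed"]

        # -- summarize -----------------------------------------------------
        stage("summarize")
        summary = summarize_parameters(draws, core, levels=config.summary_levels)
        summary_path = out / "summary.csv"
        summary.to_csv(summary_path, index=False)
        marginals = {
            name: {
                "median": est.median,
                "ci95": list(est.ci95),
            }
            for name, est in (
                (k, marginal_survival(draws, cond))
                for k, cond in _MARGINAL_CONDITIONS.items()
            )
        }
        cpf_effect = marginal_effect_pp(draws, "cpf")
        marginals["cpf_contrast_pp"] = {
            "median": cpf_effect["percentage_points"].median,
            "ci95": list(cpf_effect["percentage_points"].ci95),
        }
        marg_path = out / "marginals.json"
        marg_path.write_text(json.dumps(marginals, indent=2), encoding="utf-8")
        done(summary_path, marg_path)

        # -- ppc -----------------------------------------------------------
        stage("ppc")
        ppc = posterior_predictive(
            draws, model_data, n_replicates=config.ppc_replicates, seed=config.seed
        )
        ppc_path = out / "ppc_summary.csv"
        ppc.summary.to_csv(ppc_path, index=False)
        ppc_counts_path = out / "ppc_counts.csv"
        ppc.count_table.to_csv(ppc_counts_path, index=False)
        done(ppc_path, ppc_counts_path)

        # -- sensitivity (optional) ---------------------------------------
        if config.sensitivity_beta_scales:
            stage("sensitivity")
            specs = [config.priors] + [
                PriorSpec(**{**config.priors.to_dict(), "beta_scale": s})
                for s in config.sensitivity_beta_scales
            ]
            sens = prior_sensitivity(model_data, specs, config.sampler)
            sens_path = out / "sensitivity.csv"
            sens.to_csv(sens_path, index=False)
            done(sens_path)
    except Exception:
        if manifest["stages"]:
            manifest["stages"][-1]["status"] = "failed"
        manifest["timestamps"]["finished"] = time.time()
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )
        raise

    manifest["timestamps"]["finished"] = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    if config.fail_on_rhat and not diag["all_passed"]:
        raise RuntimeError(
            f"convergence failure: max R-hat {diag['max_rhat']:.4f} >= "
            f"{config.rhat_threshold}"
        )
    return result


def _versions() -> dict[str, str]:
    import arviz
    import scipy

    return {
        "daphtox": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "arviz": arviz.__version__,
    }


def recovery_experiment(
    truth: SimulationTruth,
    n_replicates: int,
    design: DesignSpec | None = None,
    priors: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Parameter-recovery / credible-interval coverage experiment.

    Simulates ``n_replicates`` datasets from ``truth`` (replicate r uses
    an independent substream of ``seed``), fits each, and reports per
    fixed effect and variance component: mean posterior-median bias,
    empirical coverage of the equal-tailed ``ci_level`` interval, mean
    interval width, the fraction of replicates with negative posterior
    median, and the worst R-hat per fit. Failed fits are excluded with
    their count recorded in the ``n_failed`` attribute column.
    """
    design = design if design is not None else DesignSpec.study()
    priors = priors if priors is not None else PriorSpec()
    sampler = sampler if sampler is not None else SamplerConfig()
    if n_replicates == 0:
        return pd.DataFrame(
            columns=[
                "parameter", "true_value", "mean_median_bias", "coverage",
                "mean_ci_width", "frac_median_negative", "n_ok", "n_failed",
                "frac_rhat_below_1_05",
            ]
        )
    targets = dict(
        zip(sample_fixed_effect_names(), np.asarray(truth.beta, dtype=float))
    )
    targets["sigma_pop"] = truth.sigma_pop
    targets["sigma_clone"] = truth.sigma_clone
    names = list(targets)
    records: dict[str, list] = {n: [] for n in names}
    rhat_max: list[float] = []
    n_failed = 0
    seed_seq = np.random.SeedSequence(seed).spawn(n_replicates)
    alpha = (1 - ci_level) / 2
    for r in range(n_replicates):
        rep_seed = int(seed_seq[r].generate_state(1)[0] % (2**31 - 1))
        rep_truth = SimulationTruth(
            beta=truth.beta,
            sigma_pop=truth.sigma_pop,
            sigma_clone=truth.sigma_clone,
            nu=truth.nu,
            seed=rep_seed,
        )
        try:
            units = simulate_dataset(rep_truth, design)
            model_data = ModelData(units)
            cfg = SamplerConfig(**{**sampler.to_dict(), "seed": rep_seed})
            draws = sample_posterior(model_data, priors, cfg)
        except Exception as exc:  # noqa: BLE001 - logged and excluded
            log.warning("replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        report = convergence_report(draws, names)
        rhat_max.append(float(report["rhat"].max()))
        for name in names:
            x = draws.flat(name)
            lo, hi = np.quantile(x, [alpha, 1 - alpha])
            records[name].append(
                (float(np.median(x)), float(lo), float(hi))
            )
    rows = []
    for name in names:
        if not records[name]:
            rows.append({"parameter": name, "n_ok": 0, "n_failed": n_failed})
            continue
        med, lo, hi = map(np.array, zip(*records[name]))
        true_val = targets[name]
        rows.append(
            {
                "parameter": name,
                "true_value": true_val,
                "mean_median_bias": float(np.mean(med - true_val)),
                "coverage": float(np.mean((lo <= true_val) & (true_val <= hi))),
                "mean_ci_width": float(np.mean(hi - lo)),
                "frac_median_negative": float(np.mean(med < 0)),
                "n_ok": len(med),
                "n_failed": n_failed,
                "frac_rhat_below_1_05": float(np.mean(np.array(rhat_max) < 1.05)),
            }
        )
    return pd.DataFrame(rows)
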