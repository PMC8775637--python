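"""Run configuration, draw persistence and end-to-end pipeline orchestration.

A run is fully reproducible from (config, input data, seeds): the pipeline
writes every stage's artifact — screening report, per-chain draws, summary
tables, DIC comparison, convergence diagnostics — plus a manifest recording
the seeds and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import ObservationSet
from .encoding import DEFAULT_REFERENCES, build_design_matrix, subset_columns
from .model import MCMCConfig, PosteriorDraws, PriorSpec, dic, fit_fixed_logit, gelman_rubin, run_chain
from .screening import DEFAULT_THRESHOLD, screen_variables
from .stratified import default_plan, fit_stratified, subset_by_facility
from .summaries import compare_models, summarize
from .synthetic import TrueModel, default_scheme, read_dataset, sample_covariates, simulate_outcomes, write_dataset

__all__ = ["RunConfig", "SimulateConfig", "ModelConfig", "run_pipeline", "save_draws", "load_draws", "read_dataset"]

logger = logging.getLogger(__name__)

#: Random set of the pooled-model template: the coefficients reported with a
#: parameter-distribution SD in the all-facilities analysis.
DEFAULT_RANDOM_SET = (
    "age:middle_aged vs young",
    "dividing_strip:barriers vs greenbelt",
    "vehicle_lanes:2 vs 1",
    "bike_volume:medium vs low",
    "vehicle_volume:medium vs low",
    "time_interval:evening vs morning",
)

_CONFIG_KEYS = {"seed", "input", "simulate", "screening_threshold", "prior", "model", "stratify"}


@dataclass(frozen=True)
class SimulateConfig:
    n: int = 2000
    site_block: bool = False
    mu: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ModelConfig:
    chains: int = 2
    iterations: int = 20_000
    burnin: int = 10_000
    thin: int = 1
    random_set: tuple[str, ...] = DEFAULT_RANDOM_SET


@dataclass(frozen=True)
class RunConfig:
    """Schema-validated pipeline configuration (YAML/JSON serialisable)."""

    seed: int = 0
    input: str | None = None
    simulate: SimulateConfig | None = None
    screening_threshold: float = DEFAULT_THRESHOLD
    prior: PriorSpec = field(default_factory=PriorSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    stratify: bool = False

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of 'input' and 'simulate' must be set")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            kwargs["simulate"] = SimulateConfig(**kwargs["simulate"])
        if "prior" in kwargs:
            p = dict(kwargs["prior"])
            if "random_set" in p:
                p["random_set"] = tuple(p["random_set"])
            kwargs["prior"] = PriorSpec(**p)
        if "model" in kwargs:
            m = dict(kwargs["model"])
            if "random_set" in m:
                m["random_set"] = tuple(m["random_set"])
            kwargs["model"] = ModelConfig(**m)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        out = asdict(self)
        out["prior"]["random_set"] = list(out["prior"]["random_set"])
        out["model"]["random_set"] = list(out["model"]["random_set"])
        return out


def save_draws(draws: PosteriorDraws, out_dir: str | Path) -> Path:
    """Persist draws as one CSV per chain plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mu_cols = [f"mu[{c}]" for c in draws.columns]
    s_cols = [f"sigma2[{c}]" for c in draws.random_set]
    for c in range(draws.n_chains):
        frame = pd.DataFrame(
            np.column_stack([draws.mu[c], draws.sigma2[c], draws.deviance[c]]),
            columns=mu_cols + s_cols + ["deviance"],
        )
        frame.to_csv(out / f"chain{c + 1}.csv", index=False, float_format="%.10g")
    pd.DataFrame(draws.beta_mean, columns=draws.random_set).to_csv(
        out / "beta_mean.csv", index=False, float_format="%.10g"
    )
    manifest = {
        "columns": draws.columns,
        "random_set": draws.random_set,
        "chains": draws.n_chains,
        "draws": draws.n_draws,
        "n_obs": draws.n_obs,
        "seeds": draws.seeds,
        "fingerprint": draws.fingerprint,
        "accept_rates": draws.accept_rates,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_draws(in_dir: str | Path) -> PosteriorDraws:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    K = len(manifest["columns"])
    mus, sigs, devs = [], [], []
    for c in range(manifest["chains"]):
        frame = pd.read_csv(src / f"chain{c + 1}.csv")
        arr = frame.to_numpy()
        mus.append(arr[:, :K])
        sigs.append(arr[:, K:-1])
        devs.append(arr[:, -1])
    beta_mean = pd.read_csv(src / "beta_mean.csv").to_numpy() if manifest["random_set"] else np.zeros(
        (manifest["n_obs"], 0)
    )
    if beta_mean.ndim == 1:
        beta_mean = beta_mean.reshape(-1, 1)
    return PosteriorDraws(
        columns=manifest["columns"],
        random_set=manifest["random_set"],
        mu=np.stack(mus),
        sigma2=np.stack(sigs),
        deviance=np.stack(devs),
        beta_mean=beta_mean,
        n_obs=manifest["n_obs"],
        accept_rates=manifest.get("accept_rates", {}),
        seeds=manifest.get("seeds", []),
        fingerprint=manifest.get("fingerprint", ""),
    )


def _write_summary(summary: pd.DataFrame, path: Path) -> None:
    summary.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """simulate/load -> screen -> fit (fixed + random) -> summarize [-> stratify].

    Returns a manifest dict (also written to ``manifest.json``); every output
    file is derivable from (config, input data, seeds).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.simulate is not None:
            truth = TrueModel(
                mu=dict(config.simulate.mu), sigma=dict(config.simulate.sigma), seed=config.seed
            )
            covs = sample_covariates(
                default_scheme(site_block=config.simulate.site_block), config.simulate.n, config.seed
            )
            ds = simulate_outcomes(covs, truth)
            obs = ds.observations
            write_dataset(ds, out / "simulated.csv")
        else:
            obs = read_dataset(config.input)
        logger.info("stage input: %d observations", obs.n)

        stage = "encoding"
        if obs.y is None:
            raise ValueError("dataset has no outcome column")
        dm = build_design_matrix(obs.covariates, DEFAULT_REFERENCES)

        stage = "screening"
        report = screen_variables(dm, obs.y, config.screening_threshold)
        (out / "screening.json").write_text(json.dumps(report.to_dict(), indent=2))
        dm = report.retained_design(dm)

        stage = "fit"
        random_set = tuple(c for c in config.model.random_set if c in dm.columns)
        prior = PriorSpec(
            mean_loc=config.prior.mean_loc,
            mean_var=config.prior.mean_var,
            var_shape=config.prior.var_shape,
            var_rate=config.prior.var_rate,
            random_set=random_set,
        )
        mcmc = MCMCConfig(
            chains=config.model.chains,
            iterations=config.model.iterations,
            burnin=config.model.burnin,
            thin=config.model.thin,
            seed=config.seed,
        )
        draws_rp = run_chain(dm, obs.y, prior, mcmc)
        draws_fx = fit_fixed_logit(dm, obs.y, prior, mcmc)
        save_draws(draws_rp, out / "draws_random")
        save_draws(draws_fx, out / "draws_fixed")

        stage = "summaries"
        _write_summary(summarize(draws_rp), out / "summary_random.csv")
        _write_summary(summarize(draws_fx), out / "summary_fixed.csv")
        comparison = compare_models(
            dic(draws_rp, dm, obs.y), dic(draws_fx, dm, obs.y), "random_parameter", "fixed_parameter"
        )
        (out / "dic_comparison.json").write_text(json.dumps(comparison.to_dict(), indent=2))
        diagnostics = {
            "random_parameter": gelman_rubin(draws_rp) if config.model.chains > 1 else {},
            "fixed_parameter": gelman_rubin(draws_fx) if config.model.chains > 1 else {},
        }
        (out / "convergence.json").write_text(json.dumps(diagnostics, indent=2))

        strata_files = []
        if config.stratify:
            stage = "stratify"
            plan = default_plan()
            fits = fit_stratified(subset_by_facility(obs, plan), plan, prior, mcmc)
            for label, fit in fits.items():
                if fit.draws is not None:
                    path = out / f"summary_{label}.csv"
                    _write_summary(fit.summary, path)
                    strata_files.append(path.name)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_obs": int(obs.n),
        "retained_columns": dm.columns,
        "dic": comparison.to_dict(),
        "stratified_tables": strata_files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
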