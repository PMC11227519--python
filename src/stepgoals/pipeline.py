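"""End-to-end orchestration: generate -> preprocess -> describe -> fit ->
recommend, plus the parameter-recovery experiment.

Every stage reads only files the previous stage wrote into the run
directory, and all randomness flows from the run seed, so a rerun with the
same configuration reproduces identical numeric outputs.  The default
configuration is desk-scale (tens of participants, a couple of weeks,
short chains); the study-scale sizes are reachable purely through
configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import descriptives, preprocess, synthetic
from .forecast import CellSet, recommendation_table
from .inference import PosteriorDraws, PriorSpec, run_mcmc, summarize_posterior
from .preprocess import HOUR_COLS
from .synthetic import GeneratorConfig
from .twopart import (
    DAY_TYPES,
    EVENING_STRATA,
    MORNING,
    STRATUM_EDGES,
    ModelCellKey,
    TwoPartParameters,
    design_matrix,
    design_names,
    sample_hours,
)

logger = logging.getLogger("stepgoals")

__all__ = [
    "MCMCConfig",
    "RunConfig",
    "build_cell_data",
    "fit_cells",
    "load_cellset",
    "run_pipeline",
    "parameter_recovery_experiment",
    "coverage_experiment",
]

RHAT_FLAG = 1.01


@dataclass
class MCMCConfig:
    n_chains: int = 4
    n_burn: int = 300
    n_keep: int = 300


@dataclass
class RunConfig:
    outdir: Path = Path("runs/demo")
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    fit_hours: tuple = tuple(range(18, 24))
    fit_day_types: tuple = DAY_TYPES
    goals: tuple = (5_000, 7_500, 10_000)
    recommend_hours: tuple = tuple(range(18, 24))
    recommend_subgroups: tuple = ("overall",)
    criterion: str = "mean"
    n_mean_draws: int = 100
    n_paths_per_draw: int = 25
    n_prob_paths: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if any(h < 0 or h > 23 for h in self.fit_hours):
            raise ValueError("fit_hours must be within 0..23")
        if self.recommend_hours:
            # forecasts chain through hour 23; all later hours must be fitted
            needed = set(range(min(self.recommend_hours), 24))
            if not needed <= set(self.fit_hours):
                raise ValueError(
                    "fit_hours must cover every hour from the earliest "
                    "recommendation hour through 23"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        kwargs = dict(raw)
        if "generator" in kwargs:
            gen = dict(kwargs["generator"])
            for key in ("date_start", "date_end"):
                if key in gen and isinstance(gen[key], str):
                    gen[key] = dt.date.fromisoformat(gen[key])
            for key in ("goal_boost", "cum_effect", "boost_hours"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            if "diurnal_profile" in gen:
                gen["diurnal_profile"] = {
                    (dtk, int(h)): tuple(v)
                    for (dtk, h), v in gen["diurnal_profile"].items()
                }
            kwargs["generator"] = GeneratorConfig(**gen)
        if "priors" in kwargs:
            kwargs["priors"] = PriorSpec(**kwargs["priors"])
        if "mcmc" in kwargs:
            kwargs["mcmc"] = MCMCConfig(**kwargs["mcmc"])
        for key in (
            "fit_hours",
            "fit_day_types",
            "goals",
            "recommend_hours",
            "recommend_subgroups",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# --------------------------------------------------------------------------
# stage helpers


def _paths(outdir: Path) -> dict[str, Path]:
    return {
        "profiles": outdir / "profiles.csv",
        "blocks": outdir / "blocks.csv",
        "corruption": outdir / "corruption.csv",
        "days": outdir / "participant_days.csv",
        "profiles_clean": outdir / "profiles_clean.csv",
        "exclusions": outdir / "exclusions.json",
        "hourly_summary": outdir / "hourly_summary.csv",
        "goal_bands": outdir / "goal_bands.csv",
        "rhat": outdir / "rhat.csv",
        "draws_dir": outdir / "draws",
        "recommendations": outdir / "recommendations.csv",
        "manifest": outdir / "manifest.json",
    }


def stage_generate(cfg: RunConfig) -> dict:
    paths = _paths(cfg.outdir)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    profiles = synthetic.generate_profiles(cfg.generator)
    days = synthetic.generate_hourly_steps(profiles, cfg.generator)
    blocks, sidecar = synthetic.emit_block_records(days, cfg.generator)
    profiles.to_csv(paths["profiles"], index=False)
    blocks.to_csv(paths["blocks"], index=False)
    sidecar.to_csv(paths["corruption"], index=False)
    logger.info("generate: %d profiles, %d blocks", len(profiles), len(blocks))
    return {"n_profiles": len(profiles), "n_blocks": len(blocks), "n_corrupt": len(sidecar)}


def stage_preprocess(cfg: RunConfig) -> dict:
    paths = _paths(cfg.outdir)
    blocks = pd.read_csv(paths["blocks"])
    profiles = pd.read_csv(paths["profiles"])
    clean, clean_log = preprocess.clean_blocks(blocks)
    days = preprocess.impute_and_aggregate(clean)
    days, window_log = preprocess.restrict_window_and_daytype(
        days, cfg.generator.date_start, cfg.generator.date_end
    )
    kept, reasons = preprocess.filter_profiles(profiles)
    kept = preprocess.derive_groups(kept)
    days = days[days["participant_id"].isin(kept["participant_id"])].reset_index(
        drop=True
    )
    days.to_csv(paths["days"], index=False)
    kept.to_csv(paths["profiles_clean"], index=False)
    log = {
        "blocks": clean_log.as_dict(),
        "window": window_log,
        "profiles": reasons,
    }
    with open(paths["exclusions"], "w") as fh:
        json.dump(log, fh, indent=2)
    logger.info("preprocess: %d participant-days", len(days))
    return {"n_days": len(days), "n_profiles": len(kept)}


def stage_describe(cfg: RunConfig) -> dict:
    paths = _paths(cfg.outdir)
    days = pd.read_csv(paths["days"])
    profiles = pd.read_csv(paths["profiles_clean"])
    out = {}
    for grouping in ("age_group", "bmi_group", "sex"):
        summary = descriptives.daily_summary(days, profiles, grouping)
        table = summary.per_level.assign(
            grouping=grouping,
            f_statistic=summary.test.statistic,
            p_value=summary.test.p_value,
        )
        table.to_csv(cfg.outdir / f"daily_summary_{grouping}.csv", index=False)
        out[grouping] = {
            "F": summary.test.statistic,
            "p": summary.test.p_value,
        }
    descriptives.hourly_summary(days).to_csv(paths["hourly_summary"], index=False)
    descriptives.goal_band_table(days["daily_total"].to_numpy()).to_csv(
        paths["goal_bands"], index=False
    )
    return {"groupings": out, "n_days": len(days)}


def build_cell_data(
    days: pd.DataFrame, profiles: pd.DataFrame, hour: int, day_type: str
) -> dict[ModelCellKey, tuple[np.ndarray, np.ndarray]]:
    """Design/outcome pairs for one hour and day type, split by stratum."""
    sub = days[days["day_type"] == day_type].merge(
        profiles[["participant_id", "age_group", "bmi_group", "sex"]],
        on="participant_id",
        how="inner",
    )
    y = sub[f"h{hour:02d}"].to_numpy(dtype=float)
    prev_cols = [f"h{h:02d}" for h in range(hour)]
    cum = sub[prev_cols].sum(axis=1).to_numpy(dtype=float) if prev_cols else np.zeros(len(sub))
    out: dict[ModelCellKey, tuple[np.ndarray, np.ndarray]] = {}
    if hour < 12:
        X = design_matrix(sub["age_group"], sub["bmi_group"], sub["sex"])
        out[ModelCellKey(hour, day_type, MORNING)] = (X, y)
        return out
    labels = np.searchsorted(np.asarray(STRATUM_EDGES), cum, side="right")
    for s_idx, stratum in enumerate(EVENING_STRATA):
        mask = labels == s_idx
        X = design_matrix(
            sub["age_group"][mask], sub["bmi_group"][mask], sub["sex"][mask], cum[mask]
        )
        out[ModelCellKey(hour, day_type, stratum)] = (X, y[mask])
    return out


def _cell_seed(base_seed: int, key: ModelCellKey) -> int:
    dti = DAY_TYPES.index(key.day_type)
    strata = (MORNING,) + EVENING_STRATA
    return base_seed * 100_000 + key.hour * 1_000 + dti * 100 + strata.index(key.stratum)


def fit_cells(
    days: pd.DataFrame,
    profiles: pd.DataFrame,
    cfg: RunConfig,
) -> dict[ModelCellKey, PosteriorDraws]:
    """Run the sampler for every configured (hour, day type, stratum) cell."""
    fits: dict[ModelCellKey, PosteriorDraws] = {}
    for day_type in cfg.fit_day_types:
        for hour in sorted(cfg.fit_hours):
            for key, (X, y) in build_cell_data(days, profiles, hour, day_type).items():
                fits[key] = run_mcmc(
                    X,
                    y,
                    priors=cfg.priors,
                    n_chains=cfg.mcmc.n_chains,
                    n_burn=cfg.mcmc.n_burn,
                    n_keep=cfg.mcmc.n_keep,
                    seed=_cell_seed(cfg.seed, key),
                )
                logger.info("fit %s: n=%d", key.label(), len(y))
    return fits


def stage_fit(cfg: RunConfig) -> tuple[dict, dict[ModelCellKey, PosteriorDraws]]:
    paths = _paths(cfg.outdir)
    days = pd.read_csv(paths["days"])
    profiles = pd.read_csv(paths["profiles_clean"])
    fits = fit_cells(days, profiles, cfg)

    draws_dir = paths["draws_dir"]
    draws_dir.mkdir(parents=True, exist_ok=True)
    rhat_rows = []
    for key, post in fits.items():
        merged = pd.DataFrame(post.merged(), columns=post.names)
        merged.to_csv(draws_dir / f"{key.label()}.csv", index=False)
        table = post.rhat_table()
        rhat_rows.append(
            {
                "cell": key.label(),
                "max_rhat": float(table.max()),
                "n_flagged": int((table >= RHAT_FLAG).sum()),
                "degenerate_logistic": post.degenerate.get("logistic", False),
                "degenerate_gamma": post.degenerate.get("gamma", False),
            }
        )
    rhat_df = pd.DataFrame(rhat_rows)
    rhat_df.to_csv(paths["rhat"], index=False)
    info = {
        "n_cells": len(fits),
        "max_rhat": float(rhat_df["max_rhat"].max()) if len(rhat_df) else None,
        "n_cells_flagged": int((rhat_df["max_rhat"] >= RHAT_FLAG).sum())
        if len(rhat_df)
        else 0,
    }
    return info, fits


def load_cellset(outdir: str | Path) -> CellSet:
    """Rebuild a CellSet from the draws CSVs written by the fit stage."""
    draws_dir = Path(outdir) / "draws"
    cells = {}
    for path in sorted(draws_dir.glob("*.csv")):
        day_type, hour_part, stratum = path.stem.split("_")
        key = ModelCellKey(int(hour_part[1:]), day_type, stratum)
        cells[key] = pd.read_csv(path).to_numpy(dtype=float)
    if not cells:
        raise FileNotFoundError(f"no fitted cells under {draws_dir}")
    return CellSet(cells)


def _subgroup_demo(label: str) -> dict:
    """Demographic overrides for a named subgroup ('overall' = reference)."""
    from .twopart import AGE_GROUPS, BMI_GROUPS

    if label == "overall":
        return {}
    if label in AGE_GROUPS:
        return {"age_group": label}
    if label in BMI_GROUPS:
        return {"bmi_group": label}
    if label in ("male", "female"):
        return {"sex": label}
    raise ValueError(f"unknown subgroup {label!r}")


def stage_recommend(
    cfg: RunConfig, fits: dict[ModelCellKey, PosteriorDraws] | None = None
) -> dict:
    paths = _paths(cfg.outdir)
    cells = CellSet.from_posteriors(fits) if fits else load_cellset(cfg.outdir)
    rng = np.random.default_rng([cfg.seed, 101])
    subgroups = {label: _subgroup_demo(label) for label in cfg.recommend_subgroups}
    table = recommendation_table(
        cells,
        hours=cfg.recommend_hours,
        goals=cfg.goals,
        day_types=cfg.fit_day_types,
        subgroups=subgroups,
        rng=rng,
        criterion=cfg.criterion,
        n_draws=cfg.n_mean_draws,
        n_paths_per_draw=cfg.n_paths_per_draw,
        n_prob_paths=cfg.n_prob_paths,
    )
    table.to_csv(paths["recommendations"], index=False)
    return {"n_recommendations": len(table)}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    current = "generate"
    try:
        stages["generate"] = stage_generate(cfg)
        current = "preprocess"
        stages["preprocess"] = stage_preprocess(cfg)
        current = "describe"
        stages["describe"] = stage_describe(cfg)
        current = "fit"
        fit_info, fits = stage_fit(cfg)
        stages["fit"] = fit_info
        current = "recommend"
        stages["recommend"] = stage_recommend(cfg, fits)
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "stages": stages,
        "rhat_flag_threshold": RHAT_FLAG,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(_paths(cfg.outdir)["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# --------------------------------------------------------------------------
# parameter recovery


def simulate_cell_rows(
    params: TwoPartParameters,
    n_rows: int,
    rng: np.random.Generator,
    stratum: str = MORNING,
    marginals: Mapping | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw design rows and hurdle outcomes from known cell parameters.

    Demographics are sampled from the generator marginals; for evening
    strata the accumulated count is uniform over the stratum's interval
    (capped at 12,500 for the open-ended top stratum).
    """
    marginals = marginals or synthetic.default_marginals()
    from .twopart import AGE_GROUPS, BMI_GROUPS

    age = rng.choice(
        AGE_GROUPS, size=n_rows, p=[marginals["age_group"][g] for g in AGE_GROUPS]
    )
    bmi = rng.choice(
        BMI_GROUPS, size=n_rows, p=[marginals["bmi_group"][g] for g in BMI_GROUPS]
    )
    sex = rng.choice(
        ("female", "male"),
        size=n_rows,
        p=[marginals["sex"]["female"], marginals["sex"]["male"]],
    )
    if stratum == MORNING:
        X = design_matrix(age, bmi, sex)
    else:
        bounds = {
            "S1": (0.0, 5000.0),
            "S2": (5000.0, 7500.0),
            "S3": (7500.0, 10000.0),
            "S4": (10000.0, 12500.0),
        }[stratum]
        cum = rng.uniform(*bounds, size=n_rows)
        X = design_matrix(age, bmi, sex, cum)
    y = sample_hours(params, X, rng).astype(float)
    return X, y


def parameter_recovery_experiment(
    generator: GeneratorConfig | None = None,
    cell_keys: Sequence[ModelCellKey] | None = None,
    n_rows: int = 5_000,
    mcmc: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Fit cells on data simulated from known truth and compare.

    Returns a per-parameter table (truth, posterior mean/SD, z-score,
    interval coverage) and a summary dict with the maximum |z| and the
    fraction of 95% intervals covering the truth.
    """
    generator = (generator or GeneratorConfig()).without_boost()
    truth = synthetic.compile_truth(generator)
    if cell_keys is None:
        cell_keys = [
            ModelCellKey(8, "weekday", MORNING),
            ModelCellKey(19, "weekday", "S2"),
        ]
    mcmc = mcmc or MCMCConfig(n_chains=4, n_burn=500, n_keep=500)
    priors = priors or PriorSpec()
    rng = np.random.default_rng([seed, 211])

    rows = []
    for key in cell_keys:
        params = truth[key]
        X, y = simulate_cell_rows(
            params, n_rows, rng, key.stratum, generator.demographic_marginals
        )
        post = run_mcmc(
            X,
            y,
            priors=priors,
            n_chains=mcmc.n_chains,
            n_burn=mcmc.n_burn,
            n_keep=mcmc.n_keep,
            seed=_cell_seed(seed, key),
        )
        true_vec = np.concatenate(
            [params.beta, params.gamma, [np.log(params.alpha)]]
        )
        summary = summarize_posterior(post)
        sds = post.merged().std(axis=0, ddof=1)
        for name, tv, mean, sd, lo, hi in zip(
            post.names,
            true_vec,
            summary["mean"],
            sds,
            summary["ci_lower"],
            summary["ci_upper"],
        ):
            rows.append(
                {
                    "cell": key.label(),
                    "parameter": name,
                    "truth": tv,
                    "post_mean": mean,
                    "post_sd": sd,
                    "z": (mean - tv) / sd if sd > 0 else np.inf,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "covered": bool(lo <= tv <= hi),
                }
            )
    report = pd.DataFrame(rows)
    summary = {
        "n_cells": len(cell_keys),
        "n_parameters": len(report),
        "max_abs_z": float(report["z"].abs().max()),
        "coverage": float(report["covered"].mean()),
        "pass_3sd": bool((report["z"].abs() < 3.0).all()),
    }
    return report, summary


def coverage_experiment(
    n_replicates: int = 100,
    n_rows: int = 300,
    truth: TwoPartParameters | None = None,
    mcmc: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
    seed: int = 0,
) -> dict:
    """Reduced calibration run: intercept-only cells, many replicates.

    For each replicate, data are simulated from fixed truth, the posterior
    is sampled with short chains, and coverage of the nominal 95%
    intervals is recorded per parameter.  Returns per-parameter coverage
    fractions.
    """
    truth = truth or TwoPartParameters(beta=[0.3], gamma=[6.2], alpha=1.8)
    mcmc = mcmc or MCMCConfig(n_chains=4, n_burn=250, n_keep=250)
    priors = priors or PriorSpec()
    true_vec = np.concatenate([truth.beta, truth.gamma, [np.log(truth.alpha)]])
    rng = np.random.default_rng([seed, 307])
    covered = np.zeros((n_replicates, len(true_vec)), dtype=bool)
    for r in range(n_replicates):
        X = np.ones((n_rows, 1))
        y = sample_hours(truth, X, rng).astype(float)
        post = run_mcmc(
            X,
            y,
            priors=priors,
            n_chains=mcmc.n_chains,
            n_burn=mcmc.n_burn,
            n_keep=mcmc.n_keep,
            seed=seed * 1_000_003 + r,
        )
        summary = summarize_posterior(post)
        covered[r] = (summary["ci_lower"].to_numpy() <= true_vec) & (
            true_vec <= summary["ci_upper"].to_numpy()
        )
    return {
        "n_replicates": n_replicates,
        "coverage_by_parameter": covered.mean(axis=0).tolist(),
        "coverage_overall": float(covered.mean()),
    }
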