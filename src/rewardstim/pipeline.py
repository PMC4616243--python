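"""End-to-end orchestration: simulate (or load) -> inclusion -> per-site
effects -> pooled Gaussian and accumulation fits -> population statistics ->
engagement/waning controls -> machine-readable report bundle.

One global seed fans out to named per-component substreams so stage-level
reruns are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engagement as eng
from . import population as pop
from .accumulation import reward_modulation_report
from .gaussian import pooled_reward_interaction
from .simulate import DEFAULT_LEVELS, DEFAULT_TRUTH, GeneratorConfig, simulate_session, simulate_site_set
from .trial_data import inclusion_filter, normalize_disparity, write_sites, write_trials

log = logging.getLogger("rewardstim")

SCHEMA_VERSION = 1

# Stable component labels -> substream index for seed fan-out.
_COMPONENTS = ("simulate", "fits", "population", "engagement", "delta_dx")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "results/pipeline"
    n_sites: int = 48
    n_trials_per_site: int = 500
    base_params: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    disparity_levels: tuple[float, ...] = DEFAULT_LEVELS
    eccentricity_range: tuple[float, float] = (2.0, 14.0)
    n_starts: int = 10
    window: int = 30
    run_delta_dx: bool = True
    delta_dx_n_trials: int = 12000
    mode: str = "logistic"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("disparity_levels", "eccentricity_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def component_seed(seed: int, component: str) -> int:
    """Stable per-component substream seed derived from the global seed."""
    idx = _COMPONENTS.index(component)
    return int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2**31))


def _to_native(obj):
    if isinstance(obj, dict):
        return {str(k): _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_native(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def _validate_bundle(bundle: dict) -> None:
    required = {"schema_version", "config", "inclusion", "site_effects",
                "pooled_gaussian", "accumulation", "population", "engagement"}
    missing = required - set(bundle)
    if missing:
        raise ValueError(f"report bundle missing section(s): {sorted(missing)}")


def _lr_to_dict(lr) -> dict:
    return {"chi_stat": lr.chi_stat, "p_value": lr.p_value, "df": lr.df,
            "neg_logL_full": lr.neg_logL_full, "neg_logL_nested": lr.neg_logL_nested}


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic multi-site dataset and return (and
    write) the report bundle.  Identical configs and seeds give identical
    bundles."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"schema_version": SCHEMA_VERSION, "config": dataclasses.asdict(config)}

    stage = "simulate"
    try:
        trials, sites, truth = simulate_site_set(
            n_sites=config.n_sites,
            eccentricity_range=config.eccentricity_range,
            base_params=config.base_params,
            n_trials_per_site=config.n_trials_per_site,
            disparity_levels=config.disparity_levels,
            mode=config.mode,
            seed=component_seed(config.seed, "simulate"),
        )
        write_trials(trials, out_dir / "trials.tsv")
        write_sites(sites, out_dir / "sites.tsv")
        log.info("simulated %d sites, %d trials", config.n_sites, len(trials))

        stage = "inclusion"
        inclusion = inclusion_filter(trials)
        inclusion.to_csv(out_dir / "inclusion.tsv", sep="\t")
        included = set(inclusion.index[inclusion["passed"]])
        bundle["inclusion"] = {
            "n_sites": int(len(inclusion)),
            "n_included": int(len(included)),
            "failed": sorted(set(inclusion.index) - included),
        }
        kept = trials[trials["site_id"].isin(included)]
        normalized = normalize_disparity(kept, sites)

        stage = "site_effects"
        fit_seed = component_seed(config.seed, "fits")
        site_effects = pop.build_site_effects(
            kept, sites, n_starts=config.n_starts, seed=fit_seed, apply_inclusion=False
        )
        site_effects.to_csv(out_dir / "site_effects.tsv", sep="\t", index=False)
        bundle["site_effects"] = {"n_sites": int(len(site_effects)),
                                  "n_significant_pref": int(site_effects["significant_pref"].sum())}

        stage = "pooled_gaussian"
        pooled = {}
        for animal, sub in normalized.groupby("animal_id"):
            res = pooled_reward_interaction(sub, n_starts=config.n_starts, seed=fit_seed)
            pooled[str(animal)] = {
                "reward_on_performance": _lr_to_dict(res["reward_on_performance"]),
                "reward_on_shift": _lr_to_dict(res["reward_on_shift"]),
                "params_2a": res["fits"]["2a"].params(),
            }
            for tag, fit in res["fits"].items():
                log.info("gaussian %s (%s): -logL=%.3f converged=%s starts=%d",
                         tag, animal, fit.neg_log_likelihood, fit.converged, fit.n_starts)
        bundle["pooled_gaussian"] = pooled

        stage = "accumulation"
        accum = {}
        for animal, sub in normalized.groupby("animal_id"):
            report = reward_modulation_report(sub, n_starts=config.n_starts, seed=fit_seed)
            accum[str(animal)] = report.to_dict()
            for tag, fit in report.fits.items():
                log.info("accumulation %s (%s): -logL=%.3f converged=%s starts=%d",
                         tag, animal, fit.neg_log_likelihood, fit.converged, fit.n_starts)
        bundle["accumulation"] = accum

        stage = "population"
        pop_seed = component_seed(config.seed, "population")
        summaries = {}
        for scope in ("all", "significant_pref", *sorted(site_effects["animal_id"].unique())):
            try:
                summaries[scope] = pop.reward_effect_summary(site_effects, scope)
            except ValueError as exc:
                warnings.warn(f"reward-effect summary skipped for scope {scope!r}: {exc}")
        lillie = {
            "raw_shift": pop.lilliefors(site_effects["raw_shift_overall"], seed=pop_seed),
            "norm_shift": pop.lilliefors(site_effects["norm_shift_overall"], seed=pop_seed),
        }
        bundle["population"] = {
            "reward_effect": summaries,
            "lilliefors_p": {k: v[1] for k, v in lillie.items()},
            "correlations": pop.fig8_battery(site_effects),
        }

        stage = "engagement"
        eng_seed = component_seed(config.seed, "engagement")
        profiles = {}
        labeled_frames = []
        for site_id, sub in kept.groupby("site_id"):
            profile = eng.compute_profile(sub, window=config.window)
            profiles[str(site_id)] = profile
            labeled = normalized[normalized["site_id"] == site_id].copy()
            labeled["epoch_label"] = eng.label_trials(labeled, profile).to_numpy()
            labeled_frames.append(labeled)
        labeled_all = pd.concat(labeled_frames, ignore_index=True)
        fluct = pd.DataFrame({
            "site_id": list(profiles),
            "fluctuation_area_norm": [p.fluctuation_area_norm for p in profiles.values()],
        })
        merged = site_effects.merge(fluct, on="site_id")
        fluct_corr = pop.correlation(merged["reward_effect_norm"], merged["fluctuation_area_norm"])
        epoch_tests = eng.epoch_pooled_test(labeled_all, n_starts=config.n_starts, seed=eng_seed)
        waning = eng.waning_control(kept, site_effects)
        bundle["engagement"] = {
            "fluctuation_vs_reward_effect": {"r": fluct_corr[0], "p": fluct_corr[1]},
            "epoch_reward_on_shift": {k: _lr_to_dict(v) for k, v in epoch_tests.items()},
            "waning": {m: waning[m] for m in ("spearman", "pearson")},
            "n_epochs": {label: int(sum(sum(1 for e in p.epochs if e.label == label)
                                        for p in profiles.values()))
                         for label in ("good", "bad")},
        }

        if config.run_delta_dx:
            stage = "delta_dx"
            dd_seed = component_seed(config.seed, "delta_dx")
            dd_cfg = GeneratorConfig(
                n_trials=config.delta_dx_n_trials,
                disparity_levels=config.disparity_levels,
                params=dict(config.base_params),
                delta_dx_mode=True,
                animal_id="ica",
                site_id="ica_dx",
                seed=dd_seed,
            )
            dd_trials = simulate_session(dd_cfg)
            write_trials(dd_trials, out_dir / "delta_dx_trials.tsv")
            dd_norm = dd_trials.assign(
                C=dd_trials["disparity_deg"] / dd_cfg.max_abs_disparity_deg,
                microstim=dd_trials["delta_dx"],  # the flagged perturbation plays the role of beta
            )
            res = pooled_reward_interaction(dd_norm, n_starts=config.n_starts, seed=dd_seed)
            bundle["delta_dx"] = {
                "reward_on_performance": _lr_to_dict(res["reward_on_performance"]),
                "reward_on_shift": _lr_to_dict(res["reward_on_shift"]),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _validate_bundle(bundle)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_to_native(bundle), fh, indent=2, sort_keys=True)
    return _to_native(bundle)
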