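#!/usr/bin/env python
"""Generate the synthetic study dataset.

Simulates a two-animal, multi-site microstimulation experiment (48 sites,
~500 trials each, eccentricity-dependent disparity ranges) plus the
visual-perturbation (delta-dx) control session, and writes the trial and
site tables under results/data/.
"""

from pathlib import Path

from rewardstim.pipeline import component_seed
from rewardstim.simulate import GeneratorConfig, simulate_session, simulate_site_set
from rewardstim.trial_data import write_sites, write_trials

SEED = 20_250_923
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    trials, sites, truth = simulate_site_set(
        n_sites=48, n_trials_per_site=500, seed=component_seed(SEED, "simulate")
    )
    write_trials(trials, OUT / "trials.tsv")
    write_sites(sites, OUT / "sites.tsv")
    truth.to_csv(OUT / "generative_truth.tsv", sep="\t", index=False)

    dd_cfg = GeneratorConfig(
        n_trials=12_000, delta_dx_mode=True, animal_id="ica", site_id="ica_dx",
        seed=component_seed(SEED, "delta_dx"),
    )
    dd = simulate_session(dd_cfg)
    write_trials(dd, OUT / "delta_dx_trials.tsv")

    print(f"microstimulation dataset: {len(trials)} trials over {len(sites)} sites "
          f"({sites['animal_id'].value_counts().to_dict()})")
    print(f"delta-dx control: {len(dd)} trials, "
          f"{dd['delta_dx'].mean():.1%} perturbation trials")
    print(f"written under {OUT}/")


if __name__ == "__main__":
    main()
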