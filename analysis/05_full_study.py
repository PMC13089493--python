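"""End-to-end study run on fully simulated EEG.

Simulates a small cohort of multichannel naps (both conditions), runs the
complete per-nap pipeline (filter, re-reference, artifact mask, band powers,
event detection, densities, macroarchitecture, stimulus-locked likelihoods)
and the study-level models, and writes the feature and result tables.
Problem size is kept small here — the statistical properties of the chain
are quantified at scale in steps 02-04.
"""

from pathlib import Path

import numpy as np

from napscape import pipeline, simulate

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    bundle = simulate.simulate_cohort(simulate.CohortSpec(n_subjects=6, seed=SEED))
    rng = np.random.default_rng(SEED)
    naps = []
    for _, subj in bundle.subjects.iterrows():
        for cond_name, cond in (("baseline", 0), ("stimulation", 1)):
            spec = simulate.NapSpec(
                duration_min=8.0,
                sol_min=2.0,
                condition=cond_name,
                stim_start_after_onset_s=20.0,
            )
            nap = simulate.simulate_nap(spec, rng)
            naps.append(
                {
                    "rec": nap.recording,
                    "hyp": nap.hypnogram,
                    "train": nap.train,
                    "subject": subj["subject"],
                    "condition": cond,
                    "nap_id": f"{subj['subject']}-{cond_name}",
                }
            )
    out = pipeline.run_study(naps, bundle.subjects,
                             outcomes=("swa", "sw_density", "sigma", "spindle_density"))
    out["features"].to_csv(RESULTS / "study_features.csv", index=False)
    out["descriptives"].to_csv(RESULTS / "study_descriptives.csv")
    out["models"].to_csv(RESULTS / "study_models.csv", index=False)
    out["exclusions"].to_csv(RESULTS / "study_exclusions.csv", index=False)

    feats = out["features"]
    print(f"analysed {len(feats)} naps from {feats.subject.nunique()} subjects "
          f"({len(out['exclusions'])} exclusions)")
    by_cond = feats.groupby("condition")[["swa", "sigma", "sw_density",
                                          "spindle_density"]].mean()
    for cond, row in by_cond.iterrows():
        name = "baseline" if cond == 0 else "stimulation"
        print(f"  {name:12s} SWA={row.swa:8.1f} uV^2  sigma={row.sigma:6.2f} uV^2  "
              f"SW {row.sw_density:4.1f}/min  spindles {row.spindle_density:4.2f}/min")
    stim = feats[feats.condition == 1]
    if "kc_likelihood_on" in stim:
        print(f"  K-complex likelihood ON {stim.kc_likelihood_on.mean():.3f} "
              f"vs OFF {stim.kc_likelihood_off.mean():.3f}")


if __name__ == "__main__":
    main()
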