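"""Simulate the study cohort and inspect its descriptive statistics.

Generates the cohort layer (subjects, questionnaires, planted-model outcome
rows) plus one full EEG nap per condition, and writes the descriptive tables
that the later analysis steps build on.  Binary demo files (EDF) go to
scratch/; all result tables are CSV under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from napscape import io, metrics, sensory, simulate

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 2026


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    bundle = simulate.simulate_cohort(simulate.CohortSpec(n_subjects=35, seed=SEED))
    bundle.subjects.to_csv(RESULTS / "subjects.csv", index=False)
    io.write_questionnaire(bundle.questionnaire, RESULTS / "questionnaire.csv")
    bundle.feature_rows.to_csv(RESULTS / "cohort_feature_rows.csv", index=False)

    alpha = sensory.cronbach_alpha(
        bundle.questionnaire[io.ITEM_COLUMNS].to_numpy(float)
    )
    scored = sensory.score_questionnaires(bundle.questionnaire)
    print(f"cohort: {len(bundle.subjects)} subjects, "
          f"{len(bundle.feature_rows)} nap rows")
    print(f"reactivity {scored.reactivity.min():.2f}-{scored.reactivity.max():.2f} "
          f"(median NA count {scored.n_na.median():.0f}), Cronbach alpha {alpha:.2f}")

    # one EEG nap per condition, exported in the interchange formats
    rng = np.random.default_rng(SEED)
    rows = []
    for cond in ("baseline", "stimulation"):
        spec = simulate.NapSpec(duration_min=10.0, condition=cond,
                                stim_start_after_onset_s=30.0)
        nap = simulate.simulate_nap(spec, rng)
        io.write_recording(nap.recording, SCRATCH / f"demo_{cond}.edf")
        io.write_hypnogram(nap.hypnogram, RESULTS / f"demo_{cond}_hypnogram.txt")
        io.write_events(nap.events, RESULTS / f"demo_{cond}_events.csv")
        if nap.train is not None:
            io.write_stimulus_train(nap.train, RESULTS / f"demo_{cond}_stimuli.csv")
        m = metrics.macro_summary(nap.hypnogram)
        rows.append({"condition": cond, "tst_min": m.nap_min, "sol_min": m.sol_min,
                     "waso_min": m.waso_min, "efficiency_pct": m.efficiency_pct,
                     **{f"min_{k}": v for k, v in m.stage_min.items()}})
        print(f"demo {cond} nap: TST {m.nap_min:.1f} min, "
              f"efficiency {m.efficiency_pct:.1f}%, "
              f"{len(nap.events)} planted events")
    pd.DataFrame(rows).to_csv(RESULTS / "demo_nap_macro.csv", index=False)


if __name__ == "__main__":
    main()
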