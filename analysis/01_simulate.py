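"""Simulate the synthetic study cohort.

Generates the 48-subject cohort (true segmental rest/stress MBF fields
calibrated to the study's global moments), the four observers' value
tables, and dynamic TAC studies for a handful of subjects for the
kinetics QC.  Writes everything under results/analysis/.

Run:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
from pathlib import Path

from mbfagree import io as mio
from mbfagree.heart_model import SEGMENT_IDS
from mbfagree.kinetics import BLOOD_POOL_REGION, default_schedule
from mbfagree.synthdata import (CohortSpec, InputFunctionSpec,
                                ObserverNoiseSpec, segment_region_id,
                                simulate_cohort, simulate_dynamic_study,
                                simulate_observer_tables)

N_DYNAMIC_SUBJECTS = 4
DYNAMIC_NOISE_CV = 0.05

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/analysis"))
args = ap.parse_args()
out = args.out
out.mkdir(parents=True, exist_ok=True)

cohort_spec = CohortSpec(seed=args.seed)
true_table = simulate_cohort(cohort_spec)
true_table.to_csv(out / "true_values.csv", index=False)
glob = true_table[true_table.condition == "rest"].groupby("subject")[
    "global_mbf_true"].first()
print(f"cohort: {cohort_spec.n_subjects} subjects; global rest MBF "
      f"{glob.mean():.2f} +/- {glob.std():.2f} mL/min/g "
      f"(target {cohort_spec.rest_mbf_mean} +/- {cohort_spec.rest_mbf_sd})")

obs_table = simulate_observer_tables(true_table, ObserverNoiseSpec(),
                                     cohort_spec.n_observers,
                                     seed=args.seed + 1)
mio.write_observer_table(obs_table, out / "observer_values.csv")
print(f"observer tables: {cohort_spec.n_observers} observers, "
      f"{len(obs_table)} values, {obs_table.attrs['n_clipped']} clipped at 0")

schedule = default_schedule()
seg_wide = true_table.pivot_table(index=["subject", "condition"],
                                  columns="segment", values="mbf_true")
tacs_by_subject = {}
subjects = sorted(true_table["subject"].unique())[:N_DYNAMIC_SUBJECTS]
for i, subj in enumerate(subjects):
    for j, cond in enumerate(("rest", "stress")):
        truth = {s: float(seg_wide.loc[(subj, cond), s]) for s in SEGMENT_IDS}
        tacs, blood = simulate_dynamic_study(
            truth, InputFunctionSpec(), schedule,
            noise_cv=DYNAMIC_NOISE_CV, seed=args.seed + 100 + 2 * i + j)
        regions = {segment_region_id(s): tacs[s] for s in SEGMENT_IDS}
        regions[BLOOD_POOL_REGION] = blood
        tacs_by_subject[f"{subj}_{cond}"] = regions
mio.write_tacs(tacs_by_subject, out / "tacs.csv")
print(f"dynamic studies: {len(tacs_by_subject)} (subject x condition) "
      f"at noise_cv={DYNAMIC_NOISE_CV}; wrote {out / 'tacs.csv'}")
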