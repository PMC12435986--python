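"""Corrupt a cohort with recording artifacts and watch the exclusion rules.

One trial gets a 20-sample missing run (dropped marker), another has its
displacement collapsed to 2% (tracking failure). The gap rule removes the
first; the per-participant displacement rule removes the second together
with its other-condition counterpart, keeping the design balanced.
"""

from kinesig import CohortConfig, gen_cohort, inject_artifacts
from kinesig.preprocess import preprocess_trials

trials = gen_cohort(CohortConfig(n_speakers=2, n_signers=2, n_items=3,
                                 seed=42))
corrupted = inject_artifacts(
    trials,
    gap_run_lengths=[120],            # 0.25 s dropout at 480 Hz
    outlier_trial_ids=[trials[10].uid],
    outlier_scale=0.02,
)

kept, report = preprocess_trials(corrupted, cutoff_hz=10.0)

print(f"input trials:               {sum(report.n_input.values())}")
print(f"gap-excluded:               {report.n_gap_excluded}")
print(f"displacement outliers:      {report.n_displacement_excluded}")
print(f"removed to keep balance:    {report.n_pair_propagated}")
print(f"retained per group/condition: {report.n_retained}")
for uid, reason in report.reasons:
    print(f"  - {uid}: {reason}")
print("\nRetained counts are equal across conditions within each group,")
print("which is what the paired DTW stage downstream requires.")
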