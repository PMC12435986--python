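"""A miniature two-group study, end to end.

Speakers stretch and roughen their communicative movements; signers compress
and regularize theirs. The pipeline simulates the cohort, preprocesses it,
extracts features, aligns the condition pairs with DTW and fits the mixed
models — then we read off the group-level signature.
"""

from kinesig.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(seed=7, outdir="scratch/example_study",
                        n_speakers=4, n_signers=4, n_items=3)
report = run_pipeline(config)

wc = report["models"]["warping_cost_vs_zero"]
for group in ("speaker", "signer"):
    r = wc[group]
    print(f"{group}s: mean warping cost {r['mean']:8.1f} samples "
          f"(SE {r['se']:.1f}), t_{r['df']} = {r['t']:.2f}")

print("\nfeature            interaction estimate      t      df")
for feature in ("log_jerkiness", "sample_entropy", "rhythm_strokes", "rhythm_holds"):
    inter = report["models"][feature]["terms"][3]
    print(f"{feature:<18} {inter['estimate']:12.3f}      {inter['t']:6.2f}  {inter['df']:6.1f}")

print(
    "\nPositive speaker / negative signer warping costs, a negative jerkiness"
    "\ninteraction and positive rhythmicity interactions: the two groups move"
    "\nin opposite temporal directions when communicating."
)
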