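"""The DTW warping cost as a signed temporal stretch/compression meter.

Pairs generated at stretch factors from 0.5x to 2x: the mean difference of
aligned sample indices is negative when the communicative (query) trial is
compressed relative to its non-communicative reference, zero when the
timelines match, positive when it is stretched.
"""

from kinesig import PairConfig, StrokeChainConfig, gen_pair
from kinesig.dtw import dtw_align

print("stretch   normalized distance   warping cost (samples)")
for stretch in (0.5, 0.75, 1.0, 1.5, 2.0):
    config = PairConfig(
        base=StrokeChainConfig(noise_sd_mm=0.0, interstroke_interval_sd_s=0.0,
                               sampling_hz=120.0, seed=21),
        stretch_factor=stretch,
    )
    non_comm, comm = gen_pair(config)
    result = dtw_align(non_comm.trajectory, comm.trajectory)
    print(f"  {stretch:4.2f}   {result.normalized_distance:12.3f}"
          f"   {result.warping_cost:12.1f}")

print("\nThe cost is monotone in the stretch factor and crosses zero at 1.0;")
print("the normalized distance stays small because the spatial path is shared.")
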