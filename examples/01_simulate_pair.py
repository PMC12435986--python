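"""Generate one paired trial (re-enactment vs. description) and inspect it.

The communicative member shares the spatial path of its partner but its
stroke/hold timeline is stretched by 1.4x and its inter-stroke timing is
more variable — the temporal signature this package measures.
"""

from kinesig import PairConfig, StrokeChainConfig, gen_pair
from kinesig.features import jerkiness, rhythmicity, segment_strokes_holds
from kinesig.preprocess import resample_filter
from kinesig.speed import compute_speed_2d

config = PairConfig(
    base=StrokeChainConfig(seed=11),
    stretch_factor=1.4,
    delta_interval_sd_s=0.06,
)
non_comm, comm = gen_pair(config)

for record in (non_comm, comm):
    # low-pass to 10 Hz and resample 480 -> 120 Hz before differentiating,
    # otherwise sensor noise masquerades as submovements
    profile = compute_speed_2d(resample_filter(record.trajectory))
    seg = segment_strokes_holds(profile)
    rhythm, _ = rhythmicity(seg.stroke_intervals_s)
    print(
        f"{record.condition:>17}: duration {record.trajectory.duration_s:5.2f} s, "
        f"{seg.n_strokes} strokes, log jerk {jerkiness(profile)[1]:5.2f}, "
        f"stroke rhythmicity {rhythm:5.2f}"
    )

print(
    "\nThe communicative trial is ~1.4x longer; its noisier inter-stroke"
    "\nintervals lower the rhythmicity score (higher = more isochronous)."
)
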