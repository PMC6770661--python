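"""Generate a synthetic membrane-anchored system and recover its orientation.

Builds a rigid pseudo-protein posed over a pseudo-bilayer at a known
class-A orientation (alpha 90, beta 112, TM tilt 15, heme tilt 40 degrees,
globular domain 43 A above the bilayer centre), runs the orientation
pipeline on the emitted trajectory, and compares the recovered angles and
distances with the generator's closed-form ground truth.  Agreement at
machine precision shows the vector constructions are exact.
"""

import membpos as mp

spec = mp.class_a_spec(n_frames=5)
traj, truth, segmap = mp.emit_trajectory(spec)
series = mp.orientation_series(traj, segmap)

print(f"{'field':>12} {'target':>10} {'recovered':>12} {'error':>10}")
for field in ("alpha", "beta", "gamma", "heme_tilt", "d_globular", "d_fg"):
    target = truth[field][0]
    got = series[field][0]
    print(f"{field:>12} {target:>10.3f} {got:>12.6f} {abs(got - target):>10.2e}")
print(f"\norientation class from mean beta: {mp.classify(series['beta'].mean())}")
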