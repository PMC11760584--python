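"""Derive the 19 dynamic channels of a recording, including the moment.

The moment channel M = P cos(tilt) * r sin(azimuth) treats the pen
pressure as a force producing torque about the handwriting centroid
(r is the distance of each sample to the centroid); it couples the
kinematic, pressure and angle information in one signal.
"""

import numpy as np

import inkpd

spec = inkpd.CohortSpec(n_per_class=1, duration=4.0, seed=0)
cohort = inkpd.generate_cohort(spec)
sample = cohort.samples["PD_000"]

channels = inkpd.build_channelset(sample)
print("channel families:")
for family in ("kinematic", "pressure", "angle", "moment"):
    print(f"  {family:10s} ({len(channels.family(family)):2d}): "
          + ", ".join(channels.family(family)))

v = channels.signals["Velocity"]
m = channels.signals["Moment"]
print(f"\nmean pen speed: {v.mean():8.1f} tablet-units/s")
print(f"moment range:   [{m.min():10.0f}, {m.max():10.0f}] "
      "(pressure-units x tablet-units)")

# The ablation switch drops the moment channel (18 channels remain):
ablated = inkpd.build_channelset(sample,
                                 inkpd.ChannelConfig(include_moment=False))
print(f"\nwith moment: {len(channels.signals)} channels; "
      f"ablated: {len(ablated.signals)} channels")
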