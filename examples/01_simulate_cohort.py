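"""Generate a small labelled handwriting cohort and write it as SVC files.

The generator emulates a 200 Hz pen tablet with 8192 pressure levels:
healthy controls (HC) draw a spiral with tiny physiological tremor,
Parkinson's (PD) subjects get 4-6 Hz tremor, micrographia and raised
pressure variability, essential-tremor (ET) subjects 5-8 Hz tremor.
"""

import tempfile
from pathlib import Path

import inkpd

spec = inkpd.CohortSpec(n_per_class=3, duration=4.0, seed=42)
cohort = inkpd.generate_cohort(spec)

out = Path(tempfile.mkdtemp()) / "cohort"
cohort.write(out)
print(f"wrote {len(cohort.samples)} SVC files to {out}")

print("\nground truth (injected tremor, logged separately from the data):")
print(cohort.truth.round(2).to_string())

rid, sample = next(iter(cohort.samples.items()))
print(f"\n{rid}: {len(sample)} samples at {sample.fs:.0f} Hz, "
      f"pressure range [{sample.pressure.min():.0f}, {sample.pressure.max():.0f}]")
# Each line of an SVC file is one pen sample: x y t button azimuth tilt pressure.
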