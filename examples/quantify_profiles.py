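"""Reduce a cohort to dorsal-to-ventral angular pigment profiles.

Generates a small cohort, normalizes every image's mean gray value to
the dataset mean, fits each eye's center, and prints per-larva median
8-bit intensities in 5-degree angular bins.  High medians near 90
degrees are the depigmented central injury zone; low medians toward the
dorsal (0) and ventral (180) periphery are intact pigmented RPE.
"""

import numpy as np

from rpescreen import CohortSpec, PigmentProfile
from rpescreen.pipeline import reduce_cohort
from rpescreen.simulate import generate_cohort

spec = CohortSpec(
    n_control=4,
    n_knockout=4,
    knockout_front_shift_deg=20.0,
    base_profile=PigmentProfile(dorsal_front_deg=70, ventral_front_deg=110),
    seed=7,
)
profiles = reduce_cohort(generate_cohort(spec), bin_size=5)

header = "larva          " + " ".join(f"{s:>4d}" for s in range(30, 150, 10))
print("median 8-bit intensity by angular bin start (degrees):")
print(header)
for p in profiles:
    meds = [p.bin_medians[s // 5] for s in range(30, 150, 10)]
    cells = " ".join("   ." if np.isnan(m) else f"{m:4.0f}" for m in meds)
    print(f"{p.larva_id:<15}{cells}")
# Knockout larvae show the light (high-intensity) zone extending from
# ~50 to ~130 degrees; in controls it is confined to ~70-110 degrees.
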