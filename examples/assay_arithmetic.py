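"""The screen's scalar bookkeeping: mutagenic rate, Livak fold change,
fluorescence percent area, section-count summaries, and the endpoint
test-selection tree.
"""

import numpy as np
import pandas as pd

from rpescreen import (
    compare_scalar_endpoint,
    livak_fold_change,
    mutagenic_rate,
    percent_area,
    pooled_rnp_concentration,
    rasterize,
    summarize_counts,
    validation_gate,
)

# --- guide validation: headloop vs standard PCR band calls -----------------
# ten injected embryos; headloop bands absent in lanes 5 and 6
bands = pd.DataFrame(
    {
        "embryo_id": [f"e{i + 1}" for i in range(10)],
        "gene": "goi",
        "headloop_positive": [i not in (4, 5) for i in range(10)],
        "standard_positive": True,
    }
)
rate = mutagenic_rate(bands, "goi")
print(f"mutagenic rate: {rate:.1f}% -> {'pass' if validation_gate(rate) else 'fail'} "
      "(guides must exceed 70% to proceed)")
print(f"pooled RNP mix: {pooled_rnp_concentration([9.5, 9.5, 9.5]):.1f} uM total")

# --- relative expression (2^-ddCt) -----------------------------------------
ct = pd.DataFrame(
    [
        {"sample_group": g, "replicate_id": r, "target_ct": t, "housekeeping_ct": 15.0}
        for g, t in (("control", 20.0), ("knockout", 25.644))
        for r in (1, 2, 3)
    ]
)
livak = livak_fold_change(ct)
print(f"Livak: ddCt = {livak.delta_delta_ct:.3f}, fold change = {livak.fold_change:.4f} "
      f"({livak.percent_change:+.1f}% expression)")

# --- fluorescence percent area ---------------------------------------------
rng = np.random.default_rng(0)
image = rng.integers(0, 120, size=(64, 64)).astype(np.uint8)
mask = rasterize([[8.0, 8.0], [8.0, 55.0], [55.0, 55.0], [55.0, 8.0]], image.shape)
print(f"signal area >= 40/255 inside ROI: {percent_area(image, mask, threshold=40):.1f}%")

# --- per-larva count summaries ---------------------------------------------
counts = pd.DataFrame(
    [{"larva_id": "L1", "section_index": i + 1, "count": c, "assay": "BrdU"}
     for i, c in enumerate((4, 6, 5))]
    + [{"larva_id": "L1", "section_index": i + 1, "count": c, "assay": "TUNEL"}
       for i, c in enumerate((1, 0, 2))]
)
print(summarize_counts(counts).to_string(index=False))

# --- endpoint comparison with the test-selection tree ----------------------
res = compare_scalar_endpoint(
    {"scrambled": rng.normal(10, 2, 12), "knockout": rng.normal(14, 2, 12)}
)
print(f"endpoint test: {res.test}, p = {res.p_value:.2e}")
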