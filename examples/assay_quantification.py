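"""The small assay calculators: qPCR, proliferation, cell morphometry.

Each works from plain measurement tables; no fitting involved.
"""

import numpy as np

from cenckit import mal_summary, proliferation_ratios, relative_expression

# qPCR: comparative Ct. A target 3.32 cycles later than the housekeeping
# reference is ~10x less abundant (2**-3.32 ~ 0.100).
for d_ct in (0.0, 1.0, 3.32, 10.0):
    print(f"dCt {d_ct:>5.2f} -> relative expression {relative_expression(20 + d_ct, 20.0):.4g}")

# proliferation: N_t / N_0 with N_0 the 3-hour attached-cell count
series = proliferation_ratios({3.0: 500, 48.0: 1000, 72.0: 1400, 96.0: 1750})
for t, ratio in zip(series.timepoints_h, series.ratios):
    print(f"N({t:>4.0f} h) / N(3 h) = {ratio:.2f}")

# cell major-axis length: median, central-50% box, central-98% whiskers
rng = np.random.default_rng(0)
lengths = rng.lognormal(mean=3.6, sigma=0.3, size=400)  # ~37 um median
s = mal_summary(lengths)
print(f"MAL (n={s.n}): median {s.median:.1f} um, "
      f"box [{s.box_low:.1f}, {s.box_high:.1f}], "
      f"whiskers [{s.whisker_low:.1f}, {s.whisker_high:.1f}]")
# A short MAL indicates an epithelial-like morphology, a long MAL a
# mesenchymal-like one.
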