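"""Shared constants: the fragment-size grid and published reference oscillation values.

Canine plasma cfDNA fragment sizes are analysed on the inclusive 1-bp grid
[74, 439] (366 sizes).  The reference peak/valley densities below are the
published cohort values for healthy ("normal") and hemangiosarcoma dogs:
eight oscillation cycles left of the mono-nucleosome main peak, with the
sub-peak positions 81..154 bp (~10.4 bp period).  They serve two purposes:

* worked-example inputs for the oscillation arithmetic (diff statistics,
  group means, cross-group gap ranking);
* anchors for the synthetic-cohort generator, whose sub-peak amplitudes are
  set from these printed densities rather than invented effect sizes.
"""

from __future__ import annotations

import numpy as np

#: inclusive fragment-size grid bounds (bp)
SIZE_MIN = 74
SIZE_MAX = 439
#: number of 1-bp sizes on the grid
GRID_LENGTH = SIZE_MAX - SIZE_MIN + 1  # 366

#: 5-bp display binning starts at 74; the last full bin starts at 434
BIN_WIDTH = 5

#: main (mono-nucleosome) peak positions, bp
MAIN_PEAK_NORMAL_BP = 165
MAIN_PEAK_TUMOR_BP = 160

#: short-fragment threshold used for the tumor-excess proportion, bp
SHORT_FRAGMENT_THRESHOLD_BP = 174

#: sub-peak (oscillation cycle) positions, bp, cycles 1..8
SUBPEAK_POSITIONS_BP = np.array([81, 91, 102, 112, 122, 133, 144, 154])

#: reference per-cycle peak densities (1-bp normalized density units)
REFERENCE_PEAKS = {
    "normal": np.array([0.0015, 0.0021, 0.0023, 0.0028, 0.0042, 0.0065, 0.0078, 0.0091]),
    "hemangiosarcoma": np.array([0.0029, 0.0042, 0.0046, 0.0054, 0.0089, 0.0139, 0.0164, 0.0156]),
}

#: reference per-cycle valley densities
REFERENCE_VALLEYS = {
    "normal": np.array([0.0010, 0.0014, 0.0018, 0.0022, 0.0029, 0.0048, 0.0071, 0.0086]),
    "hemangiosarcoma": np.array([0.0014, 0.0021, 0.0031, 0.0040, 0.0053, 0.0091, 0.0129, 0.0130]),
}

#: reference per-cycle diff statistics (peak - valley)
REFERENCE_DIFFS = {
    group: REFERENCE_PEAKS[group] - REFERENCE_VALLEYS[group]
    for group in ("normal", "hemangiosarcoma")
}

GROUP_LABELS = ("normal", "hemangiosarcoma")


def size_grid() -> np.ndarray:
    """The 1-bp fragment-size grid [74, 439] as an int array."""
    return np.arange(SIZE_MIN, SIZE_MAX + 1)
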