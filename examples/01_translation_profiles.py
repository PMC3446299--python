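"""Score a translational shift from four-pool polysome fractions.

Builds a control and a stress profile for one mRNA, computes the sum of
differences D, the weighted scores S, and the translation ratio R, and
applies the default calling cutoffs (D >= 30 or R outside [1/1.15, 1.15],
plus the co-directional pooled-fraction curation rule).
"""

import numpy as np

from polystress import (
    call_regulation,
    normalize_profiles,
    sum_of_differences,
    translation_ratio,
    weighted_score,
)

# raw pool abundances (free mRNA -> heavy polysomes)
control_raw = np.array([5.0, 5.0, 15.0, 25.0])
stress_raw = np.array([17.5, 17.5, 7.5, 7.5])

control, _ = normalize_profiles(control_raw)
stress, _ = normalize_profiles(stress_raw)
print("control profile (%):", control)
print("stress profile  (%):", stress)

D = sum_of_differences(stress, control)
S_c, S_s = weighted_score(control), weighted_score(stress)
R = translation_ratio(S_s, S_c)
print(f"D = {D:.1f} (0 = identical, 200 = disjoint profiles)")
print(f"S_control = {S_c:.1f}, S_stress = {S_s:.1f} (range 10-40)")
print(f"R = {R:.3f} (<1 = translational down-regulation)")

call = call_regulation("example_mRNA", D, R, control[None, :], stress[None, :])
print(f"call: {call.direction} (D cutoff passed: {call.passed_D_cutoff}, "
      f"R cutoff passed: {call.passed_R_cutoff})")
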