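"""Morphometry-based predictions and descriptive group statistics.

Computes the effective pinna diameter and the rigid-head maximal ITD from
caliper means, then shows the reporting helpers: group summaries
(mean +/- SE, range, N), the 3-SD outlier screen, and Welch's t-test.
"""

from voleabr import outlier_filter, summarize, welch_t
from voleabr.hrtf import MorphometrySet, effective_diameter, predict_max_itd

male = MorphometrySet(pinna_width_mm=10.7, pinna_length_mm=13.2,
                      inter_pinna_mm=15.3, sex="male")
female = MorphometrySet(pinna_width_mm=10.2, pinna_length_mm=13.0,
                        inter_pinna_mm=15.4, sex="female")
for m in (male, female):
    print(f"{m.sex}: effective diameter {m.effective_diameter_mm:.1f} mm, "
          f"predicted max ITD {predict_max_itd(m):.1f} us")

weights_male = [39.0, 42.5, 35.0, 41.0, 38.5, 44.0, 36.5, 40.0]
weights_female = [31.0, 33.5, 29.0, 32.0, 30.5, 34.0, 28.5, 31.5]
print("male weight:", summarize(weights_male))
print("female weight:", summarize(weights_female))

kept, removed = outlier_filter(weights_male + [80.0])
print("outlier screen removed:", removed)

t, df, p = welch_t(weights_male, weights_female)
print(f"Welch t = {t:.2f}, df = {df:.1f}, p = {p:.2g} "
      "(two-tailed; small p = the groups differ)")
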