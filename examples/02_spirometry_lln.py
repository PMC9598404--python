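"""Flagging spirometry values below the lower limit of normal (LLN).

The LLN is the 5th percentile of the LMS reference distribution
M·(1 + L·S·z)^(1/L) at z = -1.6449; an observed value strictly below it marks
an abnormally low parameter (for FEV1/FVC, an obstructive pattern).
"""

from opea import LLN_Z, LmsCoefficients, assess, lms_percentile

coef = LmsCoefficients(parameter="FEV1", sex="Female", L=0.9, M=3.2, S=0.13)

print(f"predicted (median) FEV1 : {lms_percentile(coef, 0.0):.3f} L")
print(f"LLN (5th percentile)    : {lms_percentile(coef, LLN_Z):.3f} L")

for observed in (3.2, 2.65, 2.5):
    a = assess(observed, coef)
    verdict = "below LLN (abnormal)" if a.below_lln else "normal (>= LLN)"
    print(f"observed {observed:.2f} L -> {verdict}")

print("\nA value exactly at the LLN counts as normal: the dichotomy is <LLN versus >=LLN.")
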