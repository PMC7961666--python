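"""Predict postoperative refraction for one eye with all four formulas.

The eye: axial length 23.5 mm, mean corneal radius 7.7 mm, preoperative
anterior chamber depth 3.1 mm, implanted power 21 D. Each formula uses
its own lens constant; the printed value is the spectacle-plane
spherical equivalent the formula expects ten weeks after surgery.
"""

from iolstack import predict_refraction, solve_iol_power

EYE = dict(al=23.5, r=7.7, acd=3.1)
CONSTANTS = {
    "srkt": {"A": 118.4},
    "holladay1": {"SF": 1.5},
    "hofferq": {"pACD": 5.0},
    "haigis": {"a0": -1.72, "a1": 0.277, "a2": 0.26},
}

for formula, consts in CONSTANTS.items():
    ref = predict_refraction(formula, EYE["al"], EYE["r"], EYE["acd"], 21.0, consts)
    print(f"{formula:10s} predicted refraction at 21 D: {ref:+.3f} D")

# invert the chain: which power hits a -0.25 D myopic target?
for formula, consts in CONSTANTS.items():
    power = solve_iol_power(formula, EYE["al"], EYE["r"], EYE["acd"], -0.25, consts)
    print(f"{formula:10s} power for a -0.25 D target: {power:.2f} D")

print(
    "\nNegative refraction = myopia. The formulas disagree because each "
    "assumes a different effective lens position model, and these example "
    "constants are nominal rather than personalized to a common cohort -- "
    "after per-cohort optimization the predictions align much more closely."
)
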