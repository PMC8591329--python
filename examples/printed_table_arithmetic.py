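"""Variance-corrected heritability from printed regression results.

Given a single parent–offspring regression slope and the variance-ratio F
statistic between the parent's and offspring's tactics, the corrected
heritability is h2 = 2 * b_op * (sigma_p / sigma_o) with
sigma_p/sigma_o = sqrt(F) (or 1/sqrt(F) when the parent tactic is the
less variable group).  The three cells below use slopes of -0.070, -0.045
and -0.051 with F = 0.415 (female:hooknose) and F = 2.77 (hooknose:jack),
giving h2 of -0.090, -0.150 and -0.061: intertactical heritabilities
indistinguishable from zero, i.e. no evolutionary constraint between
tactics.
"""

import math

from tactqg import heritability_from_slope

cells = [
    ("hooknose son ~ dam", -0.070, math.sqrt(0.415)),
    ("jack son ~ hooknose sire", -0.045, math.sqrt(2.77)),
    ("hooknose son ~ jack sire", -0.051, 1 / math.sqrt(2.77)),
]
for label, b_op, ratio in cells:
    est = heritability_from_slope(b_op, 0.0, sigma_p=ratio, sigma_o=1.0, corrected=True)
    print(f"{label:<26} b_op={b_op:+.3f}  sigma_p/sigma_o={ratio:.3f}  h2={est.h2:+.3f}")
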