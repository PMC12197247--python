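"""Reference per-method effect estimates and ensemble weights.

These are the printed per-method treatment-effect estimates and composite
weights from the published retrospective DVT cohort analysis this pipeline
models.  The underlying patient data are not public, so these numbers
serve as fixed *inputs* for exercising the weighted-aggregation layer
(e.g. recomputing every weighted-average row from the per-method values),
never as targets the estimation code is tuned toward.
"""

from __future__ import annotations

import pandas as pd

#: Composite ensemble weights by matching method (printed to 3 decimals).
REFERENCE_WEIGHTS: dict[str, float] = {
    "nearest_caliper": 0.362,
    "optimal_exact": 0.239,
    "genetic": 0.219,
    "mahalanobis": 0.180,
}

_ROWS = [
    # outcome, method, ate, att, atc, dr_effect
    ("los", "genetic", 0.220938, 0.138542, 0.303333, 0.234141),
    ("los", "mahalanobis", 0.030104, 0.069583, -0.009375, 0.060673),
    ("los", "nearest_caliper", 0.184853, 0.140294, 0.229412, 0.482037),
    ("los", "optimal_exact", 0.122396, 0.093542, 0.151250, -0.089078),
    ("ipr", "genetic", 7.250269, 7.126380, 7.374158, 6.657812),
    ("ipr", "mahalanobis", 9.498363, 10.104076, 8.892649, 7.468033),
    ("ipr", "nearest_caliper", 4.425388, 4.053835, 4.796941, 4.576757),
    ("ipr", "optimal_exact", 6.234179, 5.597047, 6.871312, 4.811417),
    ("cer", "genetic", 376.835863, 331.227682, 422.444043, 49.228880),
    ("cer", "mahalanobis", 234.975301, 219.382172, 250.568430, -31.334780),
    ("cer", "nearest_caliper", -382.278629, -558.997681, -205.559576, 17.847259),
    ("cer", "optimal_exact", 443.893589, 152.772527, 735.014650, 204.663569),
    ("dir", "genetic", 1.126066, 1.237232, 1.014900, 0.081863),
    ("dir", "mahalanobis", 1.040437, 0.868627, 1.212247, 0.054384),
    ("dir", "nearest_caliper", -0.510985, -0.746027, -0.275944, -0.546280),
    ("dir", "optimal_exact", 0.854262, 0.735216, 0.973309, 0.295889),
    ("dic", "genetic", -2223.558387, -3261.261570, -1185.855203, -2897.334079),
    ("dic", "mahalanobis", -2687.825196, -3521.714681, -1853.935712, -3658.028076),
    ("dic", "nearest_caliper", -4575.084249, -5472.104670, -3678.063828, -2258.112576),
    ("dic", "optimal_exact", -2914.259329, -3844.182311, -1984.336347, -3252.662104),
    ("cle", "genetic", 146.768519, 121.704870, 171.832168, 144.049049),
    ("cle", "mahalanobis", 145.561282, 123.163489, 167.959075, 159.493708),
    ("cle", "nearest_caliper", 83.567817, 92.234486, 74.901147, 117.317895),
    ("cle", "optimal_exact", 202.467521, 167.803752, 237.131289, 189.321178),
]

_WEIGHTED_ROWS = [
    # outcome, ate, att, atc, dr_effect (printed weighted-average rows)
    ("los", 0.149940, 0.115998, 0.183882, 0.215417),
    ("ipr", 6.390419, 6.185866, 6.594972, 5.609704),
    ("cer", 92.494279, -53.786728, 238.775285, 60.460884),
    ("dir", 0.453157, 0.333016, 0.573299, -0.099355),
    ("dic", -3323.379356, -4247.677021, -2399.081692, -2887.947738),
    ("cle", 136.974290, 122.308297, 151.640284, 147.968124),
]


def reference_estimates() -> pd.DataFrame:
    """Per-method reference estimates (outcome, method, ate, att, atc, dr_effect)."""
    return pd.DataFrame(_ROWS, columns=["outcome", "method", "ate", "att", "atc", "dr_effect"])


def reference_weighted_averages() -> pd.DataFrame:
    """Printed weighted-average rows (outcome, ate, att, atc, dr_effect)."""
    return pd.DataFrame(_WEIGHTED_ROWS, columns=["outcome", "ate", "att", "atc", "dr_effect"])
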