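"""Recalibrate the class thresholds from annotated nuclei.

A different scanner or stain batch shifts the DAB intensity scale, so the
three class boundaries (tau1, tau2, tau3) should be re-fit on a small
annotated set rather than copied.  Here we build a calibration table from
three synthetic tiles (mu value + true class per nucleus) and run the
exhaustive grid search.
"""

from dabquant import SyntheticSpec, calibrate_thresholds, generate_tile
from dabquant.calibration import CalibrationSet

pairs = []
for seed in (1, 2, 3):
    tile = generate_tile(SyntheticSpec(n_per_class=(8, 8, 8, 8), seed=seed))
    pairs.extend(zip(tile.mu, tile.classes))

cal = CalibrationSet(pairs=tuple(pairs))
thresholds, achieved = calibrate_thresholds(cal)  # macro-F1 objective
print(f"calibrated taus: {thresholds.as_tuple()}")
print(f"achieved macro-F1 on the calibration set: {achieved:.4f}")
# With well-separated synthetic classes the search reaches macro-F1 = 1.0
# and places each tau inside the empty gap between adjacent class bands
# (ties resolve to the lexicographically smallest grid triple).
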