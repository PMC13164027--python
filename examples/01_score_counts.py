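"""Allred-score a table of per-image nucleus counts.

The scoring rules need only the four class counts per ROI.  Here we score
the classic strongly-positive example (279 nuclei, 176 strong) plus an
all-negative and a low-positive ROI, and print the clinical read-out.
"""

import pandas as pd

from dabquant import score_batch

counts = pd.DataFrame(
    [
        {"image": "strongly_positive", "strong": 176, "moderate": 51, "weak": 33, "negative": 19},
        {"image": "all_negative", "strong": 0, "moderate": 0, "weak": 0, "negative": 148},
        {"image": "low_positive", "strong": 0, "moderate": 0, "weak": 1, "negative": 55},
    ]
)

summary = score_batch(counts)
print(summary.to_string(index=False))
# positive_pct is the percentage of DAB-positive nuclei; P bins it (0-5),
# I is the dominant staining intensity (0-3), Allred = P + I.  Totals of
# 0 or 2 read out as receptor-negative; 3-8 indicate endocrine therapy.
# Note the low-positive row: a single weak nucleus among 56 still gives
# Allred 3 ("positive") — the scoring system is deliberately sensitive.
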