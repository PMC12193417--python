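"""Published summary statistics from the motivating 46-population survey.

These are the printed per-trait and per-primer summary values from the
Ningxia paddy-field barnyard grass survey that motivates this package.  They
are *inputs* for validation — the raw 46-population data are unpublished, so
only these aggregates can be recomputed or checked against.
"""

from __future__ import annotations

import pandas as pd

#: Per-trait summary rows: Range, Max, Min, Mean, sample SD (S), CV (%) and
#: Shannon-Wiener H' over 10 trait levels, for traits M1..M9.
PUBLISHED_TRAIT_SUMMARY = pd.DataFrame(
    {
        "Range": [29.45, 1.40, 7.25, 2.00, 0.96, 0.18, 0.17, 0.62, 65.43],
        "Max": [47.50, 1.78, 13.35, 4.00, 0.96, 0.44, 0.50, 0.81, 104.40],
        "Min": [18.05, 0.38, 6.10, 2.00, 0.00, 0.26, 0.33, 0.19, 38.97],
        "Mean": [32.59, 1.06, 9.42, 2.89, 0.10, 0.35, 0.42, 0.43, 64.62],
        "S": [6.81, 0.26, 1.83, 0.56, 0.21, 0.04, 0.08, 0.14, 16.34],
        "CV": [20.91, 24.37, 19.40, 19.29, 221.91, 11.69, 20.00, 33.21, 25.29],
        "Hprime": [2.02, 1.79, 2.06, 1.96, 0.86, 1.84, 0.69, 2.03, 1.99],
    },
    index=[f"M{i}" for i in range(1, 10)],
)

#: Per-primer dominant-marker summary: polymorphic band counts, mean band
#: (allele) frequency and PIC for the six SCoT primers.
PUBLISHED_PRIMER_SUMMARY = pd.DataFrame(
    {
        "n_polymorphic": [11, 12, 7, 14, 10, 8],
        "mean_band_frequency": [0.64, 0.82, 0.69, 0.67, 0.72, 0.51],
        "PIC": [0.35, 0.25, 0.39, 0.35, 0.35, 0.37],
    },
    index=["SCoT06", "SCoT11", "SCoT12", "SCoT20", "SCoT29", "SCoT31"],
)

#: Total scored bands across the six primers (62 of which are polymorphic).
PUBLISHED_TOTAL_BANDS = 72

#: Band counts printed for individual primers: SCoT12 had the fewest bands,
#: SCoT20 the most.
PUBLISHED_BANDS_SCOT12 = 9
PUBLISHED_BANDS_SCOT20 = 15

#: Barcode locus amplicon lengths (bp) and number of variable sites found.
PUBLISHED_LOCUS_LENGTHS = {"ITS": 588, "psbA": 337, "matK": 1312, "trnL-F": 954}
PUBLISHED_VARIABLE_SITES = {"ITS": 5, "psbA": 2, "matK": 1, "trnL-F": 0}
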