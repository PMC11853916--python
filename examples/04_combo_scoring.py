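"""Score a sample against a biomarker panel.

The combination score for a panel of n taxa is

    S = sum_i 100 * W_i * (N_i - P_i) / (P_i + N_i)

with P_i and N_i the absolute distances of the sample's abundance from the
PI- and HI-group training medians and W_i the taxon's presence-frequency
enrichment in PI. S ranges over [-100*sum(W), +100*sum(W)]; positive means
the sample sits nearer the peri-implantitis profile.
"""

import numpy as np

from perimark import ComboScoreModel, combo_score

model = ComboScoreModel(
    taxa=("Taxon_A", "Taxon_B", "Taxon_C"),
    median_pi=np.array([2000.0, 50.0, 900.0]),  # ppm medians in the PI group
    median_hi=np.array([150.0, 400.0, 900.0]),  # ppm medians in the HI group
    weights=np.array([0.9, 0.7, 0.5]),
    threshold=0.0,
)

samples = {
    "PI-profile sample": {"Taxon_A": 2000.0, "Taxon_B": 50.0, "Taxon_C": 900.0},
    "HI-profile sample": {"Taxon_A": 150.0, "Taxon_B": 400.0, "Taxon_C": 900.0},
    "mixed sample": {"Taxon_A": 1200.0, "Taxon_B": 300.0, "Taxon_C": 10.0},
}
for name, sample in samples.items():
    s = combo_score(model, sample)
    call = "PI" if s > model.threshold else "HI"
    print(f"{name}: S = {s:+8.2f}  ->  predict {call}")
# Taxon_C has identical group medians, so it contributes 0 for a sample at
# that value: only taxa whose medians differ can move the score.
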