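"""Simulate a labeled peri-implant microbiome cohort.

Draws a biofilm-shaped cohort (40 healthy-implant, 20 peri-implantitis
samples over 1234 taxa), plants one differentially abundant taxon, and
prints the shape and the planted truth. Rows are ppm-normalized, so each
sample sums to one million.
"""

from perimark import PlantedMarker, SyntheticSpec, generate_cohort

spec = SyntheticSpec(  # biofilm-like: 40 HI / 20 PI
    planted_markers=[PlantedMarker(taxon_index=7, direction="up", multiplier=8.0)],
    seed=1,
)
table, labels = generate_cohort(spec)

print(f"cohort: {table.n_samples} samples x {table.n_taxa} taxa")
print(f"groups: {labels.n_group('HI')} HI / {labels.n_group('PI')} PI")
print(f"row sums (ppm): {table.data.sum(axis=1).iloc[0]:.1f}")
print(f"planted truth: {spec.planted_truth()['markers']}")

marker = table.data.iloc[:, 7]
pi_mean = marker[labels.labels == "PI"].mean()
hi_mean = marker[labels.labels == "HI"].mean()
print(f"planted taxon mean abundance: PI {pi_mean:.0f} ppm vs HI {hi_mean:.0f} ppm")
# The x8 up-shift should make the PI mean several-fold larger than the HI
# mean; downstream screening should flag exactly this kind of contrast.
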