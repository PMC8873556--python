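"""Characterize clusters statistically and summarize questionnaire severity.

Each (cluster, feature) cell is a one-sample t-test of the cluster members
against the whole-cohort mean, Bonferroni-corrected over the full table at
family-wise error 0.05.  +/- marks a significantly higher/lower cluster
mean; the number of symbols encodes adjusted p < 0.05 / 0.01 / 0.001.
"""

import numpy as np

from tapclust import (
    DEFAULT_BANDS,
    assemble_matrix,
    assign_band,
    band_percentages,
    characterize,
    direction_symbol,
    extract_cohort,
    generate_cohort,
    kmeans_restarts,
    minmax_normalize,
    rescale_subscale,
    summarize_scores,
)

cohort = generate_cohort(n_per=(150, 150, 150), seed=3)
vectors, ids = extract_cohort(cohort.sessions)
matrix, _ = assemble_matrix(vectors, ids)
scaled, _ = minmax_normalize(matrix)
labels = kmeans_restarts(scaled.to_numpy(), 3, n_init=200, seed=3).labels

table = characterize(matrix, labels)
table["symbol"] = [direction_symbol(d, m) for d, m in zip(table["direction"], table["markers"])]
print("cluster characterization (direction vs cohort baseline):")
print(table.pivot(index="feature", columns="cluster", values="symbol").to_string())

id_pos = {rid: i for i, rid in enumerate(ids)}
surveys = [cohort.surveys[id_pos[rid]] for rid in matrix.index]
print("\nquestionnaire scores per cluster (mean +/- SEM):")
summary = summarize_scores(surveys, labels)
print(summary.round(3).to_string(index=False))

print("\nseverity-band percentages (scores re-scaled to the full instruments):")
for scale, bands in DEFAULT_BANDS.items():
    raw = np.array([getattr(sv, scale) for sv in surveys], dtype=float)
    assigned = [assign_band(rescale_subscale(r, bands.max_subset, bands.max_full), bands) for r in raw]
    print(scale)
    print(band_percentages(assigned, labels).round(2).to_string(index=False))

# The cluster whose members tap slowest (plus on meanTapInter, minus on
# numberTaps) should carry the highest questionnaire means and the largest
# moderate/severe percentages.
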