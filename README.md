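# tapclust

Severity phenotyping of smartphone finger-tapping sessions for Parkinson's
disease research.

Bradykinesia — slowed, irregular movement — shows up directly in how a
person performs a 20-second alternating two-target tapping task on a phone
laid flat on a table. `tapclust` is a library for researchers working with
such tap-event streams (one record per screen tap: timestamp `t` in
seconds, position `(x, y)` in pixels) together with self-reported
questionnaires (an MDS-UPDRS Part I–II item subset, max 24 + 40 points,
and the PDQ-8 quality-of-life short form). It turns raw sessions into an
unsupervised severity phenotyping: tapping features → scaling → K-means →
cluster-count validity → statistical cluster characterization → severity
bands.

## The method

**Nine tapping features** per session. With `TapInter` the inter-tap
intervals `t_{k+1} − t_k`, and the tap positions split at the mean
x-coordinate into a left (`x < x̄`) and right (`x ≥ x̄`) set whose
within-side consecutive Euclidean gaps are `DriftLeft` / `DriftRight`:

| feature | definition |
|---|---|
| `corXY` | Pearson r between all tap x and y coordinates |
| `numberTaps` | taps completed in the 20-second window |
| `skewDriftRight`, `skewDriftLeft` | skewness `(Σ(xᵢ−μ)³/N) / s³`, `s = √(Σ(xᵢ−μ)²/N)` |
| `cvTapInter`, `cvDriftRight`, `cvDriftLeft` | coefficient of variation `σ/μ · 100` (population σ) |
| `meanTapInter`, `medianTapInter` | mean / median inter-tap interval (s) |

Features are min–max scaled per column, `x' = (x − x_min)/(x_max − x_min)`.

**Clustering.** Lloyd K-means under Euclidean distance, stopping when no
centroid moves, minimizing the sum of squared errors
`E = Σᵢ Σ_{j∈Cᵢ} ‖x_ij − uᵢ‖²`. Because a single random start can land in
a poor local minimum, 1000 independent Forgy starts are run and the
minimum-E solution kept, reproducibly from one seed.

**How many clusters?** Three criteria over a k range: the inertia elbow
(automated as the max-distance-to-chord knee), the mean silhouette
`s(i) = (b−a)/max(a,b)` (higher better), and the Davies–Bouldin index
`DB = (1/N) Σᵢ max_{j≠i} (Sᵢ+Sⱼ)/Mᵢⱼ` with RMS within-cluster dispersion
`Sᵢ` and centroid distance `Mᵢⱼ` (lower better).

**Characterization.** Each (cluster, feature) cell is a two-sided
one-sample t-test of the cluster members against the whole-cohort mean,
Bonferroni-corrected over the entire table (family-wise error 0.05);
significant cells print `+`/`−` with 1–3 symbols for adjusted
p < 0.05 / 0.01 / 0.001, otherwise `N.S.`. Questionnaire scores are
summarized per cluster as mean ± SEM, and — after linear re-scaling of the
item-subset scores onto the full instruments — tabulated as mild /
moderate / severe percentages with configurable cut-offs.

Because the study cohort sits behind governed access, the package ships a
**synthetic cohort generator**: a gamma renewal process for tap timing and
skew-controlled radial jitter around two screen anchors, in three severity
archetypes with correlated questionnaire scores, plus the adjusted Rand
index to measure cluster recovery against the planted strata.

## Worked example

```python
from tapclust import (adjusted_rand, assemble_matrix, extract_cohort,
                      generate_cohort, k_scan, kmeans_restarts, minmax_normalize)

cohort = generate_cohort(n_per=(150, 150, 150), seed=3)
vectors, ids = extract_cohort(cohort.sessions)
matrix, _ = assemble_matrix(vectors, ids)
scaled, _ = minmax_normalize(matrix)
report = k_scan(scaled.to_numpy(), range(2, 8), n_init=100, seed=3)
print(report.to_frame().round(4))
```

prints

```
 k  inertia  silhouette  davies_bouldin
 2 103.8228      0.6313          0.5729
 3  33.4036      0.6910          0.4751
 4  29.5171      0.5691          1.0086
 5  26.6470      0.3874          1.4882
 6  24.1144      0.3839          1.3768
 7  22.3046      0.3824          1.3255
```

The silhouette peaks and Davies–Bouldin bottoms out at k = 3 — the number
of planted archetypes — and the inertia knee agrees. Clustering at k = 3
then recovers the planted strata exactly:

```python
res = kmeans_restarts(scaled.to_numpy(), 3, n_init=200, seed=3)
adjusted_rand(cohort.true_labels, res.labels)   # -> 1.0
```

An ARI of 1.0 means the partition matches the generator's severity strata
up to relabeling. The scripts in `examples/` walk through each capability
(cohort generation, feature extraction, validity scan, characterization
and severity bands, full pipeline run); `examples/04_characterize_severity.py`
prints the per-cluster `+++`/`---`/`N.S.` direction table and the
questionnaire summaries whose means rise with the tapping-derived severity
ordering.

There is also a thin CLI mirroring the pipeline stages:

```bash
tapclust simulate --n-per 150,150,150 --seed 3 --out-dir sim/
tapclust run-all --config cfg.yaml
```

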