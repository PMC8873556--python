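# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical conventions, and the design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and ingestion

A *session* is one 20-second alternating two-target tapping task: ordered
events `(t, x, y)` with `t ≥ 0` seconds and pixel coordinates (origin
top-left). Events are sorted stably by time; duplicate timestamps are kept
(zero inter-tap intervals are legal). A *survey record* holds the
MDS-UPDRS Part I subset total (0–24), Part II subset total (0–40) and an
optional PDQ-8 total (0–32).

Surveys are paired with the same participant's session recorded closest in
time. Ties in time distance break toward the earlier session — a
deterministic, input-order-independent rule. Participants missing either
side are dropped. Only strict one-nearest pairing is implemented; sessions
are never averaged.

Sessions are screened before feature extraction: fewer than 4 taps total,
or fewer than 2 taps on either side of the mean-x split, is a rejection
(logged, not an exception). The thresholds are the minimal structure under
which all nine features are defined: intervals need ≥ 2 taps, each drift
series needs ≥ 2 points on its side. Coordinates are treated as raw
pixels with no device-resolution correction: the features that survive to
the matrix are correlations, dimensionless shape statistics, or interval
statistics, and the one place scale enters (drift dispersions) is
neutralized by the per-column min–max scaling.

## Features

Three base series per session: `TapInter` (consecutive timestamp
differences), and `DriftLeft`/`DriftRight` (Euclidean gaps between
consecutive tap positions *within* the left/right side, left being
`x < mean(x)`). "Consecutive" is read within the side's own time-ordered
sequence, i.e., a side's drift skips over taps on the other side.

Skewness and coefficient of variation use population (divide-by-N)
moments — `s = √(Σ(x−μ)²/N)` — consistently in both statistics; a
`ddof=1` switch exposes the sample variants for sensitivity checks, since
upstream tooling conventions differ. The even-length median is the mean of
the two central order statistics.

Degenerate inputs yield a missing flag (NaN): series shorter than 2,
zero dispersion (skewness), zero mean (CV), constant x or y (corXY).
The missing-value policy at matrix assembly is *drop the session*, with
the offending features logged; no imputation is attempted because the
downstream tests assume complete rows. Min–max scaling maps a constant
column to all zeros (documented convention) and records per-column
(min, max) so the transform is reusable.

## Clustering

Lloyd K-means with Euclidean assignment (ties to the lowest cluster
index), mean-centroid updates, and exact-equality convergence — the run
stops when no centroid moves at all. A safety cap of 300 iterations guards
pathological floating-point cycling; the per-iteration objective trace is
non-increasing by construction (each assignment and each mean update can
only lower the sum of squared errors), and the test suite asserts this on
a thousand randomized runs.

Initialization samples k distinct data rows (Forgy), which cannot produce
degenerate starts. If a cluster empties during assignment it is re-seeded
with the point currently farthest from its own centroid, stealing only
from clusters that keep at least one member; this repair also preserves
the monotone objective. 1000 restarts are run by default and the
minimum-objective solution kept (ties to the lowest restart index). Each
restart draws from its own child stream of one master `SeedSequence`, so
the selected solution is independent of execution order and fully
reproducible.

Clustering runs on the min–max-scaled matrix by default (scaling is
described as the step immediately preceding clustering); the raw-feature
route is available via `cluster_on="raw"`.

## Cluster-count validity

*Inertia/elbow*: the knee is automated as the k whose (k, E) point is
farthest (perpendicular distance) from the chord joining the first and
last points of the curve. On a near-linear curve all distances are ≈ 0 and
the returned knee is unreliable — it is a suggestion, never a hard-coded
choice.

*Silhouette*: `a(i)` is the mean distance to own-cluster co-members
(divide by |C|−1, the self-distance excluded); `b(i)` the minimum over
other clusters of the mean distance to that cluster. Two variants of the
`b(i)` denominator exist in the literature's formula transcriptions: the
standard mean (|C_k|) and a |C_k|−1 form. The default is "standard"; the
`as_printed` variant implements the |C_k|−1 form (falling back to a
divisor of 1 for a singleton other-cluster, where it would otherwise be
0), and a test demonstrates the two converge as cluster sizes grow.
Singleton-cluster points get s(i) = 0, the a = b limit.

*Davies–Bouldin*: within-cluster dispersion is the p-th root of the mean
p-th-power member-to-centroid distance (p = 2 default, i.e., RMS). Note
that common library implementations use the *mean* member-to-centroid
distance instead; the RMS form is implemented here as specified, it upper
bounds the mean form, and the two coincide exactly when all members are
equidistant from their centroid (the configuration the hand-check uses).
Coincident centroids make the index undefined and raise.

The pipeline's selection rule when a k range is scanned: k at maximum
silhouette, with the Davies–Bouldin minimizer and the inertia knee logged
beside it in the manifest. The final cluster count in a real analysis is a
judgement call informed by these metrics, so the rule is explicit and
overridable (`k=` fixes it).

## Characterization and severity summaries

For each (cluster, feature): a two-sided one-sample t-test of the cluster
members' *unscaled* feature values against the whole-cohort mean of that
feature. The cluster-vs-cohort mean comparison is scale-equivariant, so
unscaled values are used to keep units interpretable; a scaled run is a
one-line change. The t statistic uses the sample (N−1) standard deviation;
p comes from the t distribution with n−1 degrees of freedom. Zero
dispersion yields an undefined test reported as "no direction".

Bonferroni correction uses the most conservative natural family: all
clusters × all features in one table (27 cells for 3 × 9), with
`p_adj = min(1, m·p)` and family size recorded per row. Significance
markers (1/2/3 for p < 0.05/0.01/0.001) are read off the adjusted p by
default; a `marker_basis="raw"` flag exists for comparison. Direction is
the sign of (cluster mean − cohort mean) and is only reported when the
adjusted p clears the family-wise error level (0.05).

Score summaries are mean ± SEM (sample sd / √n) per cluster for Part I,
Part II, their total, and PDQ-8 — the last over the subset of participants
who completed it. Severity banding first re-scales the item-subset scores
linearly onto the full instruments (`raw · max_full / max_subset`; the
exact re-scaling used upstream is not published, so linear proportionality
is an explicit assumption recorded in the config). Band cut-offs and
full-scale maxima are configuration with documented defaults (Part I: full
max 52, mild ≤ 10 < moderate ≤ 21 < severe; Part II: full max 52,
mild ≤ 12 < moderate ≤ 29 < severe, following the published
percentile/ROC/ordinal-regression triangulation approach for MDS-UPDRS
subscales); boundaries belong to the lower band.

PCA for the 2-d cluster map: columns centered, components from the SVD,
explained percentage as each component's share of total variance, and each
component's sign fixed so its largest-magnitude loading is positive —
plots are then reproducible across runs and BLAS builds.

## Synthetic cohort

The generator exists so the pipeline is exercisable and testable end to
end without the governed study data. It is a test harness, not a
physiological model of bradykinesia.

Per archetype: inter-tap intervals are a gamma renewal process matched to
a mean interval and CV (gamma: positive support, mean and CV directly
parameterizable), accumulated from t = 0 and truncated at the 20-second
window. Taps alternate between two fixed anchors 200 px apart; each tap is
displaced by a random radius in a uniform direction. The radius
distribution controls the drift-skew direction: gamma shape 1.5 for
positive skew, shape 20 (near-symmetric) for none, and the shape-1.5 draw
reflected about its mean (clipped at 0) for negative skew. A linear tilt
term `y += tilt · (x − x̄_anchors)` induces the target x–y correlation.
Survey scores are normal around archetype means, clipped to the scale
range and rounded to integers.

Default archetypes (low / mid / high severity): mean interval 0.32 / 0.29
/ 0.75 s, interval CV 22 / 45 / 14 %, jitter sd 12 / 18 / 26 px, tilt 0 /
0.28 / 0.5, and survey means set to the published per-cluster
questionnaire means so smoke-test summaries have a recognizable shape
(presets, not ground truth). Default stratum sizes mirror the published
cluster sizes 594/897/360. These defaults plant the severity signature the
characterization should recover — high: slower taps (plus on
mean/medianTapInter, minus on numberTaps), strong x–y coupling (plus
corXY), regular timing (minus cvTapInter); low: negligible coupling and
fast taps; mid: fast but erratic timing. Only effects of this size are
listed in `PLANTED_DIRECTIONS` and asserted; the drift-skew directions are
planted qualitatively but their effect through the radius→drift mapping is
weaker, so they are not part of the guaranteed-recovery set.

What the generator does *not* emulate: device heterogeneity (screen
resolution, sampling jitter), missed or off-target taps, accelerometer
context, within-person longitudinal correlation, or any validated
relationship between tapping and questionnaire scores — the score/feature
coupling is purely by archetype membership. Passing recovery tests
therefore shows the pipeline detects structure of the planted kind at the
planted magnitude; it does not validate the clinical claim on real data.

The `separation` dial interpolates every numeric archetype parameter
toward the across-archetype mean: 1 = defaults, 0 = identical archetypes
(a null cohort; the categorical skew directions collapse to "zero"). The
null setting drives the type-I calibration and the ARI ≈ 0 checks.

## Problem sizes and numerical conventions

The acceptance-style checks run at sizes chosen to exercise the same
structure as the full study at desk scale: 300 sessions per archetype for
recovery and characterization checks, 100 null replicates of 60 sessions
for the separation-zero ARI, 200 null replicates for type-I calibration,
and k-scans with 50–100 restarts per k (the restart count only needs to
locate the global optimum reliably at these n; the 1000-restart default
remains for library use). `scripts/acceptance.py` uses strata of
198/299/120 — one third of the study's cluster sizes.

Floating-point conventions: exact-equality centroid convergence plus the
300-iteration cap; assignment ties to the lowest cluster index; restart
objective ties to the lowest restart index; min–max constant columns to 0;
silhouette of singletons 0. Determinism everywhere flows from a single
seed through `numpy.random.SeedSequence` child streams, so results do not
depend on execution order. Pipeline outputs are byte-reproducible for a
fixed config; the plain-text log records wall-clock timings and is the one
file excluded from that guarantee.

## Known limitations

- The severity cut-offs and full-scale maxima are configuration defaults,
  not validated clinimetric choices; real analyses should set them from
  the applicable reference.
- The |C_k|−1 silhouette variant's singleton fallback (divisor 1) is a
  convention with no literature anchor; use the standard variant unless
  comparing against the alternative transcription.
- The knee detector is geometric and unreliable on near-linear inertia
  curves; treat it as a suggestion.
- One-nearest survey-session pairing ignores repeated sessions entirely;
  if repeated measures matter, aggregate upstream.
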