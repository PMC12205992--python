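# Methods

This note records the models, conventions, and design choices behind
`rsslearn`, in the order data flows through the package.

## Sequence model and encoding

A library is the Cartesian product of per-position alphabets over named
RSS positions (H4–H7, S1–S2, optionally N1–N3, N8–N9). Sequences are
handled top-strand, 5'→3'; no reverse-complement normalization is applied
on ingest. Enumeration order is deterministic (lexicographic, A<C<G<T),
and position labels are symbolic rather than integer offsets.

One-hot encoding expands each position into a 4-bit block. The block
order is **A, T, G, C**, matching the `H4_A/H4_T/H4_G/H4_C` feature
naming convention used throughout; the choice is arbitrary but fixed for
reproducibility, and decode∘encode is the identity. The full 15-code
IUPAC table is supported for motif matching because the reduced-category
analyses need codes beyond N and K (D, R, Y, W, S, M).

## Read-count tables

Variants that never recombine are absent from raw tables; completion
reinserts them with count 0 so the whole library is represented (one row
per variant per replicate; idempotent). Replicate averaging takes the
arithmetic mean per variant and precedes normalization for multi-library
datasets; single-library replicates are normalized independently.

Min–max normalization maps counts to [0, 1] either dataset-wide or per
nonamer group. A constant group is mapped to all-zero targets with a
logged warning — the "no detectable recombination" reading of a flat
group. Normalization is monotone, so ranks are preserved within groups.

Composition summaries (fractions at/above a read threshold, below it, and
at zero) are rounded half-away-from-zero to the nearest percent.

## Stratified rotation cross-validation

Targets are binned into a dedicated zero bin plus (by default) 10
quantile bins over the nonzero values; bins smaller than k are merged
downward. `StratifiedKFold` over the bin labels yields k=20 folds sharing
the dataset's asymmetric shape. Rotation r uses fold r as test and fold
r+1 (mod k) as validation, so each fold serves exactly once as validation
and once as test across the k rotations. Two-sample Kolmogorov–Smirnov
checks of each role subset against the complete dataset give p-values
near 1 when stratification succeeds.

## Regression network

The regressor is a small dense network written directly on numpy:
24 (or 44) inputs → 64 → 32 → 1, rectified-linear hidden units, linear
output, mean-squared-error loss, Adam (lr 1e-3, batch 64), inverted
dropout 0.2 on hidden activations, at most 100 epochs, and early stopping
that monitors validation MSE with patience 10 and restores the
best-validation weights. Weight initialization (He), batch shuffling, and
dropout masks all derive from one seed, so training is bit-reproducible.
Outputs are not clipped to [0, 1]; metrics are computed on raw outputs.
All hyperparameters are surface-level estimator parameters and are
serialized with every saved model.

FVAF = 1 − MSE/Var(obs) equals the coefficient of determination on a
fixed evaluation set: 1 for a perfect predictor, exactly 0 for the mean
predictor, unbounded below. Spearman correlations use average ranks for
ties (many tied zero targets). FVAF is undefined (an error) on
zero-variance observations.

## Permutation-Shapley attributions

The explainer introduces a sample's features one at a time, in random
order, into a background expectation and credits each feature with the
marginal change in mean prediction; averaging over permutations (each
also replayed reversed — antithetic pairs) estimates the Shapley value.
Because each walk telescopes from the background mean to the model's
prediction, **additivity is exact for any permutation count**; sampling
only affects how credit is split among features. For a linear model the
estimate equals the closed form wᵢ(xᵢ − E[background xᵢ]) exactly, which
the tests use as an independent oracle. The default background is the
training encoding (or a seeded subsample); the additivity tolerance
(1e-4) is asserted on every row and can only fail on an implementation
bug.

## Cooperative relationship vectors

For an ordered feature pair, samples are partitioned by the pair's binary
encodings; same-position (1,1) modes are structurally empty under one-hot
encoding and are never emitted, while other degenerate modes (n < 2 or
all-identical points) are retained with length 0 so combinatorial
bookkeeping stays exact.

Per mode: the slope is the direction of PC1 of the mean-centred points
(eigen-decomposition of the 2×2 covariance); X₉₉ and Y₉₉ are 99th
percentiles (linear interpolation between order statistics) of the
absolute attributions, making the length √(X₉₉²+Y₉₉²) robust to
outliers. Because the percentile components are nonnegative, they alone
cannot select a quadrant; the package assigns each component the sign of
the mode's centroid coordinate (zero treated as +) before the
four-quadrant inverse tangent. This is the package's reconciliation of
robust lengths with four-quadrant angles; it reproduces the intended
semantics (Q1 positive cooperativity, Q3 negative, Q2/Q4 antagonism,
axis-proximal vectors dominated by one feature). Vectors within ±10° of
an axis (configurable) are additionally tagged axis-dominated.

Swapping the pair (and transposing the combo) provably preserves length
and reflects the angle across the 45°–225° diagonal; the tests check
this exhaustively. Note that with interpolated percentiles the length is
exactly invariant to point order but only asymptotically invariant to
duplicating the point set.

Cumulative curves accumulate CRV lengths as the angle sweeps
counterclockwise from 225°; they are nondecreasing and end at the group's
total length. For covariation grouping, each curve is divided by its
final value (shape, not scale, defines covariation), distance is the
maximum absolute difference between curves on the union grid, and
single-linkage clustering at a configurable threshold (default 0.15)
merges the four nucleotides of a position into IUPAC categories.

## Melting-temperature analysis

Duplex Tm of the 6-bp H4–S2 window uses the nearest-neighbor model with
the unified DNA parameter set and the Tm module's documented defaults
(50 mM Na⁺, 25 nM each strand, entropic salt correction); an independent
hand-summed ΔH/ΔS oracle in the tests reproduces it to <0.1 °C. Each of
the 256 4-mers is placed at offsets −1 (H4–H7), 0 (H5–S1), +1 (H6–S2);
each motif matches exactly 16 library sequences, and an ordinary least
squares regression of log₁₀(prediction) on Tm is fit per (4-mer,
alignment), 768 in all. Predictions ≤ 0 are excluded from log-space
analyses with the exclusion count reported; the log base is 10. For the
+1 alignment the flag `has_G_at_H6_aligned` marks 4-mers with G at the
H6-aligned offset, the implementable criterion for the high-Tm-dependence
subset.

## Effect maps and external scores

The effect of mutating base a→b at a position is the difference of mean
scores between the two complete matched sets (1024 sequences each on the
4096 library), marginalizing the other positions uniformly; maps are
antisymmetric with zero diagonal. Reduced-category maps pool member
sequences (pooled means, weighting every sequence equally) over a
partition of {A,T,G,C} such as the CRV groupings. External scores (e.g.
RIC, whose published functional range for 12-RSSs is −38.81 to 0) enter
only as precomputed two-column tables; correlation supports an optional
log₁₀ transform on one side, and striation sampling slices the scatter at
chosen x-centers (default half-width 0.25 score units) and reports
per-slice extremes, ranges, and a position-frequency matrix.

## Nonamer-informed analysis

The multi-library design randomizes H4–H7 fully, holds S1 constant, and
restricts S2 to T/G, 512 variants per nonamer group. The combined
encoding is the 24-bit H4–S2 block (the constant S1 block carries no
information but keeps the feature space a superset of the single-library
model) plus a 20-bit block for N1–N3, N8, N9 — 44 features.

Per-group attributions are rescaled by the group's global mean
|attribution| over H4–S2 features, turning values into fold changes from
the group mean (the rescaled global mean is exactly 1; rescaling is
idempotent and removes any multiplicative group scale). Two-sample KS
statistics per feature and group pair, thresholded at 0.20, flag
candidate long-distance heptamer–nonamer interactions.

**Paired attribution design.** Cross-group KS comparison uses
`per_group_attributions`: every group is explained against backgrounds
drawn at the *same* library positions (with that group's nonamer bits)
and with the same permutation draws. Without pairing, the tight
attribution modes shift with the background sample and the KS statistic
reads sampling noise as signal (KS ≈ 0.4 for groups differing only by
scale). With pairing and an exact predictor, scale-only groups give KS ≈
0 and a planted group-specific effect is flagged with exactly the pairs
involving the altered group. Through a *trained* network, per-group fit
error still contributes KS ≈ 0.3–0.6 under a scale-only null at 512
variants per group — so recovery-style checks of this analysis run on
the generator's exact predictor (`TruthPredictor`), isolating the
analysis machinery from network estimation error, while the trained-model
route remains available in the pipeline.

## Synthetic data generator

The generator emulates the assay's defining features with exact,
serializable ground truth:

* **Landscape** — additive effects per binary feature, drawn N(0, 1.6)
  and centred within each position block (sum-zero, for identifiability);
  optional cross-position pairwise terms (within-position terms are
  rejected as unidentifiable); optional per-group multiplicative nonamer
  scales and group-specific feature effects (planted long-distance
  interactions). The default link is a logistic on the latent score
  (intercept −4.5), keeping efficiencies in [0, 1] and right-skewed; an
  identity link (clipped) exists for constructions needing exact
  additivity on the efficiency scale.
* **Observation layer** — counts are negative binomial with mean
  depth × efficiency (default depth 400, dispersion 6) plus zero
  inflation representing the assay's detection limit: the structural-zero
  probability is proportional to each variant's own NB zero probability,
  with the constant solved by bisection so the expected zero fraction
  hits the configured target (default 43%). Concentrating structural
  zeros on low-efficiency variants matters: uniform dropout would make
  high-efficiency variants randomly unobservable and cap attainable FVAF
  near 0.6, contradicting the data quality the conditions emulate.
* **Defaults as study conditions** — at the defaults one simulated
  library shows ≈36/21/43% composition at the 10-read threshold and a
  trained network reaches FVAF ≈ 0.76–0.84 across splits, the regime the
  package is designed for. These were chosen once, as the emulated
  conditions, and are not tuning knobs of the tests.
* **What it does not emulate** — PCR/amplification bias,
  sequence-context-dependent noise, replicate batch effects, and any
  Tm–efficiency coupling. Consequently, passing tests demonstrate that
  the pipeline recovers what was planted under realistic count noise,
  not that any particular biological claim holds on real data; and
  Tm-sweep checks use an exactly log-linear construction to validate the
  machinery rather than asserting a biological Tm dependence.

Planted-interaction recovery experiments use interaction-only truths
(additive effects zeroed): the quadrant of a pair's (1,1) CRV reflects
the *total* contribution signs of the two features, so random main
effects of magnitude comparable to the interaction would scramble the
quadrant irrespective of the pipeline's correctness.

## Numerical conventions

Angles in degrees ([0°, 360°)), temperatures in °C, tables as TSV,
metadata as JSON. All randomized operations take explicit seeds; a
pipeline run serializes its full configuration and a content-hash
manifest. Degenerate inputs (empty samples, constant targets, constant
groups, zero-variance observations) raise informative errors or produce
documented sentinel outputs as described above.

## Known limitations

* Real assay datasets are not bundled; analyses that in the source
  experiments ran on deposited tables run here on the synthetic
  conditions.
* The KS-based long-distance screen is a candidate detector, not a
  quantification of interaction strength, and through a trained network
  its null is inflated by estimation error (see the paired design above).
* The network is intentionally small and CPU-bound; no convolutional or
  recurrent variants, and hyperparameter search is grid-over-configs
  only.
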