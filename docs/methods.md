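# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `smmsubtypes`.

## Data model

The unit of analysis is a binary patients × features **alteration matrix**:
entry (p, f) = 1 iff patient p carries at least one call for feature f.
Features are driver SNVs, arm/focal CNAs, IgH/MYC translocations, and
summative ploidy flags (hyperdiploid ⇔ more than 48 chromosomes,
hypodiploid ⇔ fewer than 45; the two are mutually exclusive by
construction). There is no missing state inside the matrix: missing calls
are resolved to 0 at construction time with a logged count, and all-zero
patients are kept and flagged rather than dropped, so the cohort size n is
never silently changed. Patients are rows internally and in all emitted
files (heat-map figures elsewhere often draw patients as columns; the I/O
here is explicit about orientation).

## Binary matrix factorization

BMF approximates X (n × m, binary) by binary W (n × K) and H (K × m). The
solver is a **penalty method**: continuous non-negative factors are
optimized by multiplicative updates on

    f(W, H) = ‖X − WH‖²_F + λ(‖W∘W − W‖²_F + ‖H∘H − H‖²_F)

with the binariness weight λ rising on a fixed schedule (0.1, ×10 every 50
iterations, capped at 10⁴; 500 iterations total; relative-change tolerance
1e−6 ends a constant-λ phase early). The update rules split the penalty
gradient into positive and negative parts,

    W ← W ∘ (XHᵀ + 3λW²) / (WHHᵀ + 2λW³ + λW),

and symmetrically for H; denominators are clamped at 1e−12. Factors are
initialized i.i.d. Uniform(0.1, 0.9) from the seeded generator (strictly
positive, as multiplicative updates require), making every run
bit-reproducible from its seed. Within each constant-λ phase the continuous
objective is non-increasing; the test suite asserts this per iteration at
1e−9 relative tolerance.

After the schedule, factors are thresholded at 0.5 and the reconstruction
re-binarized as (WH ≥ 0.5), so the reported **residual** is the integer
Hamming count of mismatched cells — directly comparable with an exhaustive
enumeration oracle on tiny matrices. Two deliberate additions to the plain
penalty method:

- **Greedy bit-flip polish.** The thresholded factors are refined by the
  best residual-reducing flip per W row and per H column per sweep, until no
  single flip improves the Hamming residual. Row flips of W are mutually
  independent (each touches one reconstruction row), as are column flips of
  H, so batching is exact; each sweep strictly decreases the residual, which
  guarantees termination. Without this step the continuous relaxation
  plateaus above the discrete optimum on small unstructured matrices; with
  it, best-of-20 restarts matches brute-force search on every 3×4 … 4×5
  instance we enumerate.
- **Loading calibration.** At the λ cap the continuous W is forced to
  near-binary values, which makes argmax cluster assignment brittle for
  patients with weak signatures. The result therefore also carries
  calibrated continuous loadings: W refit against the final dictionary by 30
  penalty-free least-squares multiplicative updates (H fixed). Cluster
  assignment takes the argmax of these loadings (ties to the lowest index);
  all-zero loading rows fall back to the nearest H row in Hamming distance
  and are flagged.

## Consensus subtyping and K selection

A consensus run fits BMF `n_runs` times (default 100) with seeds spawned
from a master seed, labels each patient per run, and records the fraction of
runs in which each patient pair is co-assigned. The consensus matrix is cut
by agglomerative clustering (Euclidean distance, Ward linkage) into K
clusters, and cluster ids are canonicalized by decreasing size so labels are
stable across equivalent runs. Consensus is built from full-cohort random
restarts; downsampling is reserved for the K diagnostics, where it probes
stability against cohort size.

Per K the diagnostics record: the silhouette of the consensus-cut labels on
**Dice dissimilarities of the raw binary profiles** (1 − 2|a∧b|/(|a|+|b|),
defined as 0 for two empty profiles); the mean and best factorization
residual and variance explained (1 − residual/‖X‖²); and the generalized
Kullback–Leibler divergence Σ[x·log(x/y) − x + y] of the best-residual
run's *continuous* reconstruction (0·log 0 := 0, y clamped at 1e−12 —
K-L on a binarized reconstruction would be degenerate at log 0).

The default selection rule: among K whose mean silhouette is at least 90% of
the maximum over the range, pick the K with the largest decrease in mean K-L
from K−1 — the elbow where one more component stops buying reconstruction
quality while cohesion is still high. The full diagnostic table is emitted
so users can override. On planted four-subtype cohorts (n = 200) the rule
recovers K = 4 in 10/10 seeds; the number of consensus runs, downsample
counts and the tie-break are package choices, documented here, not claims
about any external dataset.

## Cluster enrichment

For every (cluster, feature) pair the 2×2 table (in-cluster carriers a /
non-carriers b, out-of-cluster carriers c / non-carriers d) is tested with a
one-sided (greater) Fisher exact test: p = P(X ≥ a) for X hypergeometric.
Only positive association is tested, because the readout is each cluster's
landmark alterations. Benjamini–Hochberg adjustment is applied **within
each cluster across features** by default (matching a per-cluster ranked
readout); a `global` family over all pairs is available since the choice of
family is genuinely open. A feature is called enriched at q < 0.1. Odds
ratios are cross-products with a Haldane–Anscombe 0.5 correction when any
cell is zero — display only; p-values always use the exact counts.

## Subtype classifier

A random forest (scikit-learn) on the features present in both cohorts'
catalogs and carried by ≥3 patients of the training cohort. Training runs a
randomized search (default 50 draws) over tree count {100, 200, 300}, depth
{None, 5, 10, 20}, features-per-split {sqrt, 0.3, 0.5} and minimum leaf
size {1, 2, 4}, scored by stratified 5-fold CV accuracy, then refits the
best configuration on all data; everything is seeded. The grid is a package
decision — forests on ~40 binary features are insensitive to fine tuning,
so a modest grid keeps the search honest without burning compute.
Prediction requires every model feature (strict) or zero-fills missing
columns with a logged warning (opt-in); tie-breaks go to the lowest class
index. The label-shuffle control in the test suite confirms CV accuracy
collapses to the majority-class rate on permuted labels (no leakage).

## Clinical outcomes

- **20-2-20 stage**: strict inequalities exactly as defined (M-protein
  >2 g/dL, FLC ratio >20, BMPC >20%); 0/1/≥2 factors → low/intermediate/
  high; any missing input → stage "missing". Boundary values do not count.
- **Evolving biomarkers**: evaluated on all readings at months in (0, 12]
  against the month-0 baseline (an exactly-12-month reading counts). eMP
  needs both a ≥25% relative and a ≥0.5 g/dL absolute rise; eHb needs a
  ≥0.5 g/dL drop. A zero M-protein baseline falls back to the absolute rule
  with a warning.
- **Survival**: Kaplan–Meier with Greenwood 95% intervals (lifelines);
  median = smallest t with S(t) ≤ 0.5, undefined (∞) when the curve never
  reaches 0.5; median follow-up by reverse KM (event indicators flipped).
  Log-rank over pooled event times with (groups − 1) df. Cox partial
  likelihood with Efron tie handling (the standard modern default); constant
  covariates are rejected and separation warnings surfaced. Nested models
  are compared by the likelihood ratio 2·(ℓ_ext − ℓ_base) with df = the
  parameter difference, alongside both models' Harrell C.
- **Harrell's C**: usable pairs are distinct-time pairs whose earlier time
  is an event; tied scores contribute 0.5. The 95% CI is a Noether-type
  normal approximation, se = √(C(1−C)/n_pairs), clipped to [0, 1] — chosen
  because it is transparent and cheap; a bootstrap would be more accurate in
  small samples.
- **Evolving-marker association**: 2×2 cross-product odds ratio of flag vs
  high-risk group (Haldane correction, Woolf logit CI, two-sided Fisher p)
  by default, with a logistic-regression alternative, since either could
  legitimately produce a published odds ratio.

Patients with missing staging inputs are excluded from multivariate models
with a logged count.

## Synthetic cohorts: what they emulate, and what they do not

Defaults are the study conditions the pipeline is designed around: n = 214
patients, six subtypes in equal mixing proportions, a ~42-feature catalog
(5 translocations, a summative hyperdiploidy flag, 20 SNVs, 16 arm-level
CNAs), signature features at rate 0.7 inside their subtype against a 0.05
background, per-subtype hyperdiploidy rates (0.9 for the HL analogs, 0.69
for the HL2 analog, 0.1 for the TL analogs), exponential time to
progression with medians 2.6 / 5.2 / 11 years for high (HL2, TL1, HL3) /
intermediate (HL1, HL4) / low (TL2) risk, ~34% censoring, and eMP/eHb odds
multipliers of 9.4 / 5.3 in high-risk patients over a 5% base rate. Subtype
signature sets mirror each analog's landmark alterations (e.g. the TL2
analog: t(11;14), CCND1, 11q gain) so tests read like the biology.

Mechanistic choices, each made once:

- **Exponential event times** (one parameter per risk group) rather than
  Weibull: only group medians are specified, so a single-parameter family
  is the honest choice; rate = ln 2 / median.
- **Censoring** is independent uniform administrative censoring on
  [0, T_max], with T_max solved numerically (Brent) so the expected
  censored fraction under the exponential mixture matches the configured
  rate — the observed 34% non-progressor fraction constrains the amount,
  not the mechanism.
- **Per-patient counter-derived sub-seeds** (master seed + stream id +
  patient index): reproducibility is independent of patient order and of
  which operations are invoked.
- **Clinical baselines**: M-protein is log-normal (σ = 0.5) with median
  ≈1.4 g/dL, shifted down for the low-risk analog (those tumors present
  with lower M-protein) and mildly up for high-risk patients; FLC ratio
  log-normal, BMPC clipped normal, both mildly elevated in high-risk
  patients. This gives the 20-2-20 stage real but incomplete prognostic
  signal, so a combined clinical+genetic model has something to add — the
  regime the outcome layer is meant to demonstrate.
- **Evolving series** are constructed to satisfy or violate the eMP/eHb
  rules by margin-aware design (designated patients overshoot both
  thresholds by 30%, non-designated stay strictly below with jitter bounded
  inside the slack), so designation and detection agree by construction.

Features are **conditionally independent given the subtype**; real cohorts
show co-occurrence beyond subtype membership, clonal structure, and
measurement noise in CNA/translocation calls, none of which is simulated.
Passing the planted-recovery tests therefore shows the pipeline recovers
block-Bernoulli structure at realistic sparsity and size — not that it
resolves every real-world ambiguity. Under the default conditions the
Bayes-optimal assignment itself mislabels 2–3% of patients (ARI ceiling
0.92–0.98 across seeds), which is the right mental benchmark for the
observed consensus ARIs of 0.88–0.96.

## Problem sizes in the checked-in tests

The test suite and acceptance script size their simulations to what the
properties need: exhaustive Fisher oracles to table totals of 40; BMF
brute-force comparisons up to 4×5 at K = 2; ten master seeds at n = 214
with 100 consensus runs for subtype recovery; ten seeds at n = 200 for K
selection; n = 2000 per group for survival-parameter recovery; n = 5000 for
binomial calibration checks; 200–1000 replicates for coverage and type-I
error. These sizes give the statistical assertions comfortable power while
keeping a full run in the minutes range.

## Known limitations

- Boolean (OR-semantics) and probabilistic/Bayesian BMF variants are out of
  scope; the penalty method with polish is a local optimizer, and on
  adversarial inputs the global binary optimum may require more restarts.
- The consensus layer assumes a fixed K per run; soft or overlapping
  subtype membership is not modeled (though the continuous loadings are
  exposed).
- Time-varying covariates, competing risks and interval censoring are not
  implemented in the outcome layer.
- The classifier transfers subtypes; it does not re-derive them, calibrate
  probabilities, or handle cohorts with systematically different feature
  definitions beyond the shared-feature intersection rule.
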