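# Methods

## Model and procedure

`painconn` treats each chronic-pain patient as a single observation to be
compared against a normative cohort of healthy controls, edge by edge, over
a 76 × 116 seed-to-atlas functional-connectivity matrix.

**Connectivity.** An edge value is the sample Pearson correlation between a
pain-seed signal and an AAL-ROI signal. Testing is done by default on the
Fisher-z scale (z = atanh r, r clipped to ±(1 − 1e−7)), which roughly
stabilizes the sampling variance of correlations; the raw `pearson_r` scale
is available and the choice is recorded in the run manifest. In image mode,
an atlas ROI's signal is the unweighted mean over its labeled voxels and a
seed's signal is the unweighted mean over in-grid voxels within a sphere
around its MNI coordinate. The sphere radius is a configuration knob
(default 6 mm, a common seed-analysis convention); point-coordinate seeds
require *some* neighborhood definition, and making it explicit keeps image
runs reproducible. NaN timepoints are rejected rather than imputed, and
discarding initial volumes is left to preprocessing (a
`drop_initial_volumes` option, default 0, exists for parity with pipelines
that drop dummy scans).

**Permutation test.** For one patient and one edge, with control values
x₁…xₙ and patient value y, the statistic is d = |mean(x) − y|. The null
re-assigns which of the n + 1 pooled values plays "patient" while keeping
group sizes n/1, so exactly n + 1 distinct relabelings exist; d for
assignment i is |S − (n+1)·pᵢ|/n with S the pooled sum. `exact` mode
enumerates all n + 1 assignments; `monte_carlo` mode draws `n_perm`
assignments uniformly with a seeded generator. Ties count as "as large as
or larger" (≥ with exact floating comparison), so the true labeling always
contributes and the exact p lies on the grid {1/(n+1), …, 1}. The
Monte-Carlo p-value uses the add-one rule (1 + hits)/(1 + n_perm) by
default — standard permutation practice that avoids p = 0 — with the raw
proportion available; exact mode always reports the true proportion.

**Multiplicity.** Benjamini–Hochberg step-up FDR correction is applied per
patient across that patient's 8,816 edges (the one-patient-at-a-time
framing makes the patient the natural correction family). `fdr_bh` wraps
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`; the test
suite checks it against a brute-force step-up oracle.

**The per-edge resolution limit and the pooled null.** With n = 20 controls
the per-edge null has only 21 outcomes and the smallest achievable p is
1/21 ≈ 0.0476. BH across 8,816 edges then rejects only in near-degenerate
configurations (essentially all edges would have to sit at the floor), so
the per-edge test as described is valid but extremely conservative — the
calibration experiment measures a flagged proportion of ~0 on null
cohorts. For runs that need per-edge discoveries, the module offers an
explicitly requested variant, `null_model="pooled_edges"`, which pools the
relabeling statistics of all of the patient's edges into one shared null,
giving p-value resolution ~1/(8,816 × 21). Pooling assumes edges share a
common null scale — reasonable on the variance-stabilized Fisher-z scale,
and the reason `fisher_z` is the default. The default remains `per_edge`;
the acceptance script's injected-effect run requests the pooled variant so
the significance filter is actually exercised.

**Aggregation.** A patient's atypical set is their FDR-significant edges.
Node recurrence counts patients (a patient with five thalamus edges
contributes one to the thalamus count), edge recurrence counts patients per
edge, and all thresholds are strict inequalities ("more than k" ⇒ > k):
defaults 10 for nodes, 7 for edges, 3 for the seed-level display threshold,
4 for group-graph links. Duplicate patient ids are rejected so repeated
assessments cannot silently inflate recurrence.

**Group network and hubs.** Each ROI carries one of 18 anatomical location
groups; an edge's recurrence count flows to the unordered pair of its
endpoint groups, self-pairs included (thalamus–thalamus connectivity is
real and legal). The hub score of a group is its weighted degree — sum of
incident link weights, self-loops counted twice per the standard graph
convention — divided by the maximum weighted degree, so the top hub scores
exactly 1.00 and scores are invariant to uniform rescaling of weights. An
unweighted-degree variant is available by flag since either reading of
"degree centrality" is defensible. Centralities beyond degree are out of
scope.

**Clinical statistics.** Outcome ~ edge-strength fits use simple OLS
(scipy's `linregress` behind the `ols_fit` surface), reporting slope,
intercept, and R² = 1 − SSE/SST, with fits sorted by R² and flagged at
R² ≥ 0.10; no multiplicity correction is applied to these screens. A
constant outcome is reported as slope 0, R² = 0 (nothing to explain); a
constant predictor is a degenerate design and errors. Age–outcome
correlations are Pearson r per sex stratum with two-sided t-based p, strata
under 3 complete observations skipped with a warning. Confounder screening
uses Welch two-sample t-tests for age and mean framewise displacement and
a chi-square test with continuity correction for sex, switching to
Fisher's exact test when any expected cell is below 5; p > 0.1 counts as
passing the screen.

## Synthetic data: what it emulates and what it does not

The edge-level generator draws each edge's population mean mu_e once from
Normal(0.3, 0.1) (Fisher-z units) and subject values from
Normal(mu_e, σ_between) with σ_between = 0.1 — magnitudes chosen to
resemble typical resting-state edge distributions while keeping all values
finite. Patients are drawn from the same distribution and shifted by δ on
their injected edges only, so ground truth is exact. The time-series
generator instead samples T × 192 signals from a unit-variance multivariate
normal whose injected seed/atlas correlations are shifted by δ on the
Fisher-z scale; non-positive-definite requests error with a suggestion to
reduce couplings. Clinical outcomes are linear in a chosen edge plus
Gaussian noise; ages are Normal(58, 7) years, sexes balanced, mean
framewise displacement |Normal(0.15, 0.05)| mm.

Deliberately not modeled: hemodynamics, scanner noise spectra, motion
artifacts, spatial autocorrelation between ROIs, within-subject
repeated-measures structure (patients are independent draws, matching a
cross-sectional pooling of assessments), and any age/sex effect on
connectivity. Passing tests therefore demonstrate the statistical machinery
— calibration, sensitivity, determinism, bookkeeping — not robustness to
realistic fMRI artifacts.

## Randomness and determinism

One root seed drives everything. Subject draws use `SeedSequence.spawn`
sub-streams; each patient × edge Monte-Carlo test derives its own
sub-stream from the root seed and a CRC-32 of the patient id, so results
are independent of edge evaluation order and identical across runs. Full
pipeline runs with a fixed seed are byte-identical (floats are written with
17 significant digits, and reading uses round-trip parsing).

## Problem sizes used in tests and the acceptance script

Calibration runs use 20 controls × 50 null patients at n_perm = 2,000
(≈15 s single-core); the Monte-Carlo-vs-exact oracle check uses a 5-control
toy at n_perm = 100,000; the injected-effect pipeline run uses 20 controls,
5 patients, and 10 injected edges at δ = 0.5 = 5σ_between. At that effect
size every injected edge attains the minimum achievable exact p (1/21)
before FDR; after pooled-null BH, each patient recovers the subset of its
injected edges whose observed statistics exceed the cross-edge null
extremes, with no false positives, and the five patients jointly recover
all ten.

## Known limitations

- The per-edge null's 21-outcome grid means per-edge FDR discoveries are
  effectively unattainable at n = 20 controls; the pooled-null variant
  trades the exact single-edge exchangeability argument for resolution.
- The packaged seed and atlas tables are synthetic reconstructions
  (flagged in their filenames): AAL-116 labels are standard but coordinates
  are approximate centroids, and the 76-seed composition follows published
  counts per structure rather than an exact coordinate list. Replace them
  via `seed_table`/`atlas_table` paths for real analyses.
- Confound adjustment (age/sex regression, normative modeling) is out of
  scope; confounders are screened, not removed.
- Edge values entering clinical fits use the testing scale; slopes are
  therefore per Fisher-z unit unless `pearson_r` is configured.
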