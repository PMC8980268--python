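# Methods

This note documents the models, conventions and numerical choices behind
`hemnet`, what the synthetic cohort generator does and does not emulate,
and the known limitations.

## Study design being emulated

Two groups: patients with unilateral anterior-circulation steno-occlusive
disease and healthy controls (20 each by default). Each hemisphere is a
45-ROI network. Patients contribute only the normal-appearing hemisphere
contralateral to disease; controls contribute both hemispheres, which
define hemisphere-matched normative distributions. Patients undergo a
600-volume acquisition (TR = 2 s) with acetazolamide (ACZ) infused after
5 min of baseline; controls a 400-volume resting acquisition. Only the
first 5 min after volume discard enters network analysis for both groups,
so group comparisons use equal data lengths; CVR uses the patients' full
series.

## Synthetic cohort generator

**Signal model.** Each hemisphere's ROI signals are a band-limited
multivariate Gaussian process: white normal draws with spatial correlation
R (Cholesky factorization) are band-pass filtered to 0.01–0.08 Hz
(matching the analysis band; no hemodynamic response model), standardized,
scaled to SD 10 about a baseline of 1000 raw units (≈1% BOLD-like
fluctuation).

**Planted connectivity.** R is block-modular: `n_modules = 5` contiguous
communities, correlation `rho_within = 0.5` inside and `rho_between =
0.05` across blocks (positive definite by construction; verified at build
time). Patients' contralateral hemispheres multiply all off-diagonal
correlations by `attenuation_alpha = 0.8` — the group-level connectivity
deficit — and add `cvr_coupling_beta × (dCVR_i + dCVR_j)` to entry (i, j),
where dCVR is each node's CVR deviation from the field mean; the perturbed
matrix is re-projected to the nearest valid correlation matrix (eigenvalue
clipping at 1e-6, unit-diagonal rescale). The coupling makes
better-perfused nodes better connected, which the mixed-effects stage
recovers as a positive metric–CVR slope. The diseased (ipsilateral)
hemisphere is generated with the same attenuation but never analyzed,
mirroring the contralateral-only design.

**CVR field and ACZ response.** Per-ROI CVR is i.i.d. normal (mean 6%,
SD 2%) truncated at zero (no spatial model is claimed). Patient series
carry an additive step of amplitude CVR_i% of the baseline mean, ramping
linearly over 60 volumes from volume 160 — after the 150-volume analysis
window, so the network stage sees baseline data only, while the pre
(first 30 retained) and post (last 30) CVR windows sit fully on baseline
and plateau respectively.

**Confounds.** Six slow-drift motion surrogates (shared between a
subject's hemispheres) plus hemisphere-specific WM and CSF traces, all
standardized low-pass noise, are mixed into the data at 10% of signal SD —
visible enough that nuisance regression is testable, small enough not to
dominate (≈1% of signal variance).

**What the generator does not emulate:** voxelwise structure, realistic
hemodynamic response functions, cardiac/respiratory physiology,
between-subject heterogeneity of the underlying connectome (all subjects
share one base R), and any causal direction between CVR and connectivity —
the coupling is correlational by construction. Consequently, passing
tests demonstrate that the analysis chain recovers planted effects of the
stated size under Gaussian, stationary noise; they do not validate the
chain against physiological confounds absent from the model. One notable
consequence: uniformly attenuating all correlations leaves the
signal-to-sampling-noise geometry of the thresholded network less modular,
so the patient modularity z-score in this replica is negative, unlike the
positive shift reported for real cohorts; emulating that sign would
require disproportionate attenuation of between-module connectivity,
which the generator deliberately does not assume.

## Preprocessing

Order: volume discard + window → linear detrend → nuisance regression →
band-pass. The window starts at the first retained volume (discarded
volumes are not counted). Nuisance design: intercept, six motion traces
from the analyzed hemisphere, and WM/CSF taken from the hemisphere
contralateral to disease for patients (that is, the analyzed hemisphere —
avoiding lesion contamination) or averaged over both hemispheres for
controls (arithmetic mean; no aggregation rule is otherwise prescribed).
Regressors enter unfiltered, and regression precedes filtering, following
the listed order of operations; this is an interpretive choice, since
band-passing the regressors first is an equally common convention.

Filter: Butterworth band-pass of total order 4 (two second-order
sections), applied forward–backward (zero phase) with odd-symmetric
padding of 3× the filter order to suppress transients on 150-sample
windows. Stop-band attenuation of the two-pass filter exceeds 20 dB one
octave outside the band.

## CVR

CVR is computed from the minimally processed series (discard only): the
detrend/band-pass would remove the very ACZ step being measured. Pre and
post windows are the first and last 30 retained volumes. ROIs with a zero
pre-window mean are flagged invalid, logged, and excluded from the
association stage. CVR is scale-invariant by construction.

## Networks

Pearson correlations of the preprocessed series; constant series are an
error (naming the ROI). Thresholding keeps exactly
`round(s·n(n−1)/2)` edges at sparsity s: negative correlations and the
diagonal are removed first, the largest positive correlations are kept
with their raw values (no binarization, no Fisher transform), and ties at
the cutoff rank break deterministically in lexicographic (i, j) order.
Defaults are s ∈ {0.20, 0.30, 0.40}, analyzed separately.

## Graph metrics

All shortest-path quantities use edge length l = 1/w (the standard map
for correlation-weighted brain networks). Nodal efficiency is the mean of
1/d over partners (1/∞ = 0); global efficiency is the mean nodal
efficiency; local efficiency is the global efficiency of the subgraph
induced by a node's neighbors with original weights (nodes with < 2
neighbors score 0). Betweenness uses Brandes' accumulation with
shortest-path counts; path-length equality tolerance is 1e-12; values are
normalized by (n−1)(n−2)/2. Modularity is optimized by a multilevel
greedy heuristic with randomized node visitation (resolution 1); because
the found optimum varies between runs, the reported value is the mean Q
over repeated runs (500 by default; at that count the mean is stable to
three decimals across seeds on 45-node networks). Assortativity is the
Pearson correlation of endpoint strengths over the double-orientation
edge list; when endpoint strengths have zero variance it is undefined and
propagated as missing (never zero-filled), excluded from z-scoring with a
log message.

## Normative scoring

Control norms are sample means and SDs (n−1 denominator) per hemisphere,
sparsity and metric; zero-SD or undefined quantities are excluded with a
warning. Node metrics additionally get per-node norms. Patients are
always scored against the norms of their analyzed (contralateral)
hemisphere. One-sample two-sided t-tests ask whether patient z-scores
have mean zero. FDR (Benjamini–Hochberg) families mirror the reporting
units: the six global metrics within one sparsity form one family;
node-level maps are corrected across the 45 nodes within each metric.
Because every patient's z shares the same control mean/SD estimate, the
t-test is mildly anticonservative by construction (variance of the mean z
is 1/n_p plus a shared-norm term); this is a property of the emulated
method itself, partially offset by patients splitting across left- and
right-matched norms.

## CVR association

Model: metric = β₀ + β₁·CVR + u0_s + u1_s·CVR + ε, random effects
unstructured, REML, two-sided Wald test on β₁ (CVR is the predictor — a
modeling choice; no causal direction is asserted). Optimization uses
Powell's method with an lbfgs fallback; if the random-slope fit fails to
converge or its random-effect covariance is singular, the model refits
with random intercepts only and flags the result. Confidence intervals
for β₁ use a t reference with n_subjects − 2 df: with subject-specific
slopes the fixed slope is effectively a between-subject mean, and normal
intervals undercover at cohort sizes of 10–20 (measured 88% vs 95%
nominal at 10 subjects; the t interval restores 95%). FDR runs across the
four node-metric family; q < 0.10 is flagged as a trend. The sensitivity
rerun excludes either a named subject or, automatically, any subject
whose per-subject OLS slope lies > 2 SD from the cohort mean — a
reproducible substitute for visual outlier identification.

## Simulation study sizes

Chosen to characterize the estimators well while keeping full runs cheap:
group-effect recovery and null calibration use 20 cohorts per arm of
20 v 20 subjects at sparsity 0.40 with 20 modularity runs (the pipeline
default remains 500; the group-level mean z is insensitive to the run
count beyond ~20); mixed-model recovery and permutation-null studies use
100 seeds of 10 subjects × 45 ROIs with a planted slope of 0.02. The
acceptance script's end-to-end run uses 150 modularity runs.

## Known limitations

- The generator's single shared base connectome understates between-subject
  variance; real normative SDs would be wider and z-scores smaller.
- The modularity z-score direction differs from real-cohort reports (see
  above); degree and efficiency directions are faithfully recovered.
- The mixed model's Wald p-values are asymptotic; only the confidence
  intervals apply a small-sample correction.
- Negative correlations are discarded, not analyzed; binary-graph
  variants, interhemispheric networks and dynamic connectivity are out of
  scope.
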