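# Methods

`radkinetics` implements a longitudinal ("kinetics") radiomics analysis of
irradiated mandibular bone: texture features are computed over volumes of
interest (VOIs) at serial CT time points, screened, encoded as temporal
trajectories by multivariate functional principal component analysis
(MFPCA), and used to compare five classifier representations of
osteoradionecrosis (ORN) risk. Because the clinical cohort that motivated
the design is private, a synthetic-data module generates cohorts with known
ground truth; every claim the test suite makes is a claim about those
controlled conditions.

## Study design being modelled

Each patient contributes an ORN lesion VOI and a radiographically intact
"Control" VOI that received the same radiation dose, imaged at months 0
(pre-treatment), 2 and 6. The default synthetic cohort mirrors that shape:
21 patients, 22 ORN VOIs (one patient carries two lesions) and 21 Control
VOIs, i.e. 43 VOIs observed at three months. The paired same-patient design
is why model evaluation groups train/test splits by patient.

## Synthetic cohorts

Feature values are generated on a standardized (unit-variance Gaussian)
scale; downstream statistics are rank-based or tree-based, so marginal
shape carries no information, and Gaussianity makes the injected group
separation analytically controllable. Per VOI,

    x_t = z + trend * t + signal(mode, arm, t) + eps_t

* `z` — latent feature vector, multivariate Gaussian with block-diagonal
  exchangeable correlation (`correlation_blocks`, default two blocks of 4
  features at rho 0.8 and 0.6, remaining features independent). A patient
  random effect contributes `within_patient_rho` (default 0.3) of the
  latent variance; the study never reports the ORN-Control within-patient
  correlation, so it is exposed as a parameter rather than fixed.
* `eps_t` — per-month observation noise (`noise_sd`, default 0.2) drawn
  with the *same* block correlation, so the inter-feature correlation of
  emitted values equals the specified rho exactly rather than being
  attenuated; this makes the generator's correlation contract exact.
* `trend` — a common monotone drift (0.15/month) shared by both arms,
  standing in for post-radiotherapy tissue change.
* `signal` — where the ORN-vs-Control separation lives:
  * `baseline`: constant shift of the ORN arm at every month, so the net
    change is uninformative;
  * `delta`: shift accruing linearly to `effect_size` at month 6, with
    identical baselines;
  * `shape`: a detour of the ORN arm at month 2 only. Baselines *and* net
    changes then match in distribution; with the shared trend the Control
    mean path is monotone while the ORN path is not. This is the minimal
    realization of the scenario where neither a pre-treatment model nor a
    delta model can separate the arms but the trajectory can.

Defaults `effect_size = 1.5`, `noise_sd = 0.2` give a month-2 standardized
separation of about 1.5 under `shape` — a strong but not degenerate signal.

What the generator does **not** emulate: scanner and acquisition
variability, metal-artifact streaks, non-Gaussian heavy-tailed feature
marginals, registration error in VOI propagation, and missing-visit
mechanisms other than complete absence of a month. Passing tests therefore
demonstrate correctness of the machinery and the qualitative
representational argument, not clinical performance.

Textured phantoms (for the feature extractor) are band-limited separable
sinusoidal fields plus white noise inside two disjoint spherical VOIs on a
shared base level; amplitude and spatial period are generative knobs with
known consequences (zero amplitude ⇒ zero GLCM contrast).

## Texture features

Volumes are first resampled by trilinear interpolation to a standard voxel
size (default 1 × 1 × 3 mm, voxel-centre convention, physical extent
preserved), masks by nearest neighbour. In-mask intensities are discretized
into equal-width bins (default 32 levels) between the in-mask minimum and
maximum; the binning is configuration, recorded in provenance, because the
original extraction software's settings are not public.

* **GLCM** — symmetric co-occurrence counts at distance 1, merged over the
  13 unique 3D directions (3D mode) or the 4 in-plane directions summed
  across slices (2.5D mode), normalized after merging. Features: contrast,
  dissimilarity, correlation, cluster shade, IDMN (normalized by the level
  count) and IMC1 (base-2 entropies, 0·log0 = 0).
* **GLRL** — run-length matrices over the same direction sets, runs
  truncated at the mask boundary, matrices summed before the Galloway
  features (SRE, LRE, GLN, RLN, run percentage). Run percentage divides by
  in-mask voxels × number of directions, so a single constant line in one
  direction gives 1/n.
* **NGTDM / NID** — Amadasun–King coarseness, contrast, busyness,
  complexity and texture strength at neighborhoods k = 3, 5, 7; a voxel
  contributes only when its full k-window lies inside the mask (and, in
  3D, the volume). Occurrence *probabilities* p_i are used in all formulas
  (the standard convention); a fully constant region has every s_i = 0 and
  returns 0 for contrast/busyness/complexity/strength with coarseness
  capped at 1e12.
* **First order** — mean, SD, skewness, kurtosis, base-2 histogram entropy
  of the discretized levels, the median of per-voxel 3 × 3 × 1 local
  entropies (in-plane window: the slice spacing is anisotropic), and voxel
  volume in mm³.

Degenerate features (zero variance ⇒ GLCM correlation, empty entropies)
are flagged undefined rather than propagated as silent NaN; screening drops
flagged columns, mirroring the source analysis keeping only features
available at all time points in both VOI classes. Direction-merged 3D
features are invariant to 90° rotations because the offset sets are closed
under the rotation group; the test suite asserts this.

## Screening

At the pre-treatment month only, the Spearman correlation matrix (average
ranks for ties) feeds a greedy mean-correlation filter: while any feature's
mean absolute off-diagonal correlation over the retained set exceeds the
threshold (default 0.5), the worst offender is removed (ties broken by
column order) and the means recomputed. One-at-a-time removal with
recomputation was chosen over a single pass because the retained set
depends on it; the procedure is idempotent and deterministic. The retained
list is then applied to all months.

Screening tests each retained feature with a two-sided Mann-Whitney U test:
exact null enumeration when both groups have ≤ 10 observations without
ties, otherwise the normal approximation with tie and continuity
corrections. The direction column is the sign of mean(ORN) − mean(Control)
— arithmetic means, matching the convention of reporting a mean difference.
Raw p-values are reported; Benjamini–Hochberg is available behind a flag
but off by default.

## Trajectory encoding (MFPCA)

Three observations per VOI per feature are completed to integer months 0-6
by a natural cubic spline (interpolation only; with three points any
penalized smoother is underdetermined, so the spline itself is the
regularizer). Features are standardized to unit variance of the stacked
observations first, since raw feature scales differ by orders of magnitude
and would dominate the covariance; scales are stored and reversible.

Univariate FPCA per feature: center by the pointwise mean, form the
empirical covariance, solve the quadrature-weighted eigenproblem via the
symmetrization W^{1/2} C W^{1/2} (trapezoid weights), back-transform by
W^{-1/2} so eigenfunctions are orthonormal under the quadrature inner
product, and integrate centered curves against eigenfunctions for scores.
Components are retained to cumulative PVE 0.99.

MFPCA stacks the per-feature scores into Ξ (n × Σ M_j) and eigendecomposes
(1/(n−1)) ΞᵀΞ; multivariate scores are ρ = Ξc, per-feature eigenfunction
components ψ_m^(j) = Σ_a [c_m]_{(j,a)} φ_ja, retention to cumulative PVE
0.9. Both PVE levels are configuration (the levels used in the original
analysis are unreported) and are logged in every run manifest. Signs are
fixed (positive quadrature integral, falling back to a positive first
value; leading stacked-eigenvector entry positive) so repeated runs are
bit-identical. Eigenvalue clipping at zero and a relative tolerance on
negative eigenvalues guard the symmetric eigensolver's round-off.

## Models

Five representations feed identical random-forest machinery:

| representation | design matrix |
|---|---|
| baseline | month-0 feature values |
| delta2 | (x₂ − x₀) / max(\|x₀\|, ε), ε = 1e-8 × feature scale |
| delta6 | same with x₆ |
| trajectory | MFPCA scores ρ |
| ensemble | mean of baseline and trajectory probabilities |

Monte-Carlo cross-validation: repeated random patient-grouped train/test
splits (test fraction 1/3), a forest per split (default 500 trees,
bootstrap rows, floor(√p) split candidates), and per-VOI mean held-out
Control-class probability. Defaults of 200 repeats guarantee every VOI is
held out many times; the schedule additionally appends corrective splits if
a VOI was never held out, so the prediction set is always complete. All
representations share one schedule, making AUC comparisons paired.

Two deliberate readings are configurable: `split_candidates` can be set to
the literal number of features (the alternative reading of the forest's
split rule), and `grouped=False` restores ungrouped VOI-level splitting.
Grouped splitting is the default because paired ORN/Control VOIs from one
patient would otherwise leak across partitions. Monte-Carlo CV was chosen
over out-of-bag validation as the reading of "repeated random sampling with
left-out observations"; OOB is a possible variant but is not implemented.

## Evaluation

Probabilities are of the Control class; ORN is detection-positive and is
called when the probability falls below the threshold, with the boundary
value assigned to Control. ROC thresholds are the midpoints between sorted
distinct probabilities plus sentinels; the trapezoidal AUC then equals the
tie-corrected two-sample U-statistic exactly (asserted to 1e-12). The
Youden-optimal point maximizes J = sensitivity + specificity − 1, ties
broken toward higher sensitivity then lower threshold. Confidence
intervals: DeLong placements by default (the common default of standard ROC
packages), seeded stratified percentile bootstrap (2000 resamples) as the
alternative and as the automatic fallback when the DeLong variance
degenerates (e.g. perfect separation); the method used is always labelled
in the output.

## Benchmark problem sizes

The five-model benchmark runs on shape-signal cohorts of 100 VOIs per arm
(effect 1.5, noise 0.2) over 10 seeds, and no-signal cohorts over 3 seeds,
with 150-tree forests and 25 MC repeats — sizes at which the mean AUCs are
stable to well under the 0.15 margins being tested while keeping a full run
in minutes on one core. The library defaults (500 trees, 200 repeats)
remain the reference configuration for single-cohort analyses. Note that
on shape cohorts the 2-month delta model is also near-perfect — the
month-2 detour *is* a 0→2 change — so the discriminating comparisons are
trajectory vs baseline and trajectory vs 6-month delta, which are blind to
the detour by construction.

## Known limitations

* Sparse-design FPCA (PACE-style conditional scores) is not implemented;
  every VOI must be observed at all configured months, and VOIs missing a
  month are excluded (with a logged warning), as in the source design.
* The texture catalog is a representative subset (6 GLCM + 5 GLRL + 5
  NGTDM × modes/neighborhoods + 7 first-order), not the thousands of
  features of a full extraction platform; shape features beyond voxel
  volume, filtered (wavelet/Laplacian) features, and DICOM-RT mask
  rasterization are out of scope.
* Synthetic cohorts cannot validate clinical effect sizes; the published
  clinical AUCs are not reproducible without the private cohort, and no
  numeric claim about them is made here.
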