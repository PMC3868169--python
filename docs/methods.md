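# Methods

## Scope and model

`rcga` localizes, inside coarse regions of interest, the voxels whose
inter-regional functional connectivity differs between two subject groups,
and quantifies what the localization buys over whole-ROI averaging. The
statistical object at the core is the per-voxel **dysfunction intensity**

    I_i = N_i^B(P < alpha) / N^B,

the fraction of region B's voxels whose link with voxel i (of region A)
shows a group difference at the raw per-link level alpha. Per-link tests are
pooled-variance two-sample t-tests on Fisher-transformed Pearson
correlations; a single link test is noisy and deliberately uncorrected, and
robustness comes from aggregating N^B of them into a fraction. Source masks
are `I > theta` with a **strict** inequality (boundary voxels at exactly
theta are excluded, making thresholded counts reproducible), theta = 0.15
for reporting and theta = 0.10 when sources are re-located inside
classification training splits. An ROI probed by several links takes the
elementwise maximum of its per-link intensities; the winning link's
denominator is kept per voxel so `I * N` stays an integer count.

## Pipeline conventions

* **Signal cleaning** (order: detrend → band-pass → nuisance regression):
  least-squares removal of intercept + slope; Butterworth band-pass
  0.01–0.08 Hz (order 4 per edge) applied forward-backward (zero phase) with
  reflect padding, chosen because short resting-state series (T ≈ 170) need
  phase preservation and tame edge transients; optional OLS nuisance
  regression with collinear columns dropped. TR defaults to the image
  header but an explicit configuration value wins (with a warning).
* **Link tests**: pooled Student t by default (a `welch` flag exists);
  exactly constant voxels make a link undefined — it is excluded with p = 1
  so it can never reach a source mask. |r| ≥ 1 is clipped to 1 − 1e-7 before
  the Fisher transform.
* **Clustering**: 18-connectivity (neighbors differ by ≤1 per axis and share
  a face or an edge; the 8 corner offsets are not neighbors). Cluster ids
  are ordered by descending size, ties by lowest member linearized index;
  peak ties break to the lowest linear index. The per-cluster `min_link_p`
  column reports the minimum link p at the peak voxel — one reasonable
  reading of a per-peak "P-value", labeled as such because no standard
  definition exists for it.
* **Effect measures**: the per-subject link-presence rule is not
  standardized anywhere, so it is pluggable; the default declares a link
  present when the subject's correlation is significantly positive
  (two-sided t on r, df = T−2, alpha = 0.05, r > 0). OR is reported raw;
  the Woolf logit interval gets the Haldane–Anscombe +0.5 correction only
  when a cell is zero. `recover_counts_from_rd/or` inverts a printed
  4-decimal effect value back to the unique integer 2×2 table by exhaustive
  search (rounding half away from zero), and errors on ambiguity.
* **Permutation test**: the reported p is the add-one estimator
  `(1 + #{|RD_perm| ≥ |RD_obs|}) / (n_perm + 1)` — never zero, slightly
  conservative. With binary per-subject data the permutation distribution of
  RD is discrete with large central tie masses, so this p cannot be uniform
  under the null; calibration checks use the standard randomized tie-broken
  estimator (`tie_break="randomized"`), which is exactly U(0,1) under the
  null. Shuffling labels reduces to a hypergeometric draw of the patient
  presence count, which is how the permutations are implemented.
* **ALFF**: mean over DFT bins with band_low ≤ f ≤ band_high (inclusive) of
  the square root of the one-sided periodogram |DFT|²/T; resolution
  1/(T·tr); no across-voxel normalization. The convention is arbitrary but
  fixed, so numbers reproduce bit for bit; under the |DFT|²/T² normalization
  the two-sided periodogram sums exactly to the mean square (Parseval),
  which the tests verify.
* **Classification**: RBF-kernel SVM, C = 10, kernel width 1/n_features,
  features standardized per split with training mean/SD. Fraction schemes
  draw stratified training subsets (both classes always represented);
  leave-one-out is deterministic. Sensitivity is patient recall, specificity
  control recall. In voxel mode the sources are re-located per training
  split; an empty mask falls back to ROI features for that split (logged).
  Test-subject data never enter mask derivation (asserted by a shuffle test).

## The synthetic cohort generator

Defaults mirror the study conditions the method targets: 39 patients,
37 controls, T = 170 volumes at TR = 2 s (180 acquired minus 10 discarded),
two linked ROI pairs sharing a middle region. The 24³ grid with ROIs of
256–384 voxels and source blobs of 48–64 voxels is a desk-scale stand-in for
anatomical ROIs of 352–1184 voxels; the shared ROI has two disjoint blobs,
one per link, so the max-combination rule is exercised.

Source voxels follow
`x = a_g·c_link + w·s_roi + σ·ε` with band-limited unit-variance Gaussian
latents (c shared across the linked pair, s within the region), AR(1) noise
(ρ = 0.3) and group couplings a_control = 0.8 > a_patient = 0.2 — links are
less likely to occur in patients, the direction the effect measures expect.
Non-source voxels are independent AR(1) noise with a larger standard
deviation (σ_nonsource = 5σ). This heterogeneity is deliberate: if every
voxel had equal noise, the ROI mean would act as a matched filter
(independent noise averages away while the planted latent survives) and
coarse analysis would be essentially as good as the localized one, which is
not the regime the method exists for. Independent — rather than shared —
non-source signal keeps the null link tests exactly independent across
voxels. The 5× default makes the non-informative contribution to the
ROI-mean variance comparable to the planted circuit signal, emulating at
this scale the heterogeneity of much larger anatomical ROIs.

`expected_source_correlation` gives the closed form
`r = a_g² / (a_g² + w² + σ_eff²)` for a cross-ROI source pair after
preprocessing, with σ_eff² the band-passed AR(1) noise variance expressed in
band-passed-latent units, computed by quadrature of the zero-phase filter
power gain |H|⁴ against the AR(1) spectrum. Simulation agrees within ±0.02
at 200 subjects. Determinism: subject streams are spawned from a single seed
sequence; identical (spec, seed) give identical matrices and byte-identical
NIfTI files.

### What the generator does not emulate

No hemodynamic response, head motion, physiological confounds, spatial
autocorrelation within the noise, or registration error. Passing tests show
the statistical machinery behaves as designed under its own assumptions —
not that real cohorts will show effects of this size.

## Null behavior and a real limitation

On the fully decoupled null (`null_spec()`: a = 0, w = 0, all voxels
independent), the link-level rejection rate sits at alpha, per-voxel
significant-link counts are Binomial, mean intensity ≈ alpha, and source
masks at theta = 0.15 are empty — the calibration the intensity statistic is
designed around.

Removing only the *group difference* (a_control = a_patient > 0, or any
w > 0) is a subtler null: the tests remain exactly null link by link (group
exchangeability), but voxels inside a blob still share latents, so the
t-statistics of one voxel's links are mutually correlated. Significant-link
counts are then overdispersed relative to Binomial, and a handful of voxels
can cross theta with no group effect at all. This is a genuine property of
count aggregation under correlated links — real BOLD data are exactly such
data — and it means isolated small supra-threshold clusters on real cohorts
deserve skepticism; the intensity threshold controls false localization
only to the extent that links behave independently. The test suite pins
both facts: calibrated rejection rates under equal coupling, and empty masks
on the decoupled null.

## Numerical and design choices

* Voxel indices are 0-based; world coordinates only ever come from the
  affine. Time-series matrix columns follow ascending C-order linearized
  (x, y, z) indices, so results cannot depend on mask construction order.
* Masks with values outside {0, 1} are binarized at > 0.5 with a warning.
* Degenerate inputs: constant series detrend to zeros; identical constant
  groups give t = 0, p = 1; an empty source mask raises with advice to lower
  theta (or triggers the classification fallback).
* Problem sizes in the test suite (10 null cohorts, 500 classification
  splits at the 50% scheme, 2,000-replicate coverage/uniformity runs) were
  chosen to give Monte-Carlo error comfortably inside the asserted
  tolerances while keeping the suite in the minutes range.
* The pipeline runner hashes its configuration into every manifest;
  re-running an identical configuration is a no-op, and any stage failure is
  re-raised with the stage name.

## Known limitations

* The intensity statistic assumes the two regions' voxel counts are large
  enough for fractions to be stable; ROIs of a few dozen voxels would make
  theta-thresholding coarse.
* No cluster-extent inference is attempted (no random-field or permutation
  cluster p-values); cluster tables are descriptive.
* The per-peak `min_link_p` is an interpretation, not a calibrated
  statistic.
* Fraction-scheme classification metrics average over random splits and are
  not cross-validation estimates with independence guarantees; the
  repeated-split protocol is reproduced as-is, optimistic tendencies
  included.
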