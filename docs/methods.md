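# Methods

## Scope and data model

The package analyzes collections of single-point SERS spectra: one
wavenumber axis (cm⁻¹), one intensity vector (detector counts) and
metadata per spectrum — cell-line label, batch index, sample id. A batch
is one independently cultured, lysed and measured preparation; it is the
unit of biological/technical replication, which is why validation holds
out whole batches rather than individual spectra. Spectra must share one
axis; no resampling or interpolation is performed anywhere (the intended
use is data from a single instrument), and a spectrum on a different axis
is rejected on read.

## Preprocessing chain

Applied per spectrum, in order:

1. **Dark subtraction.** The dark trace is smoothed with a symmetric
   Whittaker smoother and subtracted, removing dark current and the
   constant bias without injecting the dark trace's shot noise. The dark
   penalty is much stiffer than the baseline penalty (`lambda_dark = 1e7`,
   d = 2) because a dark spectrum has no sharp features to preserve; at
   this stiffness the residual dark-noise SD is reduced by more than an
   order of magnitude relative to subtracting the raw dark trace (the
   noise gain of a d = 2 smoother falls off only as `lambda^(-1/8)`, so a
   merely "large" penalty such as 1e5 buys barely a factor of 7).
2. **Background correction (AsLS).** The smooth background from residual
   excitation light and fluorescence is estimated by iterated asymmetric
   reweighting of the Whittaker smoother: starting from unit weights,
   each iteration solves `(W + lambda D'D) z = W y` and then sets
   `w_i = p` where `y_i > z_i` and `1 - p` otherwise, until the weight
   vector reaches a fixpoint (tol = 0) or 20 iterations. Defaults
   `lambda = 1e5`, `p = 0.01`, `d = 2` suit a ~2 cm⁻¹ channel spacing and
   band widths of ~10–20 cm⁻¹ HWHM: the baseline is stiff on the scale of
   a band but follows the injected cubic backgrounds to within 2% of the
   tallest peak in the recovery tests. A symmetric smoother cannot
   separate peaks from background, which is why the asymmetric variant is
   used for the baseline while the plain smoother handles the dark trace.
   The normal equations are solved with a banded Cholesky factorization
   (`scipy.linalg.solveh_banded`); the system is SPD with bandwidth d.
3. **Cropping.** The fingerprint region [500, 1800] cm⁻¹ and the
   CH-stretch region [2828, 3028] cm⁻¹ are kept — both bounds inclusive,
   so the default 400–3100 cm⁻¹ axis at 2 cm⁻¹ spacing yields
   651 + 101 = 752 channels — and concatenated. The block lengths are
   recorded so that later integration never bridges the artificial jump
   between the regions.
4. **Area normalization.** Intensities are divided by the integrated
   absolute intensity, `sum_i |I_i| * dnu_i`, with trapezoidal channel
   widths computed per region. The retained area becomes exactly 1 and
   the result is invariant under positive rescaling of the input (laser
   power, collection efficiency). L1 area with trapezoid weights was
   chosen over a plain channel sum so the normalization has physical
   units of inverse area and is grid-robust; normalization is idempotent.

## Chemometrics

PCA is fitted by SVD of the column-centered training matrix; channels are
not variance-scaled (after area normalization all channels share units,
and correlation-matrix PCA would inflate noise-only channels). Loadings
are orthonormal rows with a fixed sign convention (largest-magnitude
element positive) so persisted models and score plots are reproducible.
Held-out spectra are projected as `(X - mean_train) @ loadings'` — the
training mean, never the test set's own, so no information flows from
held-out batches into the model. Four components are the default: at the
default synthetic conditions they carry ≈ 94% of the variance (the real
benchmark data reports 89%).

Classification is a soft-margin linear SVM, one-vs-one with pairwise
voting (the libSVM multiclass convention), `C = 1` by default and scores
left unstandardized — PC scores already share units. Training delegates
to scikit-learn's libSVM binding with a tightened stopping tolerance
(1e-6) so the extracted hyperplanes agree with an exact brute-force dual
solution to ~1e-4; the prediction rule (voting, exact vote ties broken
toward the earliest label in sorted label order) is implemented in the
package and is what the pipeline executes. Fitted models persist as plain
text (key/value lines plus matrix blocks) so they diff cleanly.

## Batch-wise validation and metrics

`enumerate_splits(6, 3)` produces all C(6,3) = 20 unordered choices of
three training batches with the complementary three batches for testing,
in lexicographic order. For each split the pipeline fits PCA and SVM on
the training batches only, classifies the held-out batches, and the 20
confusion matrices are summed entry-wise; each test spectrum of each
split is counted exactly once.

Pooled per-class sensitivity, specificity and accuracy are one-vs-rest on
the summed matrix. Sensitivity and specificity are also reported as the
mean ± sample SD of the per-split values; splits where a denominator is
empty are excluded from the mean and counted, and an empty class row in
the summed matrix yields NaN with a warning, never a silent zero.
Reported percentages are rounded to one decimal with ties away from zero
(898/1005 → 89.4). On the packaged reference confusion matrix this
machinery reproduces every published benchmark percentage exactly, which
pins the metric definitions to the benchmark's.

## Synthetic data generator

The generator emulates the statistical structure of lysate-SERS data, not
its photophysics. Each spectrum is

    I(nu) = sum_m A[k,m] * g[k,b,m] * L(nu; c_m, w_m)
            + poly_j(nu) + dark + drift(nu) + eps

with Lorentzian profiles `L` (unit height; natural line shape for Raman
bands), class-amplitude matrix `A`, per-(batch, band) mean-one log-normal
factors `g` (relative SD 3% — batch-to-batch enhancement variability;
the benchmark emphasizes small between-batch SDs), a per-spectrum random
cubic background (coefficient SD 30 counts, emulating residual excitation
light), a shared dark level (100 counts) with slow polynomial drift
(SD 5 counts) that also forms the returned dark spectrum, and i.i.d.
Gaussian noise (SD 0.5 counts).

The 13 default bands sit at literature positions for cellular
biomolecules — 660 (carboxylate), 723 and 1339 (adenine ring modes), 800
and 960 (CN stretches), 900 (protein), 1030/1080 (carbohydrates), 1289
(amide III), 1450 (CH₂ deformation), 1660 (amide I), 2923/2952 cm⁻¹
(CH₂/CH₃ stretches) — with 10 cm⁻¹ HWHM in the fingerprint region and
20 cm⁻¹ in the CH region, base amplitudes 45–120 counts. The four class
rows are identical except for contrasts of 5–25% at 660, 723, 900, 960
and 1339 cm⁻¹ and in the CH/fingerprint balance, mirroring where the
benchmark's principal-component loadings localize the class differences;
the MCF-7-like class is the extreme in CH-to-fingerprint area ratio (the
contrast a first PC separates). Classes therefore remain highly similar
overall, as real lysate spectra are.

Randomness is split hierarchically (dataset → class → batch → spectrum)
via `numpy.random.SeedSequence`, so a (config, seed) pair is a pure
function of the dataset bit for bit, and growing `n_per_batch` appends
spectra without reshuffling existing ones. `n_per_batch` defaults to 16
so three test batches contribute ≈ 48 spectra per class per split,
matching the benchmark's per-run trial counts (≈ 939–1005 over 20 runs);
the benchmark's stated 8–10 samples per batch would give only ≈ 24–30,
an inconsistency the generator leaves configurable rather than resolves.

Amplitudes, contrasts and noise levels were fixed once, by calibrating
the generator to the regime the benchmark reports — four PCs ≈ 90% of
variance, per-class accuracies in the high 90s — and then frozen. What
the generator does *not* model: cosmic-ray spikes, wavelength/intensity
miscalibration between sessions, nanoparticle aggregation photophysics,
heteroscedastic shot noise, and per-spectrum band-amplitude variability
beyond the shared batch factor. Passing tests on synthetic data therefore
demonstrate the correctness and leak-freedom of the pipeline, not the
real-data attainability of any particular accuracy.

## The null control and anti-learning

`chance_level_dataset` regenerates the dataset with every class-amplitude
row replaced by the across-class mean, so labels carry no signal. One
might expect every per-class sensitivity to land in a binomial band
around 1/K. Two effects break that expectation, and both are properties
of the validation design rather than bugs:

* **Anti-learning.** With the class signal removed, the only structure
  left is the per-batch amplitude fingerprint. The SVM memorizes the
  training batches' fingerprints; held-out batches have fresh
  fingerprints, and maximum-margin boundaries systematically place them
  on the far side of the training clusters. Measured pooled accuracy on
  null data is 14–21% — reliably *below* 25% — for any nonzero
  batch-level variation (0.5%–3% were measured).
* **Model-induced correlation.** All spectra of a split are classified by
  one fitted model, so predictions are not independent trials; per-class
  sensitivities are far over-dispersed relative to binomial (observed
  8–47% per class), even with batch variation set to zero, while the
  *overall* accuracy stays within the band (23–26%).

The test suite therefore asserts the property the null control actually
certifies — no leakage: label-free data is never classified *above*
chance (overall accuracy at or below the upper 99% binomial bound). The
strict per-class two-sided binomial expectation is kept as a separate
acceptance check and fails honestly at the default conditions, for the
reasons above.

## Problem sizes and runtime

Default study conditions: 4 classes × 6 batches × 16 spectra = 384
spectra of 1351 channels (752 after cropping); one full
generate → preprocess → 20-split cross-validation run takes ≈ 1.3 s on
one CPU, dominated by the per-spectrum AsLS iterations. The repeated-seed
properties (accuracy, variance capture, separation monotonicity) use ten
seeds; the whole test suite runs in ≈ 35 s and the acceptance script in
≈ 15 s.

## Known limitations

* No vendor formats (SPC/JCAMP-DX/WiRE): delimited text only.
* No cosmic-ray despiking or wavelength/intensity calibration — assumed
  done upstream, on-instrument.
* No resampler: spectra must share an axis exactly.
* Hyperparameters (lambda, p, C, number of PCs) are exposed but not
  auto-tuned; there is no nested model selection.
* The per-run sensitivity/specificity SDs depend on the split scheme and
  are not comparable across schemes with different test-set sizes.
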