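# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `skinspec`, and what its synthetic-data tests do and do
not demonstrate about real clinical spectra.

## Data model

A measurement campaign visits lesions carried by patients. Around each
lesion five single-point spots are measured: the lesional spot (L), two
peri-lesional spots on the surgical safety margin (PL) and two clinically
healthy spots (NL). Histology on the excised spindle supplies the ground
truth per spot: BCC, SCC, AK or H, with an invasiveness flag (CI/CNI) for
carcinomas. Each spot is acquired as one *sequence* of 24 spectra — 5 AF
excitations and DR, each at 4 source–detector separations — and each
sequence is repeated three times without moving the probe. Channels are
enumerated in a fixed order, (AF1,SDS1) … (AF5,SDS4), (DR,SDS1) … (DR,SDS4),
so that reports and fusion vectors are comparable across runs.

Spectra travel as long-format CSV (one row per wavelength sample). The
schema's required columns cannot distinguish a lesion's two PL spots, so the
writer adds a `site_id` column; the reader uses it when present and falls
back to grouping by (lesion, site kind) otherwise.

## Preprocessing

Stage order is fixed: median filter → dark subtraction → Savitzky–Golay
smoothing → resampling → response correction (AF only). The order is chosen
so impulse spikes cannot leak into the least-squares smoother and smoothing
precedes decimation (anti-aliasing). Defaults: median kernel 3 samples;
Savitzky–Golay window 81 samples with polynomial order 4, stated on the
instrument's native 0.3-nm grid (≈24 nm physical width); resampling to the
integer 1-nm grid inside each channel's acquisition range by linear
interpolation, never extrapolating.

Two conventions are ours: when the input grid step differs from 0.3 nm the
smoothing window is rescaled to preserve its physical width (configurable
off); and intensities are clipped at zero after dark subtraction and
smoothing, which protects the downstream CV screen and normalizations from
division blow-ups. Edge handling — nearest-value padding for the median,
truncated-window polynomial refit for Savitzky–Golay — preserves length.

## Replicate screen

The trio CV uses the population SD (denominator = number of repeats under
the root) at every wavelength, divided by the replicate mean, averaged over
the modality window (AF1–3: 421–550 nm; AF4–5: 451–580 nm; DR: 340–780 nm).
Wavelengths whose replicate mean falls below 1e-9 detector units are
excluded from the average (the formula divides by the mean; near-dark
wavelengths would dominate it with noise). Threshold 0.08 on the trio CV,
then on the three pairwise CVs; among pairs under the threshold the smallest
CV wins, ties resolved by lowest repeat indices. Retained repeats are
averaged pointwise.

## Normalization

`max` divides each spectrum by its own maximum inside 420–600 nm (AF, the
red tail being noise-dominated) or 630–690 nm (DR, where scattering
dominates hemoglobin absorption). `ratio` multiplies by the constant
(global healthy mean intensity) / (peak of the lesion's local healthy mean),
preserving shape exactly. `baseline` multiplies pointwise by
(global healthy mean spectrum) / (lesion's local healthy mean spectrum),
correcting shape as well; it is the default for AF while DR defaults to no
normalization — the configuration that performs best in practice.

The local reference of a lesion is the mean of its H-labelled sites' spectra
(typically the 2 PL + 2 NL spots): a fixed, lesion-intrinsic quantity.
Global healthy statistics, by contrast, are cohort-level estimates and are
computed from sites outside the current test fold only; a held-out site can
never move them (asserted by a poisoning test). References are floored at
1e-9 before division, with a warning, rather than erroring on isolated
near-zero values. The global healthy scalar and spectrum are computed per
channel; lesions that lost all healthy sites on a channel make their
lesional samples abstain on that channel rather than borrow another lesion's
reference.

## Classification

Per channel: classes are balanced by downsampling without replacement to the
smallest class; stratified k-fold CV (k = 5, chosen so test folds stay
useful in size; configurable) provides out-of-fold predictions; the whole
sequence, starting from the balancing draw, is repeated 5 times (repeat r
draws from seed + r) and the across-repeat SD of accuracy is reported.
Feature extraction is fitted on training folds only: PCA (default 15
components, full SVD) or a symmetric autoencoder (hidden layers 80/40/80,
squared-error reconstruction of mean-centered input, encoder = bottleneck
activations; solver and activation configurable, lbfgs recommended at small
n). Features are then centered and unit-scaled on training statistics;
components with near-zero training variance — principal directions beyond
the numerical rank — are centered but left unscaled, since dividing by a
~1e-13 SD would amplify numerical noise into the classifier. Classifiers:
SVM (default linear kernel, one-vs-rest), MLP (one hidden layer of 80), or
LDA. Hyperparameter candidates, when given as lists, are each evaluated by
mean out-of-fold accuracy over all repeats and the winner is returned; ties
go to the earliest (simplest) candidate. This selects on the same folds that
produce the reported accuracy, which is optimistic — the honest use is to
treat reported accuracy as validation accuracy, as the defaults (a single
candidate) do.

In the pipeline, balancing draws and fold assignments are computed once per
repeat on the master site list and shared by all 24 channels, so fusion sees
aligned votes; a channel whose measurement was removed by the replicate
screen abstains for that site.

## Fusion

Majority voting breaks ties by the summed per-class classifier scores, then
by a fixed severity order (most pathological first) — the clinically safer
call. Weighted voting weights each channel by its mean out-of-fold accuracy
rescaled to sum 1; stacking trains an SVM or an 80-tree random forest on the
one-hot-encoded vote vector, with abstention as an explicit category. Fold
assignments are repeat-specific, so weights and stackers are computed within
the sample's own repeat, always excluding the predicted fold — using another
repeat's rows would leak the sample's label. Grouping levels: all 24
channels, per modality (6 groups of 4) or per SDS (4 groups of 6).

## Evaluation

The headline metric is balanced multiclass accuracy: the unweighted mean of
per-class recall (diagonal of the row-percent confusion matrix), which
coincides with pooled accuracy on balanced designs and does not reward
majority-class guessing otherwise; report tables round to integer percent,
JSON keeps full precision. For binary tasks the positive class is the more
pathological of the pair (severity order H < AK < CNI < BCC < CI < SCC) and
Se, Sp and (Se+Sp)/2 are reported. Classes absent from a slice are excluded
from the recall mean rather than counted as zero.

## Synthetic generator

The generator reproduces the *structure* of the clinical dataset, not its
spectra. Defaults are the study design: 131 patients carrying 218 lesions
(round-robin, so some patients carry two), lesional class counts assigned by
largest-remainder quota from the mix BCC:SCC:AK = 90:57:96, invasive
fractions ≈0.52 (BCC) and ≈0.78 (SCC), five sites per lesion, 24 channels,
3 repeats. Spectral shapes are deliberately schematic: AF channels are sums
of three Gaussian emission bands (440/500/520 nm — structural proteins and
flavins) whose amplitudes shift with class; DR channels are a decreasing
scattering baseline times exp(−absorption) with hemoglobin-like dips at
542/577 nm whose depth shifts with class; a fixed geometric attenuation of
0.65 per SDS step carries no class information. `effect_size` scales all
class shifts; 0 makes classes exactly indistinguishable.

Stochastic layers, each on its own seeded stream so the cohort design is
invariant to which channels are generated:

* patient gain — log-normal, SD 0.3 (inter-patient intensity variability);
* per-site biological heterogeneity — relative SD 0.15 on band amplitudes
  and dip depths, shared by all of a site's repeats and channels. Without
  it every channel separates the classes almost perfectly, which real
  multiclass skin spectra do not; with it single-channel four-class balanced
  accuracies land in the 50–60% range and fusion adds a few points, the
  qualitatively realistic regime;
* multiplicative measurement noise per wavelength (relative SD 0.02), dark
  counts (mean 50, 5% jitter) and impulse spikes (rate 1e-3);
* injected replicate outliers (rate 0.05 per trio): one repeat scaled by a
  gain factor drawn outside [0.5, 2], or replaced by a flat low trace
  emulating probe lift-off; the affected trios are recorded so the screen's
  recall and clean-retention can be scored exactly.

What passing tests therefore show: the pipeline's bookkeeping, leakage
hygiene, screening behavior and fusion logic are correct, and classification
recovers signal exactly when the generator encodes it (perfect separation at
large effect and zero noise; chance level at zero effect). What they do not
show: performance on real skin spectra, whose fluorophore chemistry,
phototype/age covariates and instrument response are far richer than three
Gaussians and two dips.

## Problem sizes

The test suite runs small cohorts (6–40 lesions, channel subsets) to keep a
full run under a minute of CV work; `scripts/acceptance.py` runs the full
218-lesion, 24-channel design with 5×5-fold CV and three fusion methods in a
few minutes on one CPU.

## Known limitations

* Invasiveness (CI/CNI) is a label-level regrouping in the generator; it
  carries no spectral contrast, so invasiveness tasks on synthetic data
  classify near chance between CI and CNI by construction.
* The autoencoder is a small fully-connected net; at the default sample
  sizes PCA is almost always the better extractor, and the adam solver may
  need more iterations than the default cap to converge fully.
* The reader targets the documented CSV schema only; it does not parse any
  instrument-native acquisition format.
* No per-patient grouping constraint is applied in CV fold construction:
  sites of one patient can appear in different folds. With strong patient
  gain effects and normalization off, this can flatter accuracy slightly;
  the default baseline normalization removes most of the shared gain.
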