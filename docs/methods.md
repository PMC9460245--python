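# Methods

This note documents the models and procedures implemented in `harpipe`, the
choices made where the design was genuinely open, and what the synthetic
evaluation does and does not demonstrate.

## Signal model and preprocessing

A recording is a matrix of T samples × C channels at a fixed rate fs with a
per-sample activity label. Denoising is a running median over a centred
window of odd length k (default 3) per channel, with edge replication so the
output length equals the input. A kernel-3 median maps any isolated
single-sample outlier to the median of its two neighbours — the spike
magnitude cannot appear in the output — while leaving locally monotone
segments untouched. The filter is stateless, so whether it runs before or
after a train/test split is immaterial.

Windows of n = round(w·fs) samples (default w = 5 s) start every
round(n·(1−overlap)) samples (default overlap 0.5). Each window takes the
modal per-sample label, ties broken by the lexicographically smallest label;
windows whose modal fraction is below the purity threshold (default 0.75)
are dropped, as is a trailing partial window. The 5 s / 50% / 0.75 defaults
suit ambulatory activity at 50 Hz; longer windows help with slow, composite
activities, so all three are per-dataset configuration knobs. Missing
samples are linearly interpolated up to 5 consecutive samples; longer gaps
are an error rather than silently fabricated data.

## Feature pool

All families are computed independently per channel of a window and
concatenated under deterministic names (`ch<j>|<family>_<stat>`); under the
defaults this is 34 features per channel: 7 statistical + 12 Hilbert–Huang +
8 Haar + 2 spectral-entropy + 5 wavelet-packet.

**Statistical (7).** n, mean, sample standard deviation (n−1 denominator),
median, mode, min, max. The mode of continuous data is taken as the centre
of the fullest of 10 equal-width bins spanning [min, max] (first bin on
ties); a constant window returns the constant.

**Empirical mode decomposition and Hilbert–Huang descriptors (12).** EMD
sifts the signal into intrinsic mode functions: envelopes are cubic splines
through the local maxima/minima with up to two extrema mirrored past each
end (suppressing spline end swings), the envelope mean is subtracted, and a
candidate IMF is accepted when the Cauchy criterion
Σ(h_prev − h_cur)²/Σ h_prev² < 0.2 holds (at most 100 sift iterations).
Decomposition stops at 8 IMFs or when the residue has fewer than 3 extrema;
the residue is recomputed by subtraction so the reconstruction identity
x = Σ IMFs + residue holds to machine precision by construction. For the
first 3 IMFs (zero-filled beyond the decomposition length) the features are
energy Σc², fraction of total signal energy, and the mean and standard
deviation of instantaneous frequency — the scaled derivative of the
unwrapped analytic-signal phase (frequency-domain one-sided doubling),
evaluated on interior samples (5% trimmed per end, where the discrete
Hilbert transform is biased).

**Haar DWT (8).** Orthonormal pairs a_k = (x_{2k}+x_{2k+1})/√2,
d_k = (x_{2k}−x_{2k+1})/√2 recursed on approximations for 3 levels
(PyWavelets `haar` with periodization, which reproduces exactly this
convention); inputs are truncated to the largest multiple of 2^levels.
Features: detail energy and detail standard deviation per level, plus final
approximation energy and mean. Coefficient energy equals input energy to
rounding error, which the tests assert at 1e−9 relative.

**Spectral entropy (2).** One-sided power spectrum excluding the DC bin,
normalized to a probability vector Q; entropy Σ Q log(1/Q) in nats with
0·log(1/0) ≡ 0, plus the log N-normalized value in [0, 1]. A flat spectrum
scores exactly 1, a bin-aligned tone exactly 0. The analysed band is the
full one-sided axis; a constant window has no normalizable spectrum and its
two entropy features are defined as 0 at the extraction layer.

**Wavelet packet entropy (5).** Full 2-level Haar packet tree (both branches
recursed), giving 4 uniform frequency bands on [0, fs/2]; features are the
normalized leaf energies and the Shannon entropy of that distribution
(0 for an all-zero or single-band signal). Node energies conserve input
energy at every level.

Energy features scale as c² under amplitude scaling while every entropy and
fraction feature is scale-invariant; the test suite asserts both, plus
bitwise determinism of extraction.

## Normalization and feature selection

Min–max normalization maps each feature to [0, 1] using extremes of the
training fold only; constant training columns map to 0.5 and test values are
clipped to [0, 1]. Fitting the extremes on the training fold (rather than
the pooled matrix) costs nothing on separable data and removes a leakage
path.

Selection trains a multinomial logistic model by shuffled minibatch SGD:
constant learning rate η = 0.01, batch size min(1000, training rows), L2
penalty 1e−4 (biases unpenalized), a stratified 10% validation split, and
early stopping after 10 epochs without validation-loss improvement, keeping
the best-validation parameters. The epoch cap is 2000: with desk-scale sets
the batch cap makes each epoch a single full-batch update, and at η = 0.01
a few hundred updates demonstrably under-fit even linearly separable data,
distorting the ranking. All randomness flows from one seed, so fits are
bit-reproducible.

Features are scored by the Euclidean norm of their weight row across
classes (bias excluded), sorted descending with name tie-breaks, and the
top k kept (integer count or ceiling of a fraction; default 0.5). The L2
penalty spreads weight evenly across duplicated or strongly correlated
columns, which stabilizes the ranking. Weight-magnitude ranking of a
softmax model is the most direct way to turn an SGD fit into a feature
subset; embedded alternatives (L1 paths, RFE, mutual information) are out
of scope.

## Classifiers

The random forest fits R = 100 (default) unlimited-depth impurity-reduction
trees, each on a bootstrap resample of the training rows (with replacement,
same size), considering √p features per split; tree construction is
delegated to scikit-learn with per-tree seeds derived from the run seed.
Prediction averages per-tree class-indicator votes — the probability of a
class is its vote share — and takes the argmax, ties to the smallest class
index. This makes single-tree probabilities one-hot and keeps the ensemble
rule explicit rather than inheriting scikit-learn's leaf-posterior
averaging. Baselines: SVC with RBF kernel (C = 1, bandwidth 1/(p·var),
Platt-scaled probabilities) and AdaBoost over 100 depth-1 trees. Baseline
hyperparameters are deliberately stock; no tuning is performed.

## Evaluation

LOSO cross-validation builds one fold per subject (ordered by id); the fold
partition is asserted disjoint, exhaustive and subject-pure on every run.
Denoising, segmentation and feature extraction are stateless per window and
run once; everything fitted — normalization extremes, SGD ranking, the
classifier — is fitted per fold on training rows only, and test matrices
never enter a fit call. The pooled report concatenates fold predictions
(equivalently, sums fold confusion matrices) and is the headline number;
per-fold reports are retained for dispersion. A permuted-label mode
shuffles each fold's training labels (seeded) as a chance-level control.

Metrics come from the confusion matrix in closed form: per-class precision
TP/(TP+FP) and recall TP/(TP+FN) (0 with a logged warning when the
denominator is 0), F1 as their harmonic mean, macro scores as unweighted
class means, accuracy as the trace fraction, Cohen's kappa
(p_o − p_e)/(1 − p_e) with p_e from the marginals, and the multiclass
Matthews correlation in covariance form. ROC curves are one-vs-rest over
the model's class-probability outputs with trapezoid areas. The test suite
checks all of these against an independent brute-force evaluation on random
confusion matrices at 1e−12.

## Synthetic data: what it emulates and what it does not

Each activity class is a harmonic sum Σ aₘ sin(2π f m t + φ) with per-bout
random phases, plus white Gaussian noise and a slow random-walk drift;
static postures have zero fundamental and differ only in noise level. The
default suite has six classes: sit (noise σ 0.05), stand (σ 0.2), and four
locomotion modes at fundamentals 1.0, 1.8, 2.6 and 3.4 Hz with distinct
harmonic profiles and amplitudes 1.0–1.8. Subjects apply per-channel gains
in [0.8, 1.2] and offsets in [−0.3, 0.3], so LOSO is harder than a random
split but solvable. Optional spikes (probability per sample, default off;
0.005 in the denoising study) add 10× the loudest base amplitude at
isolated rows, drawn from a random stream separate from the signal stream
so the same seed yields the identical clean signal with and without spikes.
Everything is a deterministic function of one seed.

This family makes every feature domain informative (band energies and
instantaneous frequencies separate the locomotion modes, variance and
entropy the postures) but is deliberately idealized: no transitions within
a bout, no orientation changes, no class overlap, no magnetometer physics,
no fall events. Passing the end-to-end study therefore shows the pipeline
is correctly wired, leak-free and able to exploit its features across
subjects — it does not predict accuracy on real benchmark recordings, where
class structure is far more ambiguous.

## Problem sizes and numerical conventions

The end-to-end study uses 8 subjects × 6 activities × 3 bouts of 10 s at
50 Hz and 3 channels (9000 samples per subject, 432 retained windows of 250
samples, 102 features before selection), sizes at which the whole study runs
in well under a minute while every stage, including LOSO with 8 folds, is
exercised at realistic dimensionality. The feature-recovery study uses 50
features (5 informative with class-shifted means at 2σ steps, 45 unit-noise)
× 300 rows × 20 seeds. Exact identities (EMD reconstruction, wavelet energy
conservation) are asserted at 1e−9 relative; metric cross-checks at 1e−12;
entropy calibration points at 1e−12. Degenerate inputs are defined, not
errors, wherever a window can legitimately produce them (constant windows →
zero entropies, empty decompositions → zero HHT features); genuinely
unusable inputs (all-zero spectrum passed directly to `spectral_entropy`,
single-class training sets, even median kernels) raise.

## Known limitations

- EMD uses the classical Cauchy stopping rule; no ensemble variants
  (EEMD/CEEMDAN), so mode mixing on intermittent signals is possible.
- Spectral entropy is not band-limited; dominant low-frequency drift can
  compress the dynamic range of the normalized value.
- The SGD ranker is linear; features informative only through interactions
  rank low even when the forest could exploit them.
- Only the generic wide/long CSV schema is supported; dataset-specific
  loaders, resampling between rates, and probability calibration are out of
  scope.
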