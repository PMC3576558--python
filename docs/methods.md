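# Methods

## Signal model and preprocessing

A recording is a pair of acceleration series (anterior–posterior and
superior–inferior, anterior/superior positive) in arbitrary device units,
with a sampling rate carried in a JSON sidecar (acquisition default
10 kHz, analog bandpass 0.1 Hz–3 kHz, 10× amplification — retained as
metadata only; the pipeline itself is rate-agnostic). The two axes are
processed independently throughout: the vibration modes propagating
anteriorly and vertically are distinct, and no cross-axis coupling is
assumed.

Three artifact-removal stages run in fixed order per axis.

**Inverse filtering.** The transmission path from larynx to skin-mounted
sensor colors the signal. We estimate a whitening FIR filter from a
swallow-free calibration segment by linear prediction (autocorrelation
method, Toeplitz solve): an AR(p) model is fit to the averaged axis
autocorrelations and the prediction-error filter [1, −a₁, …, −a_p] is
applied. Default order p = 10; the calibration segment must be at least
10p samples. When no calibration recording is supplied the filter is the
identity. This is this package's own concrete whitening design; it aims at
flattening the rest-signal spectrum, which the tests verify via spectral
flatness (geometric/arithmetic periodogram mean).

**Wavelet denoising.** Discrete Meyer ('dmey') decomposition to depth L,
soft thresholding of all detail levels at the universal threshold
λ = σ√(2 ln N) with σ = MAD(finest details)/0.6745, then reconstruction
truncated to the input length. The threshold is data-driven, so all-zero
and constant inputs pass through (constants live in the approximation
band; the 62-tap FIR Meyer approximation reconstructs them to ~10⁻⁶
relative at the series boundaries, which is why the pass-through test
uses a 10⁻⁴ relative tolerance rather than machine epsilon). The
precondition is N ≥ 2^L; PyWavelets' "maximum useful level" warning,
which keys on the long dmey filter rather than on this bound, is
suppressed inside the wrapper.

**Spline detrend.** Head motion contributes drift well below the swallow
vibration band. A least-squares cubic spline with uniform interior knots
(default spacing 0.5 s) is fit and subtracted. The spline space contains
all cubic polynomials, so polynomial trends are annihilated exactly
(tested to 10⁻⁸ relative); a 0.5 Hz drift is removed to <10% residual
RMS while a 50 Hz burst loses <5% of its 45–55 Hz band energy. Knot
spacing is the one tunable: halving it tracks faster drift but begins to
absorb sub-2 Hz signal.

Decomposition depth for both denoising and features defaults to
round(log₂(fs/10)) — L = 10 at 10 kHz, L = 7 at 1 kHz — placing the
approximation band below ~5 Hz so residual drift energy stays out of the
vibration-band features.

## Segmentation

Subswallow boundaries are always explicit inputs (clinically they are read
off concurrent videofluoroscopy, from bolus-head arrival at the mandibular
ramus to lowest hyoid position); an automatic detector would have no
ground truth to be tested against and is deliberately out of scope.
Boundaries in seconds map to half-open sample windows
[floor(start·fs), floor(end·fs)), so contiguous subswallows partition
their samples with no overlap or gap. The product t·fs is rounded to
10⁻⁶ before flooring: binary floating point makes e.g. 2.3 × 10 =
22.999999999999996, and without the guard the stated convention would be
unstable to representation noise.

## Features

Per axis: relative dyadic wavelet-band energies p_j (L detail levels,
finest first, plus the approximation band; they sum to 1), log total
energy, and wavelet entropy H = −Σ p_j ln p_j ∈ [0, ln(L+1)]. Clip
duration in seconds is appended once, giving 2(L+3)+1 features. Energy
fractions and entropy are scale-invariant, so the classifier is
insensitive to per-session gain; absolute level enters only through the
log-energy term. Duration is included because swallow duration varies
systematically with patient factors (body habitus, head position, age,
sex) and carries screening-relevant signal. Zero-energy clips are
rejected as degenerate rather than assigned an arbitrary distribution.

## Classifier

Discriminant analysis on squared Mahalanobis distances
d_c(x) = (x−μ_c)ᵀ Σ_c⁻¹ (x−μ_c), computed via Cholesky factorization.
Per-class covariances (quadratic boundary) are the default reading of
class-wise Mahalanobis discrimination; a pooled covariance (linear
boundary) is available by configuration. Each covariance is shrunk
toward the scaled identity, Σ_c(γ) = (1−γ)Σ_c + γ(tr Σ_c/d)I, with
γ = 0.1 by default; shrinkage is mandatory whenever the smaller class has
fewer than 2d members, since ~20–26-dimensional features against a few
dozen unsafe swallows make raw covariances near-singular. Class priors
are equal and no log-determinant term is used: the discriminant is the
distance itself. Exact distance ties go to *unsafe* — a screening tool
should over- rather than under-flag risk.

Leave-one-out evaluation classifies each case with a model fit on all
other cases. Iteration is deterministic in key order; the result is
provably independent of order (each fold depends only on which case is
held out), which a permutation test confirms. A fold whose training set
would lose a class entirely (a class with exactly two members) is
flagged `untestable` — conservatively labeled unsafe and logged — rather
than silently dropped.

## Labels, rollup, metrics

PAS scores collapse to binary at the ≤2 / ≥3 boundary. Rollup to bolus
and participant is worst-case (unsafe iff any member unsafe); it is
idempotent, order-invariant and associative, so the resolution hierarchy
is well defined. Unsafe is the positive class of every 2×2 table —
stated here once to prevent silent transposition. Metrics with empty
denominators are reported as explicitly undefined, never 0 or 100.
Displayed percentages round half-away-from-zero; serialized output keeps
raw values. Cohen's κ on binary label vectors is included for inter-rater
agreement of the same labels the pipeline produces; the intraclass
correlation coefficient of ordinal ratings is a human-rater statistic and
out of scope.

## Synthetic cohorts

The generator emulates the screening protocol's structure: default 40
participants × 4 tasks (three teaspoons, one cup drink), each task one
bolus of 1–3 contiguous subswallows. Hierarchical labels: a participant
is unsafe with probability 0.35; each of an unsafe participant's boluses
is unsafe with probability 0.55 (so overall bolus prevalence ≈ 19%);
within an unsafe bolus each subswallow is unsafe with probability 0.85,
at least one forced — impaired boluses tend to involve multiple impaired
clean-up swallows. PAS scores are drawn uniformly within the class range
({1,2} safe, {3..8} unsafe); finer PAS structure is not modeled because
the pipeline consumes only the binary collapse.

Each subswallow window holds a burst of amplitude-modulated band-limited
noise (4th-order Butterworth, ±15% of a center frequency drawn from a
class-conditional normal), on top of recording-wide sinusoidal drift
(0.2–1 Hz, shared between axes, as head motion moves the whole sensor)
and white sensor noise. The safe class centers at 80 Hz with 15 Hz SD;
the unsafe center sits `class_separation` SDs higher (default 4 → 140
Hz), plus a mild amplitude increase (10% per separation unit) that
vanishes as separation → 0. The class difference is thus expressed
directly in the wavelet-energy space the classifier sees, and
separability is a single dial — enabling the monotone-degradation test
across separations {4, 2, 1, 0.5}. Default fs is 1 kHz for speed; 10 kHz
is available by configuration.

What the generator does **not** model: real swallow biomechanics,
burst spectra calibrated to clinical signals, covariate effects (age,
BMI, head position), inter-subswallow correlation beyond the label
hierarchy, or rater noise in PAS scores. Passing the synthetic
end-to-end tests therefore demonstrates that the pipeline's machinery is
correct and recovers a class difference of the kind it assumes — not
that it attains any particular accuracy on clinical recordings.

## Numerical and design notes

- Non-finite samples are rejected at load by default; an opt-in flag
  permits logged linear interpolation of runs ≤ 10 samples (dropouts are
  acquisition faults, not data).
- CSV signal files are written with `%.17g` and read with round-trip
  float parsing, so write→read is bit-identical.
- Problem sizes in the test suite and acceptance script: end-to-end runs
  use 40-participant cohorts at 1 kHz (~300 subswallows, ~1.5 s per run);
  the feature-level monotone-degradation check uses 300 cases per class
  per separation so binomial noise does not mask the trend.
- The classifier's behavior with very small unsafe classes is a known
  limitation: below a few dozen unsafe training cases in ~20 dimensions,
  the shrunk covariance underestimates spread along unsampled directions
  and sensitivity collapses toward zero rather than degrading gracefully.
  Pooled covariance mode mitigates this at the cost of a linear boundary.
- LOO is the only evaluation scheme offered; probability calibration,
  ROC analysis (the device result is binary), and confidence intervals
  for the screening metrics are out of scope.
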