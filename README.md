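# swallowscreen

Noninvasive aspiration screening from **dual-axis cervical accelerometry**.

Aspiration — entry of food or liquid into the airway during swallowing — is a
serious risk for people with dysphagia and often occurs silently, without
cough or other overt signs. Swallowing produces vibrations at the neck
surface, measurable with a dual-axis accelerometer in the anterior–posterior
(A–P) and superior–inferior (S–I) directions. This package implements a
signal-processing and classification pipeline that screens those recordings
for penetration–aspiration risk, for researchers in dysphagia screening and
biomedical signal processing.

## The method

For each axis of each recording:

1. **Inverse filtering** — a linear-prediction whitening FIR filter estimated
   from a swallow-free rest segment compensates device/tissue coloring.
2. **Wavelet denoising** — discrete Meyer decomposition to depth *L*, soft
   thresholding η(w) = sign(w)·max(|w|−λ, 0) at the universal threshold
   λ = σ√(2 ln N), with σ = MAD(d₁)/0.6745 from the finest detail level.
3. **Spline detrend** — a least-squares cubic spline (uniform knots, 0.5 s
   spacing) is subtracted to remove low-frequency head-motion drift.

Recordings are segmented into per-subswallow clips from externally supplied
boundary tables (in the clinical workflow these come from concurrent
videofluoroscopy). Each clip yields a fixed-length feature vector per axis:
relative dyadic wavelet-band energies p_j = E_j/E_tot, log total energy
ln E_tot, and wavelet entropy H = −Σ p_j ln p_j, plus the clip duration.

Classification is **discriminant analysis on Mahalanobis distances**: each
class c ∈ {safe, unsafe} is summarized by mean μ_c and shrinkage-regularized
covariance Σ_c, and a clip x is assigned to argmin_c (x−μ_c)ᵀΣ_c⁻¹(x−μ_c),
with distance ties resolved to *unsafe* (a screen should err toward flagging
risk). Evaluation is **leave-one-out**: every subswallow is classified by a
model trained on all the others.

Gold-standard labels come from the 8-point Penetration–Aspiration Scale
(PAS), collapsed to binary (≤2 safe vs ≥3 unsafe). Device and gold-standard
labels roll up **worst-case** from subswallows to boluses to participants,
and 2×2 contingency tables give sensitivity, specificity, NPV, PPV and
false-positive/negative rates at each resolution (unsafe is always the
positive class).

Because no clinical recordings are distributed, the package includes a
synthetic cohort generator (`swallowscreen.simulate`) producing dual-axis
recordings with class-dependent vibration bursts, head-motion drift, sensor
noise, and the cohort structure the pipeline expects (participants × 4
thin-liquid tasks × 1–3 subswallows per bolus).

## Worked example

```sh
swallowscreen simulate --out demo --seed 7 --n-participants 10
swallowscreen run --in demo --out out --seed 7
cat out/metrics.txt
```

which prints:

```
Parameter                           Per swallow         Per bolus   Per participant
Sensitivity (%)                             100               100               100
Specificity (%)                              98                97                67
Negative predictive value (%)               100               100               100
Positive predictive value (%)                94                91                88
False-positive rate (%)                       2                 3                33
False-negative rate (%)                       0                 0                 0
[swallow] n=76 unsafe=17 (TP=17 FP=1 TN=58 FN=0)
[bolus] n=40 unsafe=10 (TP=10 FP=1 TN=29 FN=0)
[participant] n=10 unsafe=7 (TP=7 FP=1 TN=2 FN=0)
```

Read: of this synthetic cohort's 76 subswallows, 17 are truly unsafe; the
leave-one-out classifier catches all 17 (100% sensitivity, 0% false
negatives) and misflags 1 of 59 safe subswallows (98% specificity). Rolled up
worst-case, all 7 unsafe participants are caught; one of the three safe
participants is misflagged, so per-participant specificity drops to 67% —
aggregation across a whole protocol trades specificity for sensitivity, as
expected of a screen.

The same pipeline is available as library calls
(`simulate_cohort`, `evaluate_cohort`, `render_report`) — see
`docs/methods.md` for the model details and parameter choices.

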