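# Methods

## The pipeline

`emdeeg` classifies binary emotional state (valence and arousal, each
binarized at the rating midpoint 5 on the 1–9 self-assessment scale) from
short multichannel EEG segments. Each 5-s, 128 Hz segment is processed
channel by channel:

1. **Empirical mode decomposition (EMD).** The signal is sifted into
   intrinsic mode functions (IMFs): at each sifting step the mean of the
   cubic-spline envelopes through the local maxima and minima is
   subtracted until the candidate satisfies the IMF admissibility
   conditions (extrema and zero-crossing counts differing by at most one;
   envelope mean near zero). IMFs come out fastest-oscillating first, and
   the IMFs plus residual sum back to the input exactly (the procedure is
   a telescoping subtraction).
2. **Per-IMF features.** Each retained IMF yields three scalars:
   `D_t`, the mean absolute first difference of its samples (time-domain
   change intensity, units of the signal); `D_p`, the mean absolute first
   difference of its unwrapped analytic (Hilbert) phase (radians/sample —
   for a narrowband component, the mean instantaneous angular frequency);
   and `log(E_norm)`, the natural log of the IMF's energy divided by the
   raw segment's energy (dimensionless weight of the component).
3. **Classification.** Feature vectors (channels × IMF levels × 3) feed a
   subject-dependent RBF-kernel SVM evaluated with leave-one-trial-out
   folds: all segments of one trial are held out per fold, which prevents
   within-trial correlation from leaking across the train/test split.
   Features are z-scored with training-fold statistics only.
4. **Channel selection.** Electrodes are ranked by the two-class Fisher
   criterion (μ₁−μ₂)²/(σ₁²+σ₂²), computed per channel per feature with
   unbiased variances over one subject's labeled segments. A named
   eight-electrode preset (Fp1, Fp2, F7, F8, T7, T8, P7, P8) is shipped
   for channel-reduced runs.

Baselines for comparison (box-counting fractal dimension, sample entropy,
db4-DWT differential entropy of the Beta/Gamma subbands) use the same
segmentation and evaluation protocol.

## Key parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `SiftConfig.sd_threshold` | 0.2 | Cauchy-type sifting stop: stop when Σm²/Σh² ≤ threshold. 0.2 is Huang's classical value. |
| `SiftConfig.zero_mean_tol` | 0.05 | envelope-mean tolerance (relative to peak) in the two-condition IMF test |
| `SiftConfig.max_sift_iterations` | 100 | hard cap; the two-condition test alone can cycle in floating point |
| `SiftConfig.max_imfs` | 5 | levels beyond 5 carry little high-frequency affect information and are wasted work; configurable |
| `SiftConfig.boundary_mode` | `mirror_extrema` | the two extrema nearest each end are mirrored across the boundary before spline fitting, the standard remedy for end swings |
| window | 5 s (640 samples) | the labeled-sample unit; 60-s trials give 12 segments |
| rating threshold | 5 | low < 5 ≤ high, on the 1–9 scale |
| SVM | RBF, C = 1, γ = 1/n_features | the classical LIBSVM defaults, pinned for reproducibility |
| SampEn | m = 2, r = 0.2·sd, N = 128 | standard physiological settings; 640-sample segments average SampEn over five non-overlapping 128-sample windows |
| FD box sizes | 2⁻¹ … 2⁻⁶ | dyadic scales on the graph normalized to the unit square |
| DWT | db4; Beta = level-2 detail, Gamma = level-1 detail at 128 Hz | bands are identified by filter level; 4–45 Hz recordings only populate the lower third of the nominal 32–64 Hz Gamma band |

## Design choices where the design was open

- **Sifting stop rule.** The qualitative two-condition IMF test is
  combined with the Cauchy SD criterion and an iteration cap; sifting of
  one IMF stops at whichever fires first. Decomposition stops when the
  residual is monotone or has fewer than three extrema.
- **Absolute first differences.** `D_t` and `D_p` use the magnitude of
  the increments. A signed mean telescopes to (last−first)/(N−1) ≈ 0 and
  cannot measure change intensity; the mean absolute first difference is
  the statistic with that meaning.
- **Phase unwrapping.** The analytic phase is the four-quadrant angle
  unwrapped along the sequence. Without unwrapping, differences at the ±π
  branch cut would be ±2π outliers and `D_p` would lose its
  instantaneous-frequency interpretation. The Hilbert transform is taken
  over the whole segment; edge distortion is accepted and quantitative
  statements are made on the interior ~80% of samples.
- **Plateau extrema.** A flat run that stands above (below) both
  neighbours contributes exactly one extremum at the floor-midpoint index
  — deterministic under ties.
- **Zero crossings.** Counted as sign changes of the nonzero samples with
  exact zeros skipped, again deterministic under ties.
- **Missing IMF levels.** If a decomposition yields fewer levels than
  requested (e.g. a pure tone has one IMF), the absent level's features
  are filled with (0, 0, log 10⁻¹²); the extreme energy value flags the
  fill and keeps vector lengths fixed.
- **Feature scaling.** Features are z-scored per fold on training
  statistics. RBF SVMs are scale sensitive and the three features live on
  different scales; fitting the scaler on the training fold only keeps the
  protocol leakage-free by construction.
- **Degenerate Fisher variance.** A within-class variance sum below 10⁻¹²
  is floored (and logged) rather than letting the score blow up, so
  rankings remain total even on pathological features.
- **t-tests.** Configuration comparisons use a two-sided *paired* t-test
  across subjects, since the same subjects underlie both conditions.
  All-zero differences return p = 1 (performance identical); constant
  nonzero differences are reported as a degenerate case rather than a
  fabricated p-value.
- **Differential entropy estimator.** The Gaussian closed form
  ½ log(2πeσ²) of the subband coefficients, the standard choice in the
  EEG differential-entropy literature.
- **DEAP label columns.** The reader defaults to the documented file
  order (valence, arousal, dominance, liking) and exposes `label_order`
  so derived files with reordered columns can be read without code
  changes.

## The synthetic generator

`SyntheticSpec`/`make_two_class_dataset` emulate the geometry of a
preprocessed affective-EEG study: by default 40 trials of 60 s at 128 Hz,
32 channels, trial-level ratings in [1, 9]. Every channel carries
1/f-shaped Gaussian background noise band-limited to 4–45 Hz (the
preprocessing band of such recordings), normalized to `noise_sd`. On the
designated informative channels, high-class trials additionally receive
flat-spectrum 16–45 Hz noise with standard deviation
`0.2 · separation · noise_sd`; low-class trials receive nothing. This
encodes the premise that the affect signal lives in the high-frequency
(Beta/Gamma) content, which EMD concentrates in IMF1. Ratings are drawn
class-first (high: uniform [5, 9); low: uniform [1, 5)) so the planted
ground truth is exact. The scale factor 0.2 was fixed once so that the
default `separation = 3.0` leaves the informative-channel IMF1 classifier
far from its error floor (empirical Bayes error well below 5%), giving
the recovery tests headroom that is attributable to the method, not the
generator.

What the generator does **not** emulate: volume conduction and
inter-channel correlation, non-stationarity within trials, artifacts
(EOG/EMG residue), subject-specific spectra, and any genuine link between
ratings and neural dynamics. Passing the recovery tests therefore shows
that the pipeline extracts planted band-power/phase-rate class structure
under realistic noise geometry — not that it reaches any particular
accuracy on real recordings.

A practical note on the evaluation floor: with balanced classes,
leave-one-trial-out sits slightly *below* 50% on label-free data (holding
a trial out makes its class the training minority — the classic
anti-learning bias of leave-one-group-out), which is why chance-level
checks use the full 40-trial design and band the mean over seeds at
40–60%.

## Problem sizes used in the shipped checks

The end-to-end checks run on reduced geometries chosen to exercise the
full protocol while keeping the suite quick on a laptop: 10-s trials
(2 segments each) instead of 60 s, 2–8 channels instead of 32, and 24–40
trials; the bookkeeping check uses the full 40 × 60 s design. Accuracy at
the default separation saturates near 100% at these sizes, so the
reduction does not weaken the conclusions the tests draw.

## Known limitations

- Plain EMD only: no ensemble or multivariate EMD variants, so mode
  mixing on intermittent signals is possible.
- Spline end swings are mitigated by extrema mirroring, not eliminated;
  the outermost samples of envelopes, phases and IMFs are less reliable.
- The DWT "Gamma" feature is a filter-level label; on 4–45 Hz band-limited
  data it measures 32–45 Hz content.
- Subject-dependent models only; no cross-subject transfer, no
  hyperparameter search, no probability calibration.
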