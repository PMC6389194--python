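# Methods

`crackletrace` reimplements an automated lung-sound analysis of cyclic
recruitment and de-recruitment of atelectasis (c-R/D) — the within-breath
opening and collapse of collapsed lung units during mechanical
ventilation — together with its 4D-CT densitometric reference and the
mixed-model validation, driven entirely by a synthetic-data generator that
emulates the porcine lavage-injury experiment the method was developed in.

## Acoustic parameters

All parameters are computed per sensor (34 active piezoelectric contact
sensors in two 3-column × 6-row thoracic arrays) on contiguous clips of
0.58 s, the frame time of the CT acquisition, and summarised over the
inspiratory phase per breath and pooled. A clip is inspiratory iff its
midpoint lies inside an annotated inspiration window. Clips lying wholly
inside the FIR settling margin (order/2 samples at each end of the record)
are flagged unreliable and excluded from aggregates.

**dCE (dynamic crackle energy).** The raw 19.2 kHz waveform is decimated
by 4 to 4800 Hz (FIR anti-aliasing, zero-phase), band-passed with a
200th-order linear-phase FIR (Hamming window design) to 600–700 Hz — the
fine-crackle band — and the RMS taken per clip. Filtering is group-delay
compensated (forward convolution, then a shift of order/2 samples) so
that a transient raises dCE only in the clip that contains it. dCE is
dimensionless (input amplitude units) and scales linearly with recording
gain.

**FFT area.** After a 75–2000 Hz band-pass, each clip's power spectral
density is estimated by Welch's method (200-sample Hamming segments, 50%
overlap, partial trailing segment discarded — 26 segments per 2784-sample
clip) and converted to dB **relative to the clip's own spectral maximum**
(peak = 0 dB). The parameter is the trapezoidal area between the dB curve
and a −70 dB floor restricted to f > 500 Hz, as a percentage of the same
area over the whole band. The per-clip peak normalisation is a design
choice: the absolute dB reference of the original device is not
recoverable, and normalisation makes the percentage bounded and exactly
gain-invariant while preserving its monotone response to crackle content.
A grid point is interpolated at the 500 Hz split so the area partition is
exact.

**SC / dSC (spectral coherence and its dynamic variation).** "Neighboring"
sensors are defined as 4-adjacent grid positions within one array (no
diagonals, no left–right pairs); pairs involving the two inactive
ambient-reference sensors are excluded. Per clip, the magnitude-squared
coherence of each pair is estimated with the same Welch segmentation,
averaged over 75–2000 Hz and over the pairs of a region of interest, and
reported on a 0–100 scale. SC is the mean and dSC the sample standard
deviation (ddof = 1; population SD available via `ddof=0`) of the
inspiratory-clip SC values. Pairs straddling a region border (rows L4–L5)
are excluded from regional series by default (`boundary="strict"`); the
alternative of assigning them to the more dependent region is available
(`boundary="lower"`). Whether the original device paired across region
borders or the body midline is unknown; neither option claims to match it.

Regions of interest: rows L1–L2 → nondependent (ventral), L3–L4 →
central, L5–L6 → dependent (dorsal); `global` pools all active sensors.
The two inactive reference positions are placed at the ventral corner of
each array (their true positions are not published).

## CT densitometry

Lung voxels (segmentation mask is an input) are classified per 0.58 s
frame into the four aeration compartments on closed integer HU intervals:
atelectatic [−300, 0], poorly aerated [−600, −301], normally aerated
[−900, −601], hyperinflated [−1024, −901]; non-integer attenuation is
rounded to the nearest integer first because the printed edges only tile
an integer grid. Masked voxels outside [−1024, 0] count toward total
imaged volume but no compartment. The lung mask is split into three
equal-thickness slabs along the gravity (dorsoventral) axis to mirror the
sensor rows.

Δatelectasis is the atelectatic volume at the last frame before
inspiration onset minus that at the last inspiratory frame (frame
midpoints define phase, consistent with the acoustic clip grid), averaged
over breaths; an extremum-based frame selection (within-breath max minus
min) is available as `mode="extremum"`. Percentages are relative to the
breath-mean total imaged volume.

## Mixed models

Acoustic parameter ~ Δatelectasis with a per-subject random intercept,
REML via `statsmodels MixedLM` (Powell-first optimiser cascade, ML
fallback on non-convergence). Both variables are standardised internally
and estimates back-transformed exactly, which makes the fit invariant to
affine rescaling of either variable and numerically robust. The figure of
merit is the marginal R²: var(fixed predictions) / (var(fixed) +
random-intercept variance + residual variance) — the fixed-effects share
of total variance. Conditional R² (fixed + random) is also reported.
Slope inference uses the normal approximation (the design here has only
6 subjects; Wald z CIs showed ~95% empirical coverage in the recovery
simulation, see `test_lmm_parameter_recovery_and_holm_oracle`).

dSC ~ region × PEEP (both categorical) with subject random intercept;
pairwise region contrasts are differences of marginal means averaged over
PEEP levels, tested by Wald z and Holm-adjusted within the three-contrast
family (the original multiple-testing family is not enumerated; we adjust
within each model's contrast family and say so in the output). Missing
design cells raise with the offending cells listed.

## Synthetic scenarios

The generator emulates the study design: 6 subjects × {healthy baseline
BLH, lavage injury LAV} × PEEP {0, 5, 10, 15} cmH₂O, 20 s records at
19.2 kHz, 6 breaths/min at I:E 1:1 (5 s inspirations starting at 2.5 s
and 12.5 s), frames every 0.58 s (34 per record).

*Recruitment.* Per region, atelectatic volume follows
V(t) = V₀ − A·(1 − e^(−t/τ)) during inspiration and relaxes back
symmetrically during expiration, with τ = 1.5 s (inside the observed
1–2 s recruitment window). LAV amplitudes A default to the published
per-region Δatelectasis means (dependent: 28.27/23.93/14.70/7.34 cm³ for
PEEP 0/5/10/15, etc.); end-expiratory baselines are the published
cycle-averaged atelectasis means plus half the swing. BLH amplitudes are
zero with a small static atelectatic rim. A per-subject log-normal
multiplier (σ = 0.25) scales LAV amplitudes, producing the
between-subject spread the random intercept absorbs.

*CT rendering.* A 20 × 20 × 24 voxel lung (295 cm³ total, voxel
≈ 0.031 cm³) is filled from the dorsal end of each gravity slab with
atelectatic-mean voxels (−150 HU) tracking the volume curve; aerated
voxels sit at −750 HU. Gaussian HU noise (default SD 30) is clipped to
the compartment interval so rendered voxels remain classifiable — the
noisy round trip therefore tests the full volumetric pipeline, not
classifier robustness to bin-crossing noise (a real scanner's partial
volume and sensor artefacts are *not* emulated).

*Acoustics.* Each sensor receives band-limited (75–2000 Hz,
spectral-mask synthesis) Gaussian breath noise shaped by a flow envelope
(unity during inspiration, 0.35 during expiration, 0.2 s ramps), mixed
from a per-region common source (weight 0.4) and an independent
component — the common source creates the neighbor-pair coherence
structure. Crackles are an inhomogeneous Poisson process with rate
coupling × max(−dV/dt, 0) summed over regions (default coupling 2
events/cm³, a free parameter — the true crackle-per-volume coupling is
unknown, so only qualitative/rank recovery is claimed, not the original
R² values). Each event is a damped 650 Hz sinusoid (90% of energy within
10 ms, amplitude 0.25 with log-normal jitter) added to sensors with
region gains 1.0 (dependent) / 0.25 (central) / 0.05 (nondependent) —
sound transmission is reduced to this gain matrix, with no wave
propagation. Crackle-rich early-inspiration clips transiently raise
dependent-region coherence, which is what gives the dependent zone its
elevated dSC.

*Seeding.* Every stream derives from (scenario seed, subject index, PEEP
index, purpose code) — never from the condition label — so a BLH and a
LAV run of the same seed with crackle coupling disabled produce
identical waveforms (a null calibration the tests assert).

What passing tests show: the estimators implement their definitions, the
CT round trip is exact to voxel quantisation, and the full pipeline
recovers a strong positive dCE–Δatelectasis relationship (dependent-zone
marginal R² ≈ 0.9) and dependent-zone dSC elevation under the published
effect sizes. What they do not show: performance under real chest-wall
acoustics, ambient noise, heart sounds, sensor artefacts, or segmentation
error, none of which the generator emulates.

## Numerical choices

- FIR order must be even (exact integer group-delay compensation);
  bands are validated against Nyquist.
- Zero clips yield a −∞ dB spectrum and an FFT area of 0; zero-variance
  inputs to coherence raise (undefined quantity).
- Welch frequency grid spacing is fs/200 = 24 Hz; band selections use
  closed intervals.
- The per-clip coherence path vectorises segment FFTs across channels and
  pairs; it is asserted equal (to 1e−9) to `scipy.signal.coherence` per
  pair.
- Problem sizes in tests and the acceptance script (20 s records, 34
  sensors, 34 frames of a 9600-voxel lung, 200 simulation replicates)
  were chosen to exercise the full design grid at desk scale.
- CSV outputs use %.9g formatting; the pipeline manifest records SHA-256
  hashes, and re-running an identical configuration reproduces
  byte-identical CSVs.

## Known limitations

- The absolute dB reference of the original FFT-area device is unknown;
  our per-clip normalisation changes absolute percentages (not their
  ordering), so printed FFT-area magnitudes are not directly comparable.
- With 6 subjects, Wald-z inference is approximate; no Satterthwaite
  degrees of freedom are available through the fitting backend, and
  contrast p-values at large effect sizes should be read as "very small"
  rather than literally.
- The crackle–volume coupling and the acoustic mixing weights are
  free parameters of the generator, not measured quantities.
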