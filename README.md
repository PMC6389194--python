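# crackletrace

Automated lung-sound analysis of **cyclic recruitment and de-recruitment
of atelectasis (c-R/D)** — the within-breath opening and collapse of
collapsed lung units during mechanical ventilation — validated against
4D-CT densitometry.

c-R/D ("atelectrauma") is a driver of ventilator-induced lung injury, but
there is no bedside tool to detect it. Because the sudden opening of
collapsed airways emits *fine crackles* (short explosive sounds centred
near 650 Hz), multi-sensor thoracic sound recordings carry a usable
signature. This package implements the complete analysis chain:

- **dCE** (dynamic crackle energy): per-clip RMS of the 600–700 Hz
  band-passed signal (200th-order FIR at 4800 Hz), the crackle-band
  energy over the inspiratory cycle;
- **FFT area**: percentage of the supra-threshold (> −70 dB, per-clip
  peak-normalised) Welch spectral area lying above 500 Hz;
- **SC / dSC**: mean magnitude-squared coherence of neighbouring-sensor
  pairs over 75–2000 Hz (0–100 scale) and its standard deviation across
  inspiratory clips — dSC localises where recruitment happens;
- **4D-CT reference**: Hounsfield-unit compartment volumetry
  (atelectatic −300…0 HU, poorly −600…−301, normal −900…−601,
  hyperinflated −1024…−901) per 0.58 s frame, and
  **Δatelectasis** = end-expiratory − end-inspiratory atelectatic volume;
- **validation**: linear mixed models (subject random intercept) of each
  acoustic parameter on Δatelectasis with marginal R², and a
  region × PEEP model for dSC with Holm-adjusted contrasts;
- **synthetic scenarios**: a seeded generator emulating the porcine
  lavage experiment (6 subjects × healthy/injured × PEEP 0/5/10/15
  cmH₂O) that couples recruiting HU volumes to Poisson crackle trains,
  so the whole pipeline is testable without animal data.

All analyses run per sensor (34 active sensors in two 3 × 6 thoracic
arrays) in 0.58 s clips matched to the CT frame time, and are pooled over
the inspiratory phase globally and for nondependent / central / dependent
lung zones. See `docs/methods.md` for the model details and design
choices.

## Worked example

Generate one injured-lung cell (1 subject, PEEP 0), run the full analysis
and pair it with the CT reference:

```python
import crackletrace as ct
from crackletrace import pipeline

cfg = ct.ScenarioConfig(seed=1, n_subjects=1, conditions=("LAV",),
                        peep_levels=(0,))
item = next(ct.generate_scenario(cfg))
rows = pipeline.analyze_item(item)
for r in rows:
    print(f"{r['roi']:>12}  dAtel {r['delta_atelectasis']:6.2f} cm3  "
          f"dCE {r['dce']:.4f}  FFTarea {r['fft_area']:5.1f}%  "
          f"SC {r['sc']:5.1f}  dSC {r['dsc']:.2f}")
```

```
nondependent  dAtel   1.41 cm3  dCE 0.0101  FFTarea  78.7%  SC  19.2  dSC 0.94
     central  dAtel   6.67 cm3  dCE 0.0133  FFTarea  78.7%  SC  20.6  dSC 1.23
   dependent  dAtel  24.69 cm3  dCE 0.0333  FFTarea  78.8%  SC  26.9  dSC 4.58
      global  dAtel  32.77 cm3  dCE 0.0194  FFTarea  78.8%  SC  18.5  dSC 1.89
```

Reading this: at zero PEEP the injured lung cycles ~25 cm³ of dependent
atelectasis per breath; the crackle-band energy (dCE) of the dependent
sensors is ~3.3× the nondependent floor, and the dependent zone shows the
largest clip-to-clip coherence variation (dSC), localising the
recruitment. On the full 6-subject × 4-PEEP grid the mixed model of
dependent-zone dCE on Δatelectasis attains a marginal R² ≈ 0.91.

The same stages are available from the shell:

```sh
crackletrace synth --seed 1 --config scenario.yaml --out data/
crackletrace acoustics --input data/s0_LAV_peep0.wav \
    --sidecar data/s0_LAV_peep0.yaml --out results/ac/
crackletrace ctvol --frames data/s0_LAV_peep0_ct.nii.gz \
    --mask data/s0_LAV_peep0_mask.nii.gz \
    --breaths data/s0_LAV_peep0_breaths.yaml --out results/cv/
crackletrace correlate --table joined.csv --out results/stats/
crackletrace all --seed 1 --out results/full/   # chains everything + manifest
```

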