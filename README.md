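# teptools

Simulation and analysis of TMS-evoked EEG potentials (TEPs) for
cortical-excitability studies.

Combined TMS-EEG tracks how a neuromodulation protocol (here: cathodal
tDCS over the posterior parietal cortex) changes cortical excitability:
single TMS pulses probe the cortex before, during and after stimulation
while high-density EEG records the evoked response.  `teptools`
implements the full analysis chain for such pre/during/post designs, plus
a synthetic session generator with known ground truth so every stage can
be validated without any recorded data:

- **Sensor level** — epoch preprocessing (downsampling to 725 Hz,
  deterministic artifact rejection, 2–40 Hz zero-phase filtering,
  spherical-spline interpolation of missing channels, average reference,
  −300..−50 ms baseline) and global / local mean field power

  `GMFP(t) = sqrt( (1/K) Σ_k (V_k(t) − V̄(t))² )`

  cumulated over the 0–50, 50–100 and 100–150 ms windows, globally and in
  four 4-electrode clusters (left/right parietal and frontal).
- **Source level** — an exact multilayer concentric-sphere forward model
  (Legendre series), a depth-weighted minimum-norm inverse with Gaussian
  smoothness prior `K = R Lᵀ (L R Lᵀ + λ²C)⁻¹`, a max-statistic sign-flip
  permutation threshold against pre-pulse baseline noise, and the
  Significant Current Density (SCD) cumulated globally and within
  left/right BA6/BA7-like parcels.
- **Inference** — per window × scope linear mixed models fitted by
  maximum likelihood (`value ~ condition + (1|subject)` vs the
  intercept-only null), the likelihood-ratio test `χ² = 2(ℓ₁−ℓ₀)` on 2 df,
  and the BIC Bayes factor `BF01 = exp((BIC₁−BIC₀)/2)` quantifying
  support for *no* condition effect — the pattern of interest when a
  protocol leaves excitability unchanged.
- **Simulation harnesses** — condition-gain scenarios with full
  determinism, used to measure type-I error, power and family-wise error
  calibration of the whole chain.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from teptools import (build_montage, build_sphere_model, build_source_space,
                      lead_field, sample_subject, simulate_block,
                      gmfp, cumulate, validate_tdcs_montage)
from teptools.preprocess import preprocess_evoked

montage = build_montage()                       # 60-channel 10-10 cap
sphere = build_sphere_model()                   # 92/85/81 mm shells
space = build_source_space(n_sources=812)       # reduced cortical grid
L = lead_field(sphere, montage, space)

subject = sample_subject(seed=1)                # draw one subject
epochs = simulate_block(subject, gain=1.0, leadfield=L, n_trials=60,
                        rng=np.random.default_rng(0))
tep, report = preprocess_evoked(epochs, montage)
print(f"retained {int(report['kept'].sum())}/{len(report)} trials")

trace = gmfp(tep)
for window in ((0, 50), (50, 100), (100, 150)):
    print(f"GMFP {window[0]:>3}-{window[1]:<3} ms: "
          f"{cumulate(trace, window):7.2f} uV*ms")

cathode, anode = validate_tdcs_montage(0.75, 9.0, 25.0)
print(f"cathode density {cathode.current_density} mA/cm^2, "
      f"anode density {anode.current_density} mA/cm^2")
```

prints

```
retained 42/60 trials
GMFP   0-50  ms:   66.36 uV*ms
GMFP  50-100 ms:   65.28 uV*ms
GMFP 100-150 ms:   62.16 uV*ms
cathode density 0.08 mA/cm^2, anode density 0.03 mA/cm^2
```

The rejection step removed the simulated artifact trials (the generator's
default artifact rate is 0.3, so ~70% of trials survive); the cumulated
GMFP values are the per-window excitability indices that feed the mixed
models, and the tDCS check reproduces the protocol's electrode current
densities (0.75 mA through a 9 cm² cathode and 25 cm² anode).

A whole experiment — 15 subjects × 3 conditions, field power, source SCD
and all condition tests — runs from a single config:

```bash
teptools run-all --reduced --outdir out/
teptools check-montage
teptools --help          # simulate / preprocess / fieldpower / source / stats
```

Every run writes tidy CSV tables (`fieldpower.csv`, `scd.csv`,
`stats.csv`), a JSON manifest (config hash, seed, versions) and a log;
identical config + seed reproduces the outputs bit-for-bit.

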