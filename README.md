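# fnirspipe

Analysis pipeline for **single-channel, two-wavelength functional
near-infrared spectroscopy (fNIRS)** recordings of the kind produced by
low-cost open-hardware devices (one LED pair at 660/880 nm over the left
dorsolateral prefrontal cortex, one photodiode), together with a forward
simulator that generates raw recordings with exact ground truth so the whole
chain can be validated without hardware.

It is written for researchers evaluating low-cost optical neuroimaging:
every stage is a plain function over explicit containers, every output file
carries its parameters, and every claim the pipeline makes can be checked
against simulated truth.

## The analysis chain

1. **Optical density.** Raw intensity `I(t)` per wavelength is converted to
   optical density, `OD(t) = -log10(I(t)/I0)`, with `I0` the mean intensity
   over the recording.
2. **Motion-artifact detection.** A sliding 0.2 s window flags abrupt OD
   excursions exceeding either an absolute threshold (0.3 OD) or 10x a
   robust scale (1.4826 x MAD) of the first differences; flags are dilated
   by ±0.1 s and pooled across wavelengths.
3. **Spline correction.** Inside each flagged segment a cubic smoothing
   spline (smoothing parameter 0.99) is fit and subtracted; segments are
   re-leveled to the surrounding clean signal, removing spikes and
   persistent baseline steps (MARA-style).
4. **Band-pass.** Zero-phase 3rd-order Butterworth, 0.01–0.1 Hz, applied
   forward–backward, isolating the hemodynamic band.
5. **Modified Beer–Lambert law.** Per sample,
   `dOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)` is inverted as a 2×2
   linear system (ε from a shipped extinction table; d = 3 cm, DPF = 6 by
   default), yielding ΔHbO/ΔHbR in mol/L.
6. **Block analysis.** Task-locked epochs, baseline correction, pointwise
   block average ± SEM, and per-run task/rest scalar means.
7. **Statistics & SNR.** Paired-samples t-test
   `t = mean(d)/(sd(d)/√n)` with paired Cohen's `d = t/√n`, and a per-task
   signal-to-noise ratio (evoked peak-to-peak over rest-residual SD).

The simulator inverts this chain: a double-gamma HRF convolved with the
block design gives true ΔHbO/ΔHbR; the forward Beer–Lambert map gives clean
OD; cardiac (1.1 Hz), respiratory (0.3 Hz) and Mayer-wave (0.1 Hz)
oscillations, drift, sensor noise and spike/step motion artifacts are added
in OD space; intensity is derived last as `I = I0·10^(-OD)`.

## Worked example

```bash
fnirspipe run --paradigm finger_tapping --seed 3 --out out/
```

simulates a 165 s finger-tapping session (5 blocks of 15 s rest / 15 s
tapping at 10 Hz), runs the full chain and prints:

```
recovery ratio 1.0075, SNR 18.478; outputs in out/
```

i.e. the pipeline recovered the injected evoked ΔHbO amplitude to within
0.8 %, and the task-evoked response is ~18x the rest-period residual
variability.
`out/` contains the resolved config, the raw recording and markers, each
preprocessing stage, ΔHbO/ΔHbR, the block-average curve and a text report.

The same chain is available stage by stage (`fnirspipe simulate |
preprocess | analyze | report`) and as a library:

```python
import fnirspipe as fp

cfg = fp.SimulationConfig.for_paradigm("nback1", seed=1)
rec, truth = fp.simulate_recording(cfg)
od = fp.intensity_to_od(rec)
mask = fp.detect_motion(od)
filtered = fp.bandpass(fp.spline_correct(od, mask))
conc = fp.od_to_concentration(filtered)
```

The numbered scripts under `analysis/` reproduce the full study workflow on
synthetic cohorts (session simulation, preprocessing and block averages,
group-level paired tests and SNR); they write tables under `results/`.

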