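# mousecmr

Self-gated, SENSE-accelerated cardiac cine MRI of the mouse heart — an
end-to-end synthetic pipeline for method development and validation.

Cardiac MRI in mice is hard: the heart beats at 400–550 bpm, the animal
breathes at 60–150 breaths/min, and ECG-free (self-gated) cine protocols
compensate by acquiring continuously for many minutes and sorting k-space
lines into cardiac phases afterwards. Parallel imaging (SENSE) can cut
those long scans by 2–3×, at the price of spatially varying noise
amplification — so the question any small-animal imaging lab has to answer
is whether accelerated self-gated cines still support accurate
left-ventricular (LV) function measurements. `mousecmr` provides a fully
synthetic, ground-truth-controlled version of that entire experiment:

- **`phantom`** — a dynamic digital mouse heart (short-axis LV/RV stack,
  sinusoidal contraction hitting an exact ejection fraction, respiratory
  translation, infarct variant with sector wall thinning and cavity
  dilation), a cylindrical 4-element receive array, and a simulated
  Cartesian FLASH acquisition with a navigator echo per TR and correlated
  multi-coil noise. Cavity volumes, LV mass and wall thickness all have
  closed forms.
- **`selfgating`** — band-pass separation of the navigator into cardiac
  (5–12 Hz) and respiratory (0.5–3 Hz) waveforms, trigger picking,
  retrospective assignment of every line to one of 10 cardiac frames or a
  respiratory reject frame, and complex-averaged binning with
  nearest-phase completion of empty bins.
- **`recon`** — coil sensitivity maps from a low-resolution calibration
  scan (sum-of-squares reference, noise-adaptive signal mask
  τ = MEAN + f·SD, region-growing extrapolation), and regularized SENSE:
  per readout column, solve (EᴴΨ⁻¹E + λI)x = EᴴΨ⁻¹y with the coil noise
  covariance Ψ applied by pre-whitening. Uniform integer undersampling
  uses the classic aliasing-group unfolding; arbitrary (fractional-R)
  patterns use the general per-column solve. Geometry-factor maps
  g = √([(EᴴΨ⁻¹E)⁻¹]ₚₚ·[EᴴΨ⁻¹E]ₚₚ) quantify the noise amplification.
- **`lvfunc`** — threshold segmentation at τ = 0.6·MEAN(S_LV) over a
  cavity+wall ROI, EDV/ESV/SV/EF by voxel counting × voxel volume, LV
  mass via the 1.05 mg/mm³ specific gravity of myocardium, wall–cavity
  contrast-to-noise ratio, radial wall-thickness profiles every 15°, and
  the cohort statistics ΔP_LV = (100/N)·Σᵢ|P_R,i − P_1.0,i|/P_1.0,i and
  cross-sectional-area regression.
- **`pipeline` / `cli`** — protocol handling and scan-time accounting
  (floor(N_pe/R) lines × TR × NR × slices), HDF5 k-space containers,
  NIfTI cine output, YAML configuration, cohort studies, and the `mcs`
  command line tool.

## Worked example

One simulated subject, processed fully sampled and 3×-accelerated:

```python
from mousecmr.pipeline import RunConfig, run_subject, study_protocol, subject_phantom
from mousecmr.phantom import compute_ground_truth

phantom = subject_phantom(1)                     # jittered healthy anatomy
truth = compute_ground_truth(phantom, 40)
print(f"analytic truth: EDV {truth.edv_ul:.1f} ul  ESV {truth.esv_ul:.1f} ul  "
      f"EF {truth.ef_percent:.1f} %")
for r in (1.0, 3.0):
    cfg = RunConfig(phantom=phantom, protocol=study_protocol(acceleration=r))
    fn = run_subject(cfg, seed=phantom.seed).function
    print(f"R={r:.1f}: EDV {fn['EDV']:.1f} ul  ESV {fn['ESV']:.1f} ul  "
          f"SV {fn['SV']:.1f} ul  EF {fn['EF']:.1f} %")
```

prints

```
analytic truth: EDV 45.2 ul  ESV 13.0 ul  EF 71.2 %
R=1.0: EDV 40.7 ul  ESV 12.3 ul  SV 28.4 ul  EF 69.8 %
R=3.0: EDV 40.6 ul  ESV 12.0 ul  SV 28.6 ul  EF 70.5 %
```

The accelerated measurement agrees with the fully sampled reference to
within ~1–2% on every parameter, while both share the small systematic
offset from the analytic truth that the fixed 0.6 threshold factor
introduces at this voxel size (see `docs/methods.md`). Scan-time
accounting for the in vivo short-axis protocol:

```
$ mcs scantime -R 1 -R 3
R=1.0: 154 lines/slice/repetition, 18.7 min
R=3.0: 51 lines/slice/repetition, 6.2 min
```

The full file-based pipeline (HDF5 k-space → gating CSV → cine NIfTI with
g-factor maps → function/CNR/wall-profile tables) runs as

```bash
mcs run --config demo.yaml --seed 7 --out run_dir/
```

and is deterministic for a fixed config and seed.

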