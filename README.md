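# spindletrack

Automated detection, sub-pixel model-based fitting, and tracking of
fluorescent microtubules and spindles in 3D live-cell image stacks.

Fluorescently labelled tubulin renders microtubules as diffraction-limited
Gaussian *lines* (and, when bent, *curves*), and spindle pole bodies as
Gaussian *spots*.  At the signal-to-noise ratios typical of live yeast
imaging, thresholding-based analysis fails and microtubules are still often
traced by hand.  `spindletrack` instead fits an explicit intensity model to
each 3D frame,

```
F_θ(x, y, z) = B0 + Σ f_θ(x, y, z),
```

where each feature `f_θ` is a 3D Gaussian spot
(`A e^{−((x−x0)/σx)² − ((y−y0)/σy)² − ((z−z0)/σz)²}`, 7 parameters), a point
Gaussian integrated along a straight segment (10 parameters), or a point
Gaussian integrated along a curved centerline whose planar curvature is a
truncated Fourier series `K(t) = k0 + Σ p_i cos(iwt) + q_i sin(iwt)`
(15 parameters at two Fourier terms).  Geometry scanning produces initial
guesses (pole finding on the maximum intensity projection, angular
intensity profiles `I(φ)` for radiating microtubules, principal-axis
analysis for bipolar spindles, ridge tracing for curved filaments); bounded
trust-region least squares then optimizes all parameters against the raw
voxels, and the number of microtubules is itself optimized with a
nested-model F-test.  Fitted features are linked through time by linear
assignment, short-lived (spurious) features are discarded, and length-vs-
time series yield dynamic-instability statistics (polymerization and
depolymerization speeds, growth before catastrophe).

A built-in simulator renders monopolar, bipolar, and astral spindle
geometries with ground truth and noise calibrated to a target SNR (defined
as background-subtracted mean microtubule intensity over the image
median), so the whole pipeline can be validated quantitatively: at what
SNR are microtubules reliably found, and how accurately are their tips
placed?  See `docs/methods.md` for the full model and algorithm notes.

The package is aimed at quantitative cell biologists working with yeast
spindles (monopolar mutants, anaphase spindles, curved astral
microtubules) and at anyone needing model-based curvilinear feature
fitting in anisotropic 3D stacks.

## Worked example

```python
from spindletrack import (
    SimulationConfig, simulate_image, analyze_frame,
    classify_detections, position_errors,
)

cfg = SimulationConfig(seed=11, target_snr=3.0)   # monopolar spindle phantom
stack, truth = simulate_image(cfg)
print(f"simulated {len(truth.microtubules)} microtubules, "
      f"realized SNR {truth.realized_snr:.2f}")

result = analyze_frame(stack, structure="monopolar")
for mt in result.model.microtubules():
    print(f"  tip ({mt.tip[0]:.2f}, {mt.tip[1]:.2f}, {mt.tip[2]:.2f}) um, "
          f"length {mt.length:.2f} um")

report = classify_detections(result.model.features, truth, match_radius=0.5)
errors = position_errors(report, cfg.voxel_size)
print(f"correct {report.n_correct}/{report.n_truth}, "
      f"spurious {report.n_spurious}")
print(f"mean 3D tip error {errors['err_3d_px'].mean():.2f} px")
```

prints

```
simulated 5 microtubules, realized SNR 3.00
  tip (4.94, 5.27, 1.84) um, length 2.94 um
  tip (1.78, 4.48, 1.99) um, length 1.60 um
  tip (2.13, 1.67, 2.10) um, length 1.87 um
  tip (4.67, 5.45, 1.44) um, length 2.74 um
  tip (2.89, 4.04, 1.89) um, length 0.64 um
correct 5/5, spurious 0
mean 3D tip error 0.29 px
```

All five simulated microtubules are recovered with tips matched to the
truth within the 0.5 µm criterion, and the average 3D tip error — the
Euclidean norm of the per-axis errors in pixel units (0.1 µm in XY,
0.5 µm in Z) — is well below one pixel: sub-pixel localization at SNR 3.

## Command line

```sh
spindletrack simulate --structure monopolar --snr 1.25 --seed 7 --output sim/
spindletrack fit      --input movie.tif --structure monopolar --output run/
spindletrack track    --input run/frames.json --output tracks.csv
spindletrack dynamics --input run/tracks.csv --output events.csv
spindletrack validate --snr 1.25 --snr 3.0 --reps 20 --seed 1
```

`fit` runs the full per-frame pipeline (detect → local fits → global fit →
feature-count selection) and then tracks; `validate` runs the simulation
benchmark over an SNR grid and writes a per-level table of detection rates
and localization errors.

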