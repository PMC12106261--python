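# leadspect

Quantitative gamma-camera imaging analysis for the **²⁰³Pb/²¹²Pb theragnostic
pair**, aimed at medical physicists evaluating SPECT/CT protocols for
lead-based targeted alpha therapy. ²⁰³Pb (t½ = 51.9 h, 279 keV) serves as the
imaging surrogate; ²¹²Pb (t½ = 10.6 h, 239 keV) is the therapy nuclide whose
high-energy daughter emissions (up to 2.6 MeV from ²⁰⁸Tl) cause severe
detector dead time and septal penetration.

The package implements the full phantom analysis chain:

* **Dead time.** The paralyzable detector model
  `C(A) = α · A · exp(−τ · α · A)`, with nonlinear fitting (parameterized in
  the decorrelated product τα), exclusion of post-peak measurements, and
  closed-form inversion to the peak activity `A_peak = 1/(τα)` and the
  activity at fractional count loss f, `A_f = −ln(1 − f)/(τα)`.
* **Scatter.** Triple-energy-window (TEW) correction
  `S = (C_low/w_low + C_up/w_up) · w_peak/2`, per voxel or per VOI, with the
  camera's energy-window sets (photopeak ±10%, scatter-window widths as
  percentages of the photopeak center).
* **NEMA IQ phantom metrics.** Deterministic digital NEMA image-quality
  phantom (six spheres 10–37 mm, cold lung insert, torso background) and its
  full VOI scheme (6 sphere VOIs, 72 background spheres, 3 background
  cylinders, lung VOI); contrast recovery `CRC = 100·(N̄_S/N̄_BG − 1)/(R − 1)`,
  contrast-to-noise `CNR = (N̄_S − N̄_BG)/σ_BG`, background noise CV_BG, lung
  count error ΔN_Lung, and spatial resolution via a closed-form
  ball⊗Gaussian radial-profile fit (FWHM = 2√(2 ln 2)·σ).
* **Quantification.** Calibration factor `CF = N_VOI/(V_VOI · t · Ā)` from a
  5650 ml uniform cylinder and recovery coefficients
  `RC = Ā_SPECT/Ā_true` per sphere and for the background.
* **Synthetic data.** A seeded generator producing count-rate series, planar
  views and reconstructed-like SPECT volumes with Gaussian blur,
  scatter/penetration background, global dead-time loss and Poisson noise —
  the test bed standing in for scanner data.

## Worked example

Fit the dead-time behaviour of the ²¹²Pb / high-energy-collimator / 239 keV
protocol from a simulated count-rate experiment (12 activities between 5 and
290 MBq, 2 min per point):

```python
import numpy as np
from leadspect import (ImagingSystemModel, simulate_count_rate_series,
                       fit_pdm, activity_at_loss, activity_at_peak)

model = ImagingSystemModel.for_setup("Pb-212", "HE", 239)
activities = np.geomspace(5, 290, 12)
series = simulate_count_rate_series(model, activities, 120.0, seed=1)
fit = fit_pdm(series)
print(f"alpha       = {fit.alpha_cps_per_mbq:.1f} cps/MBq")
print(f"tau*alpha   = {fit.tau_alpha_per_mbq:.6f} 1/MBq  (tau = {fit.tau_s*1e6:.2f} us)")
print(f"A_peak      = {activity_at_peak(fit):.1f} MBq")
print(f"A(10% loss) = {activity_at_loss(fit, 0.10):.1f} MBq")
print(f"A(20% loss) = {activity_at_loss(fit, 0.20):.1f} MBq")
```

prints

```
alpha       = 622.4 cps/MBq
tau*alpha   = 0.005179 1/MBq  (tau = 8.32 us)
A_peak      = 193.1 MBq
A(10% loss) = 20.3 MBq
A(20% loss) = 43.1 MBq
```

The fitted curve peaks at 193 MBq: above that activity the camera records
*fewer* counts as activity grows. One fifth of all counts are already lost
at 43 MBq — far below typical ²¹²Pb therapy activities, which is why
post-treatment quantitative imaging of ²¹²Pb needs dead-time correction.
The point above the peak (index 11) was automatically excluded from the fit.

The same workflows are available from the shell:

```bash
leadspect simulate --nuclide Pb-212 --collimator HE --window 239 \
    --setup contrast-8to1 --seed 1 --out runs/nema
leadspect fit-deadtime series.csv --out fit.json
leadspect calibrate runs/cylinder --out cf.json
leadspect analyze-iq runs/nema --calibration cf.json --out runs/iq
```

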