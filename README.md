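# phantomwaxs

X-ray scattering through thick tissue phantoms: Monte Carlo photon
transport with molecular form factors, detector-image reduction to I(q),
and the peak/attenuation analyses that decide whether diffraction
biomarkers survive centimetres of tissue.

## The problem

Wide-angle X-ray scattering of adipose tissue shows a reflection near
**q = 14.5 nm⁻¹** (momentum transfer q = 4π sin θ/λ, 2θ the scattering
angle) produced by the inter-fatty-acid molecular spacing.  Its
intensity is a candidate structural biomarker: it changes when lipid
metabolism changes.  Measurements are routine on millimetre biopsy
samples; a diagnostic measurement through a whole organ is another
matter — photons are absorbed, scatter multiple times, and photons
scattered at the same angle from different depths land at different
radii, broadening every peak.  This package provides the simulation and
analysis machinery to quantify those effects for tissue phantoms up to
10 cm thick, probed with a 22 keV (silver-anode) pencil beam and a
768 × 512 pixel detector (135 μm pitch) whose edge the beam grazes
about 70 cm downstream.

Three analyses sit at the core:

* **scatter multiplicity** — classify detected photons by how often they
  scattered (and by which process: Rayleigh carries the diffraction
  signal, Compton is background);
* **peak broadening** — fit the fat peak width σ(t) per thickness t and
  compare with the closed-form geometric prediction
  σ(t)² = σ₀² + (q₀t)²/(12·D_eff²), D_eff = platform − t/2;
* **attenuation** — Beer–Lambert fit I₀·e^(−μd) to the intensity
  integrated below q = 3 nm⁻¹.

The reduction chain is standard powder-diffraction practice: silver
behenate ring calibration (d001 = 5.838 nm) for beam centre and
sample-to-detector distance, per-pixel q = (4π/λ)·sin(atan(r/D)/2),
azimuthal averaging with non-destructive beam-stop masks, replicate
averaging, and window normalisation.  See `docs/methods.md` for the
model in full.

## Worked example

```python
import numpy as np
from phantomwaxs import (
    PhantomGeometry, SimulationConfig, run_simulation, accumulate_image,
    CalibrationResult, azimuthal_integrate, fit_gaussian_peaks,
    classify_detected_events, single_scatter_share, wavelength_nm,
)

cfg = SimulationConfig(phantom=PhantomGeometry(thickness_cm=4.0),
                       n_photons=2_000_000, seed=7)
res = run_simulation(cfg)
print("tally:", res.tally)
print(classify_detected_events(res.events))
print(f"single-scatter share of detected scattered photons: "
      f"{single_scatter_share(res.events):.1f}%")

img = accumulate_image(res.events, cfg.detector)
cal = CalibrationResult(beam_center_px=cfg.detector.beam_center_px,
                        distance_cm=cfg.effective_distance_cm)
profile = azimuthal_integrate(img, cal, lam_nm=float(wavelength_nm(22.0)))
fit = fit_gaussian_peaks(profile, n_peaks=1, window=(10.0, 18.0))
peak = fit.peak_nearest(14.5)
print(f"fat peak: center = {peak.center:.2f} nm^-1, sigma = {peak.sigma:.2f} nm^-1, "
      f"R^2 = {fit.r_squared:.3f}")
```

prints

```
tally: {'absorbed': 941126, 'escaped': 878558, 'detected': 180316}
              unscattered  rayleigh_only  compton_only  mixed
multiplicity
0                  129932              0             0      0
1                       0          35317           191      0
2                       0          11293            10    189
3+                      0           3195             0    189
single-scatter share of detected scattered photons: 70.5%
fat peak: center = 14.46 nm^-1, sigma = 1.07 nm^-1, R^2 = 0.981
```

Reading it: of 2×10⁶ incident photons, 47% are absorbed in the 4 cm
phantom, 9% reach the detector (half the direct beam falls off the
array edge by design), and among the detected *scattered* photons about
70% scattered exactly once — essentially all of them coherently, which
is why the azimuthally integrated image still shows the fat reflection
as a clean Gaussian at 14.5 nm⁻¹ about 1.1 nm⁻¹ wide.

The same pipeline is scriptable from the shell:

```bash
phantomwaxs simulate --config config.yaml --out out/
phantomwaxs reduce   --config config.yaml --image out/sim_t4cm.tif --out out/
phantomwaxs fit      --config config.yaml --profile out/sim_t4cm_profile.csv
```

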