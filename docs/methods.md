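# Methods

`phantomwaxs` models a wide-angle X-ray scattering (WAXS) transmission
experiment on thick tissue phantoms: a monochromatic pencil beam passes
through a cylinder of adipose-like material and the scattered photons are
recorded on a small planar pixel detector far behind it.  The question the
package is built to answer is quantitative: how do the diffraction
features of fat — above all the inter-fatty-acid reflection near
q = 14.5 nm⁻¹ — degrade (broaden, attenuate, drown in multiple
scattering) as the sample grows from 2 cm to 10 cm, and do they remain
measurable?

## Photon transport model

Photons are tracked one interaction at a time through a homogeneous
cylinder (default: 4 cm diameter, thickness 2–10 cm, axis along the
beam):

* **Free paths** are exponential with mean 1/μ_total(E), where
  μ_total = μ_photo + μ_rayleigh + μ_compton is assembled from three
  independently tabulated linear attenuation coefficients (cm⁻¹).
* **Process selection** is proportional to the partial coefficients.
* **Photoelectric** events terminate the history.
* **Rayleigh (coherent)** deflections sample the polar angle from
  p(θ) ∝ sin θ · (1 + cos²θ)/2 · F²(q(θ)),  q = 4π sin(θ/2)/λ,
  i.e. the Thomson angular factor modulated by the squared molecular
  form factor.  The energy is unchanged.  Sampling uses a tabulated
  inverse CDF on a 2048-point θ grid — exact to grid resolution and
  cheap to vectorise.
* **Compton (incoherent)** deflections are rejection-sampled from the
  Klein–Nishina density (bound f ≤ 2, efficiency ≈ 0.65 at 22 keV) and
  the photon continues with E′ = E / (1 + (E/m_ec²)(1 − cos θ)).  The
  incoherent scattering function S(q) defaults to 1; a table can be
  supplied.  At 22 keV the energy loss is at most ~8%, so the flat
  attenuation tables are exercised over a narrow span only.
* Photons that leave the cylinder (side or either face) fly in a straight
  line to the detector plane; air scattering and absorption between
  sample and detector are neglected.  Photons crossing the sensitive area
  are recorded with energy, landing position, direction and per-process
  scatter counters; everything else is tallied as absorbed or escaped,
  and the three tallies partition the incident photons exactly.

The tracer advances whole batches of histories in lock-step with numpy,
which makes 5×10⁶-photon runs a matter of ~10–20 s on one core.  A single
Philox stream drives each run with a fixed batch size, so a (config,
seed) pair reproduces its event list bit-for-bit.

### Geometry

The instrument has a vertical optical axis.  Coordinates put the origin
at the beam entry point on the phantom entry face with the beam along
−z; the detector plane is at the platform distance L = 72 cm from the
entry face, so the phantom centre sits at D_eff = L − t/2 from the
detector — the effective distance used in reduction (71 cm for the 2 cm
calibration sample).  The detector is a 768 × 512 array of 135 μm pixels
whose edge the beam axis intersects at the centre of a short side, so
one half-plane of scattering angles is covered out to the far edge
(q ≈ 16–17 nm⁻¹ at these distances).  The beam is a 100 μm-radius
pencil; because the axis sits on the array edge, half of the direct beam
falls off the sensitive area by construction.

### Material model

Defaults for the adipose phantom at the 22 keV working energy
(λ = hc/E = 0.05636 nm):

| parameter | default | note |
|---|---|---|
| μ_photo | 0.16 cm⁻¹ | absorptive component of breast-tissue attenuation at 22 keV |
| μ_rayleigh | 0.25 cm⁻¹ | model default, configurable |
| μ_compton | 0.10 cm⁻¹ | model default, configurable |
| density | 0.95 g/cm³ | adipose |

The attenuation decomposition is deliberately exposed as three config
values: measured tissue data rarely reports the split, and the analyses
here (multiplicity decomposition, Beer–Lambert recovery) are sensitive
to it.  The detected doubles-to-singles ratio, in particular, scales
roughly linearly with μ_rayleigh·t, so studies of the multiplicity
decomposition should treat that coefficient as the controlling knob.
Compilation-grade coherent/incoherent coefficients for adipose at 22 keV
are closer to (0.05, 0.18) cm⁻¹; the package defaults keep the total at
0.51 cm⁻¹ with a heavier coherent channel, which weights the simulation
toward the diffraction signal of interest.

The default coherent form factor is parametric:

    F²(q) = 0.35·exp(−q/9) + 1.0·G(q; 14.5, 1.1) + 0.15·G(q; 4.5, 0.6)

a smooth decaying atomic baseline plus Gaussian interference peaks
(centre, σ in nm⁻¹): the dominant inter-fatty-acid spacing reflection at
14.5 and the weak third-order triglyceride packing line at 4.5.  The
relative units are irrelevant — only the shape enters the sampler.  The
peak-to-baseline contrast at 14.5 nm⁻¹ is ≈ 15:1, a deliberately clean
diffraction signal.  Two-column text tables (q nm⁻¹, F²) override the
parametric form, and four-component tissue mixtures (fat, water,
collagen, calcium hydroxyapatite) combine component form factors by
weight fraction; the default phantom is pure fat.

## Reduction chain

1. **Calibration** — silver behenate rings (q_n = n·2π/d001,
   d001 = 5.838 nm) fix beam centre and distance.  Ring radii are found
   on a radial histogram around the direct-beam spot centroid, the ring
   pixels are jointly fit as intensity-weighted concentric circles
   (Levenberg–Marquardt), diffraction orders are assigned by trying
   consecutive-order hypotheses, and the distance follows from
   r_n = D·tan(2θ_n).  On synthetic frames the round-trip recovers
   centres to < 0.1 px and distances to < 0.05%.
2. **q conversion** — q = (4π/λ)·sin(atan(r/D)/2) per pixel centre.
3. **Azimuthal integration** — per-bin mean of unmasked pixel counts
   (default bin width 0.05 nm⁻¹, finer than any peak of interest), with
   Poisson uncertainty √(Σcounts)/n_pix; bins with no contributing
   pixels are carried as missing (NaN), never as zero.  Beam-stop
   shadows are non-destructive boolean masks (circle + optional support
   arm) that integration simply skips.  No solid-angle or polarization
   corrections are applied by default; at the largest angle used here
   (2θ ≈ 9°) both are sub-percent effects.
4. **Averaging and normalisation** — replicate profiles (three lateral
   points per sample) are averaged pointwise (σ combined as RMS/√k);
   profiles are rescaled to unit maximum over 6–18 nm⁻¹ before
   cross-thickness comparison.

## Statistical layer

* **Peak decomposition**: nonlinear least squares of one or two
  Gaussians plus a constant background over a q window (default 6–18
  nm⁻¹).  Initialisation is deterministic — centres at the named
  features 9 and 14.5 nm⁻¹, widths 1.5 nm⁻¹, amplitudes from local
  maxima — with bounds keeping centres in-window, σ ∈ (0.05, 10] and
  amplitudes/background ≥ 0.  Goodness of fit is reported as
  R² = 1 − SS_res/SS_tot and RMSE on the window points; non-convergence
  is flagged and the partial result returned.  The reported peak width
  is the fitted σ (FWHM = 2.3548σ available).  Because the models are
  nested, the two-Gaussian SS_res can never exceed the one-Gaussian
  SS_res beyond optimiser tolerance — a property the tests enforce.
* **Width vs thickness**: ordinary least squares of the fat-peak σ on
  thickness.  The geometric expectation is closed-form: a scatterer at
  depth z deflecting by 2θ₀ lands at (L − z)·tan 2θ₀, while reduction
  assumes the single distance D_eff = L − t/2, so uniform depth smears
  q₀ into a top-hat of full width q₀·t/D_eff and
  σ(t)² = σ₀² + (q₀t)²/(12·D_eff²).  Over 2–10 cm this is mildly convex
  but close to linear (its own linear fit has R² ≈ 0.96), which bounds
  the R² obtainable from simulation.
* **Attenuation**: the intensity integrated over 0 < q ≤ 3 nm⁻¹
  (trapezoidal, missing bins skipped) is fit to I₀·exp(−μ_eff·d) by
  log-space least squares (variance stabilisation for counts) with a
  nonlinear refinement.  With scattering disabled this recovers the
  configured μ_photo to well under 5%; with full physics the decay
  reflects the total attenuation less forward-scatter fill-in.

## Synthetic data

The generators provide every input class with known ground truth, so all
closure tests run without measured data: 1-D phantom-like curves (peaks
at 4.5/9/14.5 nm⁻¹, constant background, c/q air-scatter term, Poisson
noise — the 9 nm⁻¹ shoulder grows with thickness, treated purely
phenomenologically), Gaussian-annulus ring frames, AgBH calibrant frames
(rings at n·2π/d001, 1/n amplitudes, direct-beam spot, flat floor), and
event streams of exactly specified multiplicity composition
(largest-remainder apportionment, shuffled order).  Each generator emits
its truth sidecar and is reproducible from (spec, seed).

What the synthetic data does **not** emulate: detector artifacts (hot
pixels, crosstalk, point spread), flat-field/dark structure, beam-stop
diffraction fringes, sample inhomogeneity and packing gradients, and
polychromaticity.  Closure on synthetic data therefore demonstrates the
correctness of the reduction/fitting mathematics, not robustness to
instrument systematics.

## Problem sizes and numerical choices

Simulated studies in the test-suite use 5×10⁶–5×10⁷ photons per run,
chosen from measured estimator precision: the fat-peak width standard
error at 10 cm is ≈ 0.05 nm⁻¹ at 5×10⁶ photons and the full width range
across thicknesses is only ≈ 0.13 nm⁻¹, so the width-trend analysis runs
the thicker samples at up to 5×10⁷ histories (width SE ≈ 0.015 nm⁻¹).
Scatter-off attenuation checks need only 3×10⁵ photons per thickness.
Runs of different sizes are compared on a per-incident-photon scale.

Other numerics: form-factor and S(q) lookups are linear in q and clamp
(never extrapolate) outside the grid; attenuation lookups are linear in
E and raise outside the tabulated range; the cylinder-exit solver treats
a < 10⁻³⁰⁰ quadratic coefficients as axis-parallel rays; histories are
capped at 10⁴ interactions (never reached in practice — survivors would
be tallied as escaped); curve fits run with analytic bounds and
`maxfev = 20000`.

## Known limitations

* Homogeneous phantom: no packing non-uniformity, so simulated
  attenuation coefficients exceed what heterogeneous real samples show.
* The multiplicity decomposition among detected photons depends strongly
  on the coherent/incoherent attenuation split, which the defaults fix
  by convention rather than measurement (see Material model above).
* No detector energy response or threshold (configurable energies are
  recorded, not filtered).
* Air contributes only as a synthetic 1/q background term in generated
  curves; it is not transported.
* Source-to-sample distance is irrelevant to the model (ideal pencil
  beam); beam divergence is not modelled.
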