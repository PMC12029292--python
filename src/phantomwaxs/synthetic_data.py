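"""Ground-truth synthetic inputs: profiles, ring frames, AgBH frames,
event streams.

Every generator here mimics one class of real input to the pipeline and
emits its :class:`SyntheticTruth` sidecar, so closure tests (generate →
reduce → fit → compare with truth) can run without any measured data:

* phantom-like I(q) curves — Gaussian peaks at 4.5 (weak triglyceride
  order), 9 (phenomenological shoulder that grows with thickness) and
  14.5 nm⁻¹ (fat), a constant background, a c/q air-scatter term and
  Poisson counting noise;
* azimuthally symmetric detector frames: a single Gaussian annulus in q,
  or an AgBH calibrant pattern with rings at q_n = n·2π/d001 plus a
  direct-beam spot;
* canned detected-event streams with an exactly specified
  multiplicity/process composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detector_image import DetectorGeometry, ScatterImage
from .reduction import CalibrationResult, Profile, pixel_to_q

__all__ = [
    "SyntheticTruth",
    "default_phantom_truth",
    "synth_profile",
    "synth_ring_image",
    "synth_agbh_image",
    "synth_event_stream",
]

_MULTIPLICITY_NAMES = {
    "unscattered": (0, 0),
    "direct": (0, 0),
    "single": (1, 0),
    "double": (2, 0),
    "triple": (3, 0),
}


@dataclass
class SyntheticTruth:
    """Generator parameters frozen alongside the data they produced.

    ``peaks`` is a list of (amplitude, center nm⁻¹, sigma nm⁻¹); the air
    term contributes ``air_coeff / q``.
    """

    peaks: list
    background: float = 0.0
    air_coeff: float = 0.0
    mu_cm: float = 0.0
    seed: int = 0
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        for a, _c, s in self.peaks:
            if a < 0 or s <= 0:
                raise ValueError("peak amplitudes must be >= 0 and widths > 0")
        if self.background < 0 or self.air_coeff < 0:
            raise ValueError("background terms must be >= 0")

    def expectation(self, q):
        """Noise-free expected intensity at q (before exposure scaling)."""
        q = np.asarray(q, dtype=float)
        out = np.full_like(q, float(self.background))
        for a, c, s in self.peaks:
            out = out + a * np.exp(-0.5 * ((q - c) / s) ** 2)
        if self.air_coeff:
            with np.errstate(divide="ignore"):
                out = out + np.where(q > 0, self.air_coeff / np.clip(q, 1e-12, None), 0.0)
        return out

    def to_dict(self):
        return {
            "peaks": [list(p) for p in self.peaks],
            "background": self.background,
            "air_coeff": self.air_coeff,
            "mu_cm": self.mu_cm,
            "seed": self.seed,
            "geometry": self.geometry,
        }


def default_phantom_truth(thickness_cm: float = 2.0, seed: int = 0,
                          mu_cm: float = 0.16) -> SyntheticTruth:
    """Phantom-curve truth emulating the measured thickness series.

    Peak amplitudes attenuate as exp(−μd); the 9 nm⁻¹ shoulder grows
    with thickness relative to the fat peak (treated phenomenologically —
    its physical origin in the measurements is unclear).
    """
    atten = np.exp(-mu_cm * thickness_cm)
    grow = 0.25 + 0.05 * thickness_cm  # 9 nm^-1 shoulder relative weight
    peaks = [
        (30.0 * atten, 4.5, 0.5),
        (100.0 * grow * atten, 9.0, 1.8),
        (100.0 * atten, 14.5, 1.2),
    ]
    return SyntheticTruth(peaks=peaks, background=10.0 * atten, air_coeff=40.0 * atten,
                          mu_cm=mu_cm, seed=seed,
                          geometry={"thickness_cm": thickness_cm})


def synth_profile(truth: SyntheticTruth, bins=None, exposure_scale: float = 1.0,
                  noise: bool = True) -> Profile:
    """Poisson-sampled I(q) curve from an analytic truth.

    Expected counts are ``exposure_scale × (Σ Gaussians + bkg + c/q)``;
    with ``noise=False`` the expectation itself is returned (the
    zero-noise limit).  Sampling uses the seed stored in the truth.
    """
    if bins is None:
        bins = np.arange(0.5, 20.0, 0.05)
    q = np.asarray(bins, dtype=float)
    expect = exposure_scale * truth.expectation(q)
    if np.any(expect < 0):
        raise ValueError("negative expected intensity")
    if noise:
        rng = np.random.Generator(np.random.Philox(truth.seed))
        counts = rng.poisson(expect).astype(float)
    else:
        counts = expect
    sigma = np.sqrt(np.clip(expect, 1.0, None))
    return Profile(q=q, intensity=counts, sigma=sigma,
                   n_pix=np.ones_like(q, dtype=int),
                   meta={"synthetic": True, "seed": truth.seed,
                         "exposure_scale": exposure_scale})


def _pixel_q_map(det: DetectorGeometry, center_px, distance_mm, lam_nm):
    jj, ii = np.mgrid[0:det.n_slow, 0:det.n_fast]
    r_mm = np.hypot(ii + 0.5 - center_px[0], jj + 0.5 - center_px[1]) * det.pitch_mm
    return pixel_to_q(r_mm, distance_mm, lam_nm), r_mm


def synth_ring_image(q0: float, width_q: float, det: DetectorGeometry,
                     distance_cm: float, lam_nm: float = 0.05636,
                     counts: float = 1e6, seed: int = 0,
                     noise: bool = True) -> tuple[ScatterImage, SyntheticTruth]:
    """Azimuthally symmetric Gaussian annulus at q₀, Poisson sampled.

    The pixel expectation is normalised so the image sums to ``counts``
    in expectation.  Raises if the ring lies entirely off the detector.
    """
    q, _r = _pixel_q_map(det, det.beam_center_px, distance_cm * 10.0, lam_nm)
    sigma_q = max(width_q, 1e-6)
    expect = np.exp(-0.5 * ((q - q0) / sigma_q) ** 2)
    total = expect.sum()
    if total <= 1e-12 or np.abs(q - q0).min() > 3.0 * sigma_q:
        raise ValueError("ring lies outside the detector reach")
    expect *= counts / total
    rng = np.random.Generator(np.random.Philox(seed))
    img_counts = rng.poisson(expect) if noise else np.round(expect).astype(np.int64)
    geom = DetectorGeometry(det.n_fast, det.n_slow, det.pitch_mm,
                            det.beam_center_px, distance_cm)
    truth = SyntheticTruth(peaks=[(1.0, q0, sigma_q)], seed=seed,
                           geometry={"distance_cm": distance_cm,
                                     "beam_center_px": list(det.beam_center_px)})
    return ScatterImage(counts=img_counts.astype(np.int64), geometry=geom,
                        metadata={"synthetic": "ring", "q0": q0}), truth


def synth_agbh_image(cal: CalibrationResult, d001_nm: float, n_rings: int,
                     det: DetectorGeometry, lam_nm: float = 0.05636,
                     counts: float = 2e6, ring_width_px: float = 1.5,
                     beam_spot: bool = True, seed: int = 0) -> ScatterImage:
    """Silver behenate calibration frame with rings at q_n = n·2π/d001.

    Ring amplitudes fall off as 1/n; a compact direct-beam spot marks the
    true centre (used to seed calibration), plus a small flat background.
    At least two rings are required for a frame to be calibratable.
    """
    if n_rings < 2:
        raise ValueError("need n_rings >= 2 for a calibratable frame")
    center = cal.beam_center_px
    distance_mm = cal.distance_cm * 10.0
    jj, ii = np.mgrid[0:det.n_slow, 0:det.n_fast]
    r_px = np.hypot(ii + 0.5 - center[0], jj + 0.5 - center[1])
    q1 = 2.0 * np.pi / d001_nm
    expect = np.full(det.shape, 0.02)
    n_on = 0
    for n in range(1, n_rings + 1):
        theta = np.arcsin(n * q1 * lam_nm / (4.0 * np.pi))
        ring_r_px = distance_mm * np.tan(2.0 * theta) / det.pitch_mm
        term = (1.0 / n) * np.exp(-0.5 * ((r_px - ring_r_px) / ring_width_px) ** 2)
        if np.abs(r_px - ring_r_px).min() < 3.0 * ring_width_px:
            n_on += 1
        expect += term
    if n_on < 2:
        raise ValueError("fewer than two rings fall on the detector")
    if beam_spot:
        expect += 50.0 * np.exp(-0.5 * (r_px / 1.2) ** 2)
    expect *= counts / expect.sum()
    rng = np.random.Generator(np.random.Philox(seed))
    geom = DetectorGeometry(det.n_fast, det.n_slow, det.pitch_mm,
                            det.beam_center_px, cal.distance_cm)
    return ScatterImage(counts=rng.poisson(expect).astype(np.int64), geometry=geom,
                        metadata={"synthetic": "agbh", "d001_nm": d001_nm,
                                  "true_center_px": list(center),
                                  "true_distance_cm": cal.distance_cm, "seed": seed})


def synth_event_stream(proportions: dict, n: int, seed: int = 0,
                       det: DetectorGeometry | None = None) -> pd.DataFrame:
    """Detected-event table with an exactly specified composition.

    ``proportions`` maps multiplicity names ('single', 'double', 'triple',
    'unscattered') or explicit ``(n_rayleigh, n_compton)`` tuples to
    fractions summing to 1.  Counts are deterministic (largest-remainder
    apportionment); positions are uniform over the sensitive area and row
    order is shuffled.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    keys = list(proportions)
    fracs = np.array([proportions[k] for k in keys], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be >= 0 and sum to 1")
    det = det or DetectorGeometry()
    counts = np.floor(fracs * n).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    counts[order[:remainder]] += 1

    rng = np.random.Generator(np.random.Philox(seed))
    rows = {c: [] for c in ("n_rayleigh", "n_compton")}
    for key, k in zip(keys, counts):
        nr, nc = _MULTIPLICITY_NAMES[key] if isinstance(key, str) else key
        rows["n_rayleigh"].extend([nr] * k)
        rows["n_compton"].extend([nc] * k)
    u = rng.uniform(0, det.n_fast, n)
    v = rng.uniform(0, det.n_slow, n)
    cf, cs = det.beam_center_px
    df = pd.DataFrame({
        "id": np.arange(n),
        "energy_keV": np.full(n, 22.0),
        "x_mm": (u - cf) * det.pitch_mm,
        "y_mm": (v - cs) * det.pitch_mm,
        "dirx": np.zeros(n), "diry": np.zeros(n), "dirz": np.full(n, -1.0),
        "n_rayleigh": np.array(rows["n_rayleigh"], dtype=int),
        "n_compton": np.array(rows["n_compton"], dtype=int),
    })
    return df.sample(frac=1.0, random_state=int(seed) % (2**32)).reset_index(drop=True) if n else df
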