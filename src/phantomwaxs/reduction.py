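"""Image → I(q) reduction: geometry calibration and azimuthal integration.

The chain mirrors standard powder-diffraction practice: a silver behenate
(AgBH) frame fixes the beam centre and sample-to-detector distance from
its evenly spaced rings (q_n = n·2π/d001, d001 = 5.838 nm); pixel radii
are converted to momentum transfer by q = (4π/λ)·sin(atan(r/D)/2); the
azimuthal mean of unmasked pixel counts per q bin gives the profile, with
Poisson uncertainties; replicate profiles (three lateral points per
sample) are averaged; profiles are normalised to unit maximum over the
6–18 nm⁻¹ window before peak comparison across thicknesses.

For a phantom of finite thickness the effective distance is measured to
the sample centre: ``platform − thickness/2`` (71 cm for the 2 cm
calibration sample on a 72 cm platform).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .detector_image import DetectorGeometry, ScatterImage

__all__ = [
    "AGBH_D001_NM",
    "Profile",
    "CalibrationResult",
    "CalibrationError",
    "pixel_to_q",
    "q_to_radius",
    "effective_sample_distance",
    "calibrate_agbh",
    "azimuthal_integrate",
    "average_profiles",
    "normalize_profile",
    "subtract_profiles",
]

AGBH_D001_NM = 5.838  # silver behenate lamellar spacing


class CalibrationError(RuntimeError):
    """Geometry calibration could not be established from the frame."""


@dataclass
class Profile:
    """1-D scattering profile I(q) with uncertainties.

    Bins with no contributing pixels carry ``intensity = nan`` and
    ``n_pix = 0`` (missing, not zero).
    """

    q: np.ndarray  # nm^-1, strictly increasing bin centres
    intensity: np.ndarray
    sigma: np.ndarray
    n_pix: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.n_pix = np.asarray(self.n_pix, dtype=int)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        for arr in (self.intensity, self.sigma, self.n_pix):
            if arr.shape != self.q.shape:
                raise ValueError("profile columns must share the q grid shape")
        if np.any(self.sigma[np.isfinite(self.sigma)] < 0):
            raise ValueError("sigma must be >= 0")

    @property
    def valid(self) -> np.ndarray:
        return self.n_pix > 0

    # -- CSV round trip ----------------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("q_nm_inv,intensity,sigma,n_pix\n")
            for q, i, s, n in zip(self.q, self.intensity, self.sigma, self.n_pix):
                fh.write(f"{q:.6g},{i:.8g},{s:.8g},{n}\n")

    @classmethod
    def from_csv(cls, path) -> "Profile":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                elif line.strip():
                    rows.append(line)
        data = np.loadtxt(io.StringIO("".join(rows[1:])), delimiter=",", ndmin=2)
        return cls(q=data[:, 0], intensity=data[:, 1], sigma=data[:, 2],
                   n_pix=data[:, 3].astype(int), meta=meta)


@dataclass(frozen=True)
class CalibrationResult:
    """Beam centre (continuous pixels) and sample-to-detector distance."""

    beam_center_px: tuple
    distance_cm: float
    residual_mm: float = 0.0

    def __post_init__(self):
        if self.distance_cm <= 0:
            raise ValueError("distance must be > 0")


# ---------------------------------------------------------------------------
# geometry conversions
# ---------------------------------------------------------------------------

def pixel_to_q(r_mm, distance_mm, lam_nm):
    """q = (4π/λ)·sin(atan(r/D)/2) for radial distance r on the detector."""
    if distance_mm <= 0:
        raise ValueError("distance must be > 0")
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    return 4.0 * np.pi / lam_nm * np.sin(0.5 * np.arctan(r / distance_mm))


def q_to_radius(q_nm_inv, distance_mm, lam_nm):
    """Inverse of :func:`pixel_to_q`: detector radius (mm) of a given q."""
    q = np.asarray(q_nm_inv, dtype=float)
    theta = np.arcsin(np.clip(q * lam_nm / (4.0 * np.pi), -1.0, 1.0))
    return distance_mm * np.tan(2.0 * theta)


def effective_sample_distance(platform_distance_cm: float, thickness_cm: float) -> float:
    """Distance to the sample centre: platform − thickness/2 (cm)."""
    d = platform_distance_cm - thickness_cm / 2.0
    if d <= 0:
        raise ValueError("non-positive effective distance")
    return d


# ---------------------------------------------------------------------------
# AgBH calibration
# ---------------------------------------------------------------------------

def _radial_profile(counts, mask, center, bin_px=0.5):
    n_slow, n_fast = counts.shape
    jj, ii = np.mgrid[0:n_slow, 0:n_fast]
    r = np.hypot(ii + 0.5 - center[0], jj + 0.5 - center[1])
    good = ~mask
    r_max = r[good].max()
    edges = np.arange(0.0, r_max + bin_px, bin_px)
    idx = np.clip(np.digitize(r[good], edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=counts[good].astype(float), minlength=len(edges) - 1)
    npx = np.bincount(idx, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        prof = np.where(npx > 0, sums / np.maximum(npx, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, prof, r


def _initial_center(img: ScatterImage):
    """Centroid of the brightest pixels (the attenuated direct-beam spot)."""
    counts = np.where(img.mask, 0, img.counts).astype(float)
    thresh = 0.5 * counts.max()
    jj, ii = np.nonzero(counts >= thresh)
    w = counts[jj, ii]
    return (float(np.average(ii + 0.5, weights=w)), float(np.average(jj + 0.5, weights=w)))


def calibrate_agbh(
    img: ScatterImage,
    d001_nm: float = AGBH_D001_NM,
    lam_nm: float = 0.05636,
    center_guess: tuple | None = None,
    min_ring_radius_px: float = 8.0,
) -> CalibrationResult:
    """Fit beam centre and distance to the AgBH ring pattern.

    Ring radii are located on a radial histogram around an initial centre
    (the direct-beam spot centroid unless ``center_guess`` is given), each
    ring's pixels are then jointly fit as concentric circles
    (least squares, intensity-weighted), orders are assigned against
    q_n = n·2π/d001, and the distance follows from r_n = D·tan 2θ_n.

    Raises :class:`CalibrationError` when fewer than two rings are found.
    """
    counts = np.where(img.mask, 0, img.counts).astype(float)
    if counts.max() <= 0:
        raise CalibrationError("empty frame")
    center0 = tuple(center_guess) if center_guess is not None else _initial_center(img)

    radii_px, prof, _ = _radial_profile(counts, img.mask, center0)
    core = radii_px < min_ring_radius_px
    prof_search = np.where(np.isnan(prof) | core, 0.0, prof)
    floor = np.nanmedian(prof_search[prof_search > 0]) if np.any(prof_search > 0) else 0.0
    peaks, _props = signal.find_peaks(
        prof_search, prominence=max(5.0 * floor, 1.0), distance=10
    )
    if len(peaks) < 2:
        raise CalibrationError(f"found {len(peaks)} candidate rings; need >= 2")
    ring_r0 = radii_px[peaks]

    # joint concentric-circle fit: parameters (cx, cy, r_1..r_K)
    n_slow, n_fast = counts.shape
    jj, ii = np.mgrid[0:n_slow, 0:n_fast]
    pix_x = (ii + 0.5).ravel()
    pix_y = (jj + 0.5).ravel()
    wts = counts.ravel()
    r_all = np.hypot(pix_x - center0[0], pix_y - center0[1])
    sel_sets = []
    for r0 in ring_r0:
        sel = (np.abs(r_all - r0) < 4.0) & (wts > 0)
        if sel.sum() < 20:
            raise CalibrationError("too few pixels on a candidate ring")
        sel_sets.append(np.flatnonzero(sel))

    def residuals(params):
        cx, cy = params[:2]
        res = []
        for k, sel in enumerate(sel_sets):
            rk = params[2 + k]
            dist = np.hypot(pix_x[sel] - cx, pix_y[sel] - cy)
            res.append(np.sqrt(wts[sel]) * (dist - rk))
        return np.concatenate(res)

    p0 = np.concatenate([center0, ring_r0])
    fit = optimize.least_squares(residuals, p0, method="lm", max_nfev=200)
    cx, cy = fit.x[:2]
    ring_r = np.sort(fit.x[2:])
    pitch = img.geometry.pitch_mm if img.geometry is not None else 0.135
    r_mm = ring_r * pitch

    # order assignment and distance fit: r_n = D tan(2 asin(n q1 λ / 4π))
    q1 = 2.0 * np.pi / d001_nm
    best = None
    for n0 in range(1, 5):
        orders = n0 + np.arange(len(r_mm))
        theta = np.arcsin(orders * q1 * lam_nm / (4.0 * np.pi))
        u = np.tan(2.0 * theta)
        D = float(np.sum(r_mm * u) / np.sum(u * u))
        rms = float(np.sqrt(np.mean((r_mm - D * u) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, D)
    rms_mm, D_mm = best
    return CalibrationResult(
        beam_center_px=(float(cx), float(cy)),
        distance_cm=D_mm / 10.0,
        residual_mm=rms_mm,
    )


# ---------------------------------------------------------------------------
# azimuthal integration
# ---------------------------------------------------------------------------

def azimuthal_integrate(
    img: ScatterImage,
    cal: CalibrationResult | None = None,
    lam_nm: float = 0.05636,
    bins: np.ndarray | None = None,
    bin_width: float = 0.05,
) -> Profile:
    """Azimuthal mean of unmasked pixel counts per q bin.

    ``cal`` may be omitted when the image geometry carries a beam centre
    and distance.  ``sigma`` is Poisson: sqrt(sum of counts)/n_pix.
    """
    geom = img.geometry if img.geometry is not None else DetectorGeometry()
    if cal is not None:
        center = cal.beam_center_px
        distance_mm = cal.distance_cm * 10.0
    else:
        if geom.distance_cm is None:
            raise ValueError("no calibration and no distance in the image geometry")
        center = geom.beam_center_px
        distance_mm = geom.distance_cm * 10.0

    n_slow, n_fast = img.shape
    jj, ii = np.mgrid[0:n_slow, 0:n_fast]
    r_mm = np.hypot(ii + 0.5 - center[0], jj + 0.5 - center[1]) * geom.pitch_mm
    q = pixel_to_q(r_mm, distance_mm, lam_nm)

    good = ~img.mask
    if not good.any():
        raise ValueError("all pixels are masked")
    if bins is None:
        bins = np.arange(0.0, q[good].max() + bin_width, bin_width)
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    qg = q[good]
    cg = img.counts[good].astype(float)
    inside = (qg >= bins[0]) & (qg < bins[-1])
    idx = np.digitize(qg[inside], bins) - 1
    nb = len(bins) - 1
    sums = np.bincount(idx, weights=cg[inside], minlength=nb)
    npx = np.bincount(idx, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(npx > 0, sums / np.maximum(npx, 1), np.nan)
        sigma = np.where(npx > 0, np.sqrt(np.clip(sums, 0, None)) / np.maximum(npx, 1), np.nan)
    centers = 0.5 * (bins[:-1] + bins[1:])
    meta = dict(img.metadata)
    meta.update({"distance_cm": distance_mm / 10.0, "lam_nm": lam_nm})
    return Profile(q=centers, intensity=intensity, sigma=sigma, n_pix=npx, meta=meta)


# ---------------------------------------------------------------------------
# profile arithmetic
# ---------------------------------------------------------------------------

def _check_same_grid(profiles):
    q0 = profiles[0].q
    for p in profiles[1:]:
        if p.q.shape != q0.shape or not np.allclose(p.q, q0):
            raise ValueError("profiles must share the same q grid")
    return q0


def average_profiles(profiles) -> Profile:
    """Pointwise mean of replicate profiles; σ combined as RMS/√k."""
    if not profiles:
        raise ValueError("need at least one profile")
    q0 = _check_same_grid(profiles)
    k = len(profiles)
    inten = np.nanmean([p.intensity for p in profiles], axis=0)
    sigma = np.sqrt(np.nanmean([p.sigma**2 for p in profiles], axis=0)) / np.sqrt(k)
    npx = np.sum([p.n_pix for p in profiles], axis=0)
    meta = dict(profiles[0].meta)
    meta["points_averaged"] = k
    return Profile(q=q0, intensity=inten, sigma=sigma, n_pix=npx, meta=meta)


def normalize_profile(p: Profile, q_lo: float = 6.0, q_hi: float = 18.0) -> Profile:
    """Scale so the maximum over [q_lo, q_hi] is 1; σ scales identically."""
    window = (p.q >= q_lo) & (p.q <= q_hi) & p.valid
    if not window.any():
        raise ValueError("normalisation window contains no valid bins")
    peak = np.nanmax(p.intensity[window])
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("normalisation window is all zero")
    meta = dict(p.meta)
    meta["normalized"] = f"[{q_lo}, {q_hi}]"
    return Profile(q=p.q.copy(), intensity=p.intensity / peak, sigma=p.sigma / peak,
                   n_pix=p.n_pix.copy(), meta=meta)


def subtract_profiles(p: Profile, background: Profile) -> Profile:
    """Optional background subtraction (e.g. empty-tube frame)."""
    _check_same_grid([p, background])
    sigma = np.sqrt(p.sigma**2 + background.sigma**2)
    meta = dict(p.meta)
    meta["background_subtracted"] = True
    return Profile(q=p.q.copy(), intensity=p.intensity - background.intensity,
                   sigma=sigma, n_pix=np.minimum(p.n_pix, background.n_pix), meta=meta)
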