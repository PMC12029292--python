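"""Phantom materials: attenuation coefficients and coherent form factors.

A :class:`Material` bundles everything the transport engine needs to know
about a homogeneous medium at diagnostic X-ray energies: the three partial
linear attenuation coefficients (photoelectric, Rayleigh/coherent,
Compton/incoherent) tabulated against photon energy, the squared coherent
molecular form factor ``F²(q)`` that shapes the Rayleigh angular
distribution, and an optional incoherent scattering function ``S(q)``.

Soft tissue is modelled as a weighted mixture of four basis components
(fat, water, collagen, calcium hydroxyapatite); for adipose phantoms the
mixture collapses to pure fat.  The default adipose form factor is
parametric: a smooth decaying atomic baseline plus Gaussian interference
peaks at 4.5 nm⁻¹ (third order of triglyceride packing, weak) and
14.5 nm⁻¹ (inter-fatty-acid spacing, dominant).  Tabulated two-column
text files override the parametric default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Material",
    "MixtureSpec",
    "MIXTURE_COMPONENTS",
    "adipose_form_factor_sq",
    "default_adipose",
    "load_form_factor_table",
    "total_attenuation",
    "coherent_form_factor_sq",
    "incoherent_function",
    "mixture_form_factor",
]

#: Canonical order of the four-component tissue mixture.
MIXTURE_COMPONENTS = ("fat", "water", "collagen", "hydroxyapatite")

# Parametric adipose F²(q) defaults (relative units, q in nm^-1).
ADIPOSE_BASELINE_AMP = 0.35
ADIPOSE_BASELINE_DECAY = 9.0  # nm^-1 e-folding of the smooth atomic term
ADIPOSE_PEAK_Q = 14.5  # inter-fatty-acid spacing peak
ADIPOSE_PEAK_SIGMA = 1.1
ADIPOSE_PEAK_AMP = 1.0
ADIPOSE_TRIGLYCERIDE_Q = 4.5  # third order of triglyceride packing
ADIPOSE_TRIGLYCERIDE_SIGMA = 0.6
ADIPOSE_TRIGLYCERIDE_AMP = 0.15

# Default partial linear attenuation coefficients of adipose tissue at the
# Ag-anode working energy, cm^-1.  The photoelectric value is the breast
# tissue absorption coefficient at 22 keV; the two scatter channels are
# independently configurable model parameters.
ADIPOSE_MU_PHOTO = 0.16
ADIPOSE_MU_RAYLEIGH = 0.25
ADIPOSE_MU_COMPTON = 0.10


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated attenuation range."""


def _interp_clamped(x, xp, fp):
    """Linear interpolation, clamped to the boundary values outside the grid."""
    return np.interp(x, xp, fp)


def _validate_table(q, f, name):
    q = np.asarray(q, dtype=float)
    f = np.asarray(f, dtype=float)
    if q.ndim != 1 or q.size == 0 or q.shape != f.shape:
        raise ValueError(f"{name}: need matching non-empty 1-D grids")
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{name}: q grid must be strictly increasing")
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise ValueError(f"{name}: values must be finite and >= 0")
    return q, f


@dataclass
class Material:
    """Homogeneous medium with tabulated cross-sections and form factor.

    Attenuation coefficients are linear (cm⁻¹) and tabulated on a common
    energy grid (keV); lookups are linear in energy and raise
    :class:`EnergyRangeError` outside the grid.  ``form_factor_sq`` and
    ``incoherent_fn`` are ``(q, value)`` tables in nm⁻¹ / relative units;
    lookups are linear in q and clamp to the boundary value outside the
    grid (no extrapolation).
    """

    name: str
    density: float  # g/cm^3
    energy_keV: np.ndarray
    mu_photo_table: np.ndarray  # cm^-1
    mu_rayleigh_table: np.ndarray
    mu_compton_table: np.ndarray
    ff_q: np.ndarray  # nm^-1
    ff_sq: np.ndarray  # relative units, F^2(q)
    incoh_q: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    incoh_s: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be > 0")
        e = np.asarray(self.energy_keV, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be 1-D, >= 2 points, strictly increasing")
        self.energy_keV = e
        for attr in ("mu_photo_table", "mu_rayleigh_table", "mu_compton_table"):
            mu = np.asarray(getattr(self, attr), dtype=float)
            if mu.shape != e.shape:
                raise ValueError(f"{attr} must match the energy grid")
            if np.any(mu < 0) or not np.all(np.isfinite(mu)):
                raise ValueError(f"{attr} must be finite and >= 0")
            setattr(self, attr, mu)
        self.ff_q, self.ff_sq = _validate_table(self.ff_q, self.ff_sq, "form_factor_sq")
        self.incoh_q, self.incoh_s = _validate_table(self.incoh_q, self.incoh_s, "incoherent_fn")

    # -- energy-dependent lookups -------------------------------------------------
    def _check_energy(self, E):
        E = np.asarray(E, dtype=float)
        if np.any(E < self.energy_keV[0]) or np.any(E > self.energy_keV[-1]):
            raise EnergyRangeError(
                f"energy outside tabulated range "
                f"[{self.energy_keV[0]}, {self.energy_keV[-1]}] keV"
            )
        return E

    def mu_photo(self, E):
        return _interp_clamped(self._check_energy(E), self.energy_keV, self.mu_photo_table)

    def mu_rayleigh(self, E):
        return _interp_clamped(self._check_energy(E), self.energy_keV, self.mu_rayleigh_table)

    def mu_compton(self, E):
        return _interp_clamped(self._check_energy(E), self.energy_keV, self.mu_compton_table)

    def mu_total(self, E):
        E = self._check_energy(E)
        return (
            _interp_clamped(E, self.energy_keV, self.mu_photo_table)
            + _interp_clamped(E, self.energy_keV, self.mu_rayleigh_table)
            + _interp_clamped(E, self.energy_keV, self.mu_compton_table)
        )

    # -- q-dependent lookups ------------------------------------------------------
    def form_factor_sq(self, q):
        q = np.asarray(q, dtype=float)
        if np.any(q < 0):
            raise ValueError("q must be >= 0")
        return _interp_clamped(q, self.ff_q, self.ff_sq)

    def incoherent_fn(self, q):
        q = np.asarray(q, dtype=float)
        if np.any(q < 0):
            raise ValueError("q must be >= 0")
        return _interp_clamped(q, self.incoh_q, self.incoh_s)


@dataclass(frozen=True)
class MixtureSpec:
    """Weight fractions of the four tissue basis components.

    Weights are ordered as :data:`MIXTURE_COMPONENTS`, must be non-negative
    and sum to one within 1e-9.
    """

    weights: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("mixture weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "weights", tuple(w))

    @classmethod
    def pure(cls, component: str) -> "MixtureSpec":
        idx = MIXTURE_COMPONENTS.index(component)
        w = [0.0] * len(MIXTURE_COMPONENTS)
        w[idx] = 1.0
        return cls(tuple(w))


# -- module-level operations ------------------------------------------------------

def total_attenuation(material: Material, E) -> float:
    """Total linear attenuation μ_photo + μ_rayleigh + μ_compton at E (cm⁻¹)."""
    if np.any(np.asarray(E, dtype=float) <= 0):
        raise ValueError("E must be > 0")
    return material.mu_total(E)


def coherent_form_factor_sq(material: Material, q):
    """Interpolated squared coherent form factor F²(q), clamped beyond the grid."""
    return material.form_factor_sq(q)


def incoherent_function(material: Material, q):
    """Interpolated incoherent scattering function S(q) (defaults to 1)."""
    return material.incoherent_fn(q)


def mixture_form_factor(spec: MixtureSpec, components, q):
    """Weighted combination of component form factors at q.

    ``components`` must be one :class:`Material` per mixture weight, in the
    :data:`MIXTURE_COMPONENTS` order.
    """
    if len(components) != len(spec.weights):
        raise ValueError(
            f"{len(spec.weights)} weights but {len(components)} component materials"
        )
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q, dtype=float)
    for w, mat in zip(spec.weights, components):
        if w:
            out = out + w * mat.form_factor_sq(q)
    return out if out.ndim else float(out)


# -- default adipose model --------------------------------------------------------

def adipose_form_factor_sq(
    q,
    baseline_amp: float = ADIPOSE_BASELINE_AMP,
    baseline_decay: float = ADIPOSE_BASELINE_DECAY,
    peak_amp: float = ADIPOSE_PEAK_AMP,
    peak_q: float = ADIPOSE_PEAK_Q,
    peak_sigma: float = ADIPOSE_PEAK_SIGMA,
    tri_amp: float = ADIPOSE_TRIGLYCERIDE_AMP,
    tri_q: float = ADIPOSE_TRIGLYCERIDE_Q,
    tri_sigma: float = ADIPOSE_TRIGLYCERIDE_SIGMA,
):
    """Parametric adipose F²(q): decaying atomic baseline + interference peaks.

    The dominant Gaussian at 14.5 nm⁻¹ is the inter-fatty-acid spacing
    reflection; the weak one at 4.5 nm⁻¹ is the third order of the
    triglyceride lamellar packing.  Units are relative (the transport
    sampler only uses the shape).
    """
    q = np.asarray(q, dtype=float)
    base = baseline_amp * np.exp(-q / baseline_decay)
    p1 = peak_amp * np.exp(-0.5 * ((q - peak_q) / peak_sigma) ** 2)
    p2 = tri_amp * np.exp(-0.5 * ((q - tri_q) / tri_sigma) ** 2)
    out = base + p1 + p2
    return out if out.ndim else float(out)


def default_adipose(
    mu_photo: float = ADIPOSE_MU_PHOTO,
    mu_rayleigh: float = ADIPOSE_MU_RAYLEIGH,
    mu_compton: float = ADIPOSE_MU_COMPTON,
    q_max: float = 250.0,
    n_q: int = 4096,
    **ff_kwargs,
) -> Material:
    """Adipose phantom material with the parametric form factor.

    Attenuation coefficients are held constant over 1–30 keV (the study
    uses a monochromatic 22 keV beam; Compton losses stay above 20 keV, so
    the flat table is exercised only over a ~2 keV span).
    """
    q = np.linspace(0.0, q_max, n_q)
    return Material(
        name="adipose",
        density=0.95,
        energy_keV=np.array([1.0, 30.0]),
        mu_photo_table=np.array([mu_photo, mu_photo]),
        mu_rayleigh_table=np.array([mu_rayleigh, mu_rayleigh]),
        mu_compton_table=np.array([mu_compton, mu_compton]),
        ff_q=q,
        ff_sq=adipose_form_factor_sq(q, **ff_kwargs),
    )


def load_form_factor_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column whitespace form-factor file (q nm⁻¹, F² relative).

    Lines starting with ``#`` are headers.  Raises on an empty table.
    """
    data = np.loadtxt(Path(path), comments="#", ndmin=2)
    if data.size == 0:
        raise ValueError(f"{path}: empty form-factor table")
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (q, F^2)")
    q, f = _validate_table(data[:, 0], data[:, 1], str(path))
    return q, f
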