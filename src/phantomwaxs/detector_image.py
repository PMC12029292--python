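"""Detector geometry, event-to-image binning, masks and TIFF round-trips.

The instrument is a vertical-axis diffractometer with a 768 × 512 photon
counting array (135 μm pitch).  The primary beam intersects the detector
at the centre of a short side, on the edge of the sensitive area, so that
one half-plane of scattering angles is recorded out to the far edge.

Conventions
-----------
* image arrays are ``(n_slow, n_fast)`` = (512, 768), row-major;
* pixel indexing is 0-based, the centre of pixel ``(i, j)`` (fast, slow)
  lies at ``((i + 0.5 - c_fast) * pitch, (j + 0.5 - c_slow) * pitch)`` in
  lab millimetres, where ``(c_fast, c_slow)`` is the continuous-pixel beam
  centre;
* the mask is boolean with True = excluded; masking never alters counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorGeometry",
    "ScatterImage",
    "accumulate_image",
    "apply_beamstop_mask",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Planar pixel-array detector geometry.

    ``beam_center_px`` is in continuous pixel units and may lie outside
    the array (edge geometries are the norm here).  ``distance_cm`` is the
    effective sample-to-detector distance used for q conversion; it may be
    None for purely image-domain work.
    """

    n_fast: int = 768
    n_slow: int = 512
    pitch_mm: float = 0.135
    beam_center_px: tuple = (0.0, 256.0)  # (fast, slow), continuous
    distance_cm: float | None = None

    def __post_init__(self):
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be > 0")
        if self.n_fast <= 0 or self.n_slow <= 0:
            raise ValueError("array dimensions must be positive")

    @property
    def shape(self) -> tuple:
        """Image array shape, (n_slow, n_fast)."""
        return (self.n_slow, self.n_fast)

    # -- coordinate transforms ---------------------------------------------------
    def lab_to_pixel(self, x_mm, y_mm):
        """Continuous (fast, slow) pixel coordinates of lab positions (mm)."""
        cf, cs = self.beam_center_px
        return (
            np.asarray(x_mm, dtype=float) / self.pitch_mm + cf,
            np.asarray(y_mm, dtype=float) / self.pitch_mm + cs,
        )

    def pixel_centers_mm(self):
        """Lab-mm coordinates of all pixel centres as (x, y) 2-D arrays."""
        cf, cs = self.beam_center_px
        i = np.arange(self.n_fast)
        j = np.arange(self.n_slow)
        x = (i + 0.5 - cf) * self.pitch_mm
        y = (j + 0.5 - cs) * self.pitch_mm
        return np.meshgrid(x, y)  # shape (n_slow, n_fast) each

    def contains(self, x_mm, y_mm):
        """True for lab positions that fall on the sensitive area."""
        u, v = self.lab_to_pixel(x_mm, y_mm)
        return (u >= 0) & (u < self.n_fast) & (v >= 0) & (v < self.n_slow)


@dataclass
class ScatterImage:
    """Pixel-count raster with a non-destructive exclusion mask."""

    counts: np.ndarray
    mask: np.ndarray | None = None
    geometry: DetectorGeometry | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts")

    @property
    def shape(self):
        return self.counts.shape


def accumulate_image(events, det: DetectorGeometry) -> ScatterImage:
    """Bin detected events into pixel counts.

    ``events`` is the event table produced by the transport engine (any
    mapping/DataFrame with ``x_mm`` and ``y_mm`` columns).  Events whose
    position falls outside the sensitive area are dropped and counted in
    ``metadata['n_dropped']``.
    """
    x = np.asarray(events["x_mm"], dtype=float)
    y = np.asarray(events["y_mm"], dtype=float)
    u, v = det.lab_to_pixel(x, y)
    i = np.floor(u).astype(np.int64)
    j = np.floor(v).astype(np.int64)
    ok = (i >= 0) & (i < det.n_fast) & (j >= 0) & (j < det.n_slow)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("accumulate_image: dropped %d out-of-bounds events", n_dropped)
    counts = np.zeros((det.n_slow, det.n_fast), dtype=np.int64)
    np.add.at(counts, (j[ok], i[ok]), 1)
    return ScatterImage(
        counts=counts,
        geometry=det,
        metadata={"n_events": int(x.size), "n_dropped": n_dropped},
    )


def apply_beamstop_mask(
    img: ScatterImage,
    center_px: tuple,
    radius_px: float,
    arm: tuple | None = None,
) -> ScatterImage:
    """Flag the beam-stop shadow as masked; counts are left untouched.

    The shadow is a filled circle (continuous pixel centre + radius) plus
    an optional support-arm rectangle ``(i_lo, i_hi, j_lo, j_hi)`` in
    pixel units.  Returns a new image sharing nothing with the input.
    """
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    n_slow, n_fast = img.shape
    jj, ii = np.mgrid[0:n_slow, 0:n_fast]
    mask = img.mask.copy()
    if radius_px > 0:
        cf, cs = center_px
        mask |= ((ii + 0.5 - cf) ** 2 + (jj + 0.5 - cs) ** 2) <= radius_px**2
    if arm is not None:
        i_lo, i_hi, j_lo, j_hi = arm
        mask |= (ii + 0.5 >= i_lo) & (ii + 0.5 <= i_hi) & (jj + 0.5 >= j_lo) & (jj + 0.5 <= j_hi)
    meta = dict(img.metadata)
    meta["beamstop"] = {"center_px": tuple(center_px), "radius_px": float(radius_px)}
    return ScatterImage(counts=img.counts.copy(), mask=mask, geometry=img.geometry, metadata=meta)


def write_image(img: ScatterImage, path) -> None:
    """Write counts as 32-bit TIFF; mask (if any pixel set) as a sidecar TIFF.

    Metadata and geometry go into the TIFF ImageDescription as JSON so the
    round-trip is lossless.
    """
    path = Path(path)
    desc = {"metadata": img.metadata}
    if img.geometry is not None:
        g = img.geometry
        desc["geometry"] = {
            "n_fast": g.n_fast,
            "n_slow": g.n_slow,
            "pitch_mm": g.pitch_mm,
            "beam_center_px": list(g.beam_center_px),
            "distance_cm": g.distance_cm,
        }
    tifffile.imwrite(path, img.counts.astype(np.uint32), description=json.dumps(desc))
    if img.mask.any():
        tifffile.imwrite(_mask_path(path), img.mask.astype(np.uint8))


def _mask_path(path: Path) -> Path:
    return path.with_suffix(".mask.tif")


def read_image(path) -> ScatterImage:
    """Read a counts TIFF (+ optional mask sidecar) back to a ScatterImage."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        counts = tif.asarray()
        desc = tif.pages[0].description
    if np.any(np.asarray(counts, dtype=np.int64) < 0):
        raise ValueError(f"{path}: negative pixel values are not a valid count raster")
    geometry = None
    metadata = {}
    if desc:
        try:
            payload = json.loads(desc)
        except json.JSONDecodeError:
            payload = {}
        metadata = payload.get("metadata", {})
        g = payload.get("geometry")
        if g is not None:
            geometry = DetectorGeometry(
                n_fast=g["n_fast"],
                n_slow=g["n_slow"],
                pitch_mm=g["pitch_mm"],
                beam_center_px=tuple(g["beam_center_px"]),
                distance_cm=g.get("distance_cm"),
            )
    mask = None
    mp = _mask_path(path)
    if mp.exists():
        mask = tifffile.imread(mp).astype(bool)
    return ScatterImage(counts=np.asarray(counts, dtype=np.int64), mask=mask,
                        geometry=geometry, metadata=metadata)
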