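"""Prism dispersion geometry and camera/sample-plane scaling.

In slitless ("massively parallel") spectroscopy a prism sits in the imaging
path in front of the camera sensor, so every point emitter is projected as a
wavelength-separated spot pattern along the dispersion axis.  For a thin
prism at small deviation angles the lateral pixel offset of a spot is linear
in the refractive index of the prism material at the emission wavelength.
This module models that mapping with a two-term Cauchy dispersion law for the
prism glass (PMMA by default) and a single gain factor (px per unit
refractive-index difference) that lumps together apex angle, prism-to-sensor
distance and pixel pitch.  The gain is calibrated from one measured spot-pair
separation with known anchor wavelengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CauchyIndex",
    "DispersionModel",
    "CameraGeometry",
    "WavelengthRangeError",
    "refractive_index",
    "calibrate_dispersion",
    "pair_separation",
    "sample_plane_scale",
    "field_width",
]

#: Supported wavelength band of the dispersion model, nm.
WAVELENGTH_BAND = (400.0, 900.0)

#: Default PMMA Cauchy coefficients: two-term fit through datasheet values
#: n(486 nm) = 1.497 and n(589 nm) = 1.492.
PMMA_CAUCHY_A = 1.4813
PMMA_CAUCHY_B = 3698.0  # nm^2


class WavelengthRangeError(ValueError):
    """Wavelength outside the supported band of the dispersion model."""


@dataclass(frozen=True)
class CauchyIndex:
    """Two-term Cauchy refractive index, n(lambda) = A + B / lambda^2.

    Parameters
    ----------
    A : dimensionless index offset (n at the long-wavelength limit).
    B : Cauchy coefficient in nm^2; B > 0 gives normal dispersion
        (n strictly decreasing with wavelength).
    """

    A: float = PMMA_CAUCHY_A
    B: float = PMMA_CAUCHY_B

    def n(self, wavelength_nm: float) -> float:
        lo, hi = WAVELENGTH_BAND
        lam = np.asarray(wavelength_nm, dtype=float)
        if np.any(lam < lo) or np.any(lam > hi):
            raise WavelengthRangeError(
                f"wavelength {wavelength_nm} nm outside supported band "
                f"{lo:.0f}-{hi:.0f} nm"
            )
        out = self.A + self.B / lam**2
        return float(out) if out.ndim == 0 else out


def refractive_index(wavelength_nm: float, index: CauchyIndex | None = None) -> float:
    """Refractive index of the prism material at ``wavelength_nm`` (400-900 nm)."""
    return (index or CauchyIndex()).n(wavelength_nm)


@dataclass(frozen=True)
class DispersionModel:
    """Calibrated thin-prism dispersion: pixel offset linear in n(lambda).

    ``gain`` converts a refractive-index difference into a pixel separation
    on the sensor; it encapsulates the prism apex angle, the 60 mm
    prism-to-sensor distance and the 6.5 um pixel pitch, and is obtained by
    :func:`calibrate_dispersion` from one measured anchor separation.
    ``axis_angle_deg`` orients the dispersion axis in the image plane
    (0 deg = +column direction, shorter wavelengths at smaller column index).
    """

    index: CauchyIndex = field(default_factory=CauchyIndex)
    gain: float = 0.0  # px per unit refractive-index difference
    axis_angle_deg: float = 0.0
    reference_wavelength: float = 802.0  # nm

    def pair_separation(self, lambda1_nm: float, lambda2_nm: float) -> float:
        """Absolute on-sensor separation (px) of the two spots of one emitter."""
        return pair_separation(lambda1_nm, lambda2_nm, self)

    def offset_px(self, wavelength_nm: float) -> tuple[float, float]:
        """Signed (d_row, d_col) offset of a spot relative to the reference
        wavelength's spot.  Shorter wavelengths (larger n) land at smaller
        column index for axis_angle 0."""
        dn = self.index.n(wavelength_nm) - self.index.n(self.reference_wavelength)
        along = -self.gain * dn  # shorter lambda -> larger n -> negative (left)
        theta = math.radians(self.axis_angle_deg)
        return along * math.sin(theta), along * math.cos(theta)


def calibrate_dispersion(
    lambda_short_nm: float,
    lambda_long_nm: float,
    separation_px: float,
    index: CauchyIndex | None = None,
    axis_angle_deg: float = 0.0,
) -> DispersionModel:
    """Calibrate the dispersion gain from one measured spot-pair separation.

    The returned model reproduces ``separation_px`` exactly at the anchor
    wavelengths: gain = separation / (n(lambda_short) - n(lambda_long)).

    Raises
    ------
    ValueError
        If the anchor wavelengths coincide (degenerate anchor) or the
        separation is not positive.
    """
    index = index or CauchyIndex()
    if lambda_short_nm >= lambda_long_nm:
        raise ValueError("anchor requires lambda_short < lambda_long")
    if separation_px <= 0:
        raise ValueError("anchor separation must be positive")
    dn = index.n(lambda_short_nm) - index.n(lambda_long_nm)
    if dn <= 0:
        raise ValueError("degenerate anchor: no index contrast between anchors")
    return DispersionModel(
        index=index,
        gain=separation_px / dn,
        axis_angle_deg=axis_angle_deg,
        reference_wavelength=lambda_long_nm,
    )


def pair_separation(
    lambda1_nm: float, lambda2_nm: float, model: DispersionModel
) -> float:
    """Spot-pair separation in px for two emission wavelengths.

    Symmetric in its wavelength arguments, zero for equal wavelengths, and
    additive over intermediate wavelengths (the offset is linear in n).
    """
    if model.gain <= 0:
        raise ValueError("model is not calibrated (gain must be positive)")
    n1 = model.index.n(lambda1_nm)
    n2 = model.index.n(lambda2_nm)
    return abs(model.gain * (n1 - n2))


@dataclass(frozen=True)
class CameraGeometry:
    """Camera sensor and imaging geometry.

    Defaults match an sCMOS with 6.5 um pixels behind a 60x objective,
    1024 x 1024 px frames, 10 ms exposures at 100 ms frame intervals.
    """

    pixel_pitch_um: float = 6.5
    magnification: float = 60.0
    frame_size_px: int = 1024
    exposure_ms: float = 10.0
    frame_interval_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0 or self.magnification <= 0:
            raise ValueError("pixel pitch and magnification must be positive")
        if self.frame_size_px <= 0:
            raise ValueError("frame size must be positive")


def sample_plane_scale(geom: CameraGeometry) -> float:
    """Sample-plane size of one pixel, um/px (pitch / magnification)."""
    return geom.pixel_pitch_um / geom.magnification


def field_width(geom: CameraGeometry) -> float:
    """Field-of-view width in the sample plane, um."""
    return geom.frame_size_px * sample_plane_scale(geom)
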