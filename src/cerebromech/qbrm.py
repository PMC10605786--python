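"""Quantitative birefringence microscopy: six-frame polarizer-step inversion.

With a linear polarizer stepped through theta_k = k*30 deg (k = 0..5) and a
circular analyzer, each pixel's intensity follows

    I(theta) = a0 * (1 + r * sin(2*(theta - phi)))

where a0 is the mean intensity, r in [0, 1] the relative retardance
(normalized modulation amplitude), and phi in [0, pi) the in-plane
optic-axis orientation, measured counterclockwise from the horizontal
image axis.  Because 2*theta samples the full circle at exact 60 deg
steps, the harmonic coefficients come from discrete-Fourier orthogonality:

    a0 = mean_k I_k
    c  = (2/6) * sum_k I_k cos(2 theta_k)   (= -a0 r sin 2phi)
    s  = (2/6) * sum_k I_k sin(2 theta_k)   (=  a0 r cos 2phi)

so r = sqrt(c^2 + s^2)/a0 and phi = atan2(-c, s)/2 wrapped to [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

POLARIZER_ANGLES_DEG = np.arange(6) * 30.0
#: orientation is meaningless where the modulation is in the noise floor
DEFAULT_RETARDANCE_FLOOR = 0.02


class QBRMError(ValueError):
    pass


@dataclass(frozen=True)
class PolarizationStack:
    """Six co-registered intensity frames at polarizer angles 0,30,...,150 deg."""

    frames: np.ndarray  # (6, H, W)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] != 6:
            raise QBRMError(f"need exactly 6 frames, got shape {self.frames.shape}")

    @property
    def angles_deg(self) -> np.ndarray:
        return POLARIZER_ANGLES_DEG


@dataclass
class BirefringenceMaps:
    """Per-pixel harmonic decomposition of a polarization stack."""

    a0: np.ndarray
    retardance_rel: np.ndarray  # in [0, 1]; 0 where invalid
    orientation_phi: np.ndarray  # radians in [0, pi); NaN where masked
    valid: np.ndarray  # a0 > 0
    oriented: np.ndarray  # valid & retardance above floor


def invert_stack(
    stack: PolarizationStack, retardance_floor: float = DEFAULT_RETARDANCE_FLOOR
) -> BirefringenceMaps:
    """Per-pixel harmonic regression of the six-angle intensity series.

    Pixels with a0 <= 0 are masked invalid; orientation is additionally
    masked (NaN) where the relative retardance is below ``retardance_floor``.
    Retardance estimates are clipped to [0, 1] (noise can push the raw
    ratio marginally above 1).
    """
    I = np.asarray(stack.frames, dtype=float)
    two_theta = 2.0 * np.deg2rad(POLARIZER_ANGLES_DEG)[:, None, None]
    a0 = I.mean(axis=0)
    c = (I * np.cos(two_theta)).sum(axis=0) / 3.0
    s = (I * np.sin(two_theta)).sum(axis=0) / 3.0

    valid = a0 > 0
    r = np.zeros_like(a0)
    np.divide(np.hypot(c, s), a0, out=r, where=valid)
    r = np.clip(r, 0.0, 1.0)

    phi = np.mod(0.5 * np.arctan2(-c, s), np.pi)
    oriented = valid & (r >= retardance_floor)
    phi = np.where(oriented, phi, np.nan)
    return BirefringenceMaps(a0=a0, retardance_rel=r, orientation_phi=phi, valid=valid, oriented=oriented)


def render_orientation(maps: BirefringenceMaps) -> np.ndarray:
    """Retardance-weighted orientation map as an RGB float array.

    Hue encodes phi on a pi-periodic color wheel; brightness encodes the
    relative retardance, so isotropic or invalid pixels render black.
    """
    h, w = maps.a0.shape
    hue = np.where(np.isnan(maps.orientation_phi), 0.0, maps.orientation_phi / np.pi)
    value = np.where(maps.oriented, maps.retardance_rel, 0.0)
    hsv = np.stack([hue, np.ones((h, w)), value], axis=-1)
    return hsv_to_rgb(hsv)


def render_retardance(maps: BirefringenceMaps) -> np.ndarray:
    """Grayscale relative-retardance image in [0, 1]."""
    return np.where(maps.valid, maps.retardance_rel, 0.0)
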