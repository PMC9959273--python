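"""Chiral-nematic (cholesteric) structure optics.

A cholesteric film selectively reflects a photonic-bandgap (PBG) band at

    lambda = n * P * sin(theta)

where ``n`` is the film's average refractive index, ``P`` the helical pitch
(the distance over which the director rotates a full 360 degrees) and
``theta`` the reflection angle. In the layer-stacking picture the pitch is
set by how many rod layers a full period needs: adjacent layers rotate by the
cross angle ``alpha``, so a period stacks ``360/alpha`` layers at spacing
``d`` and ``P = (360/alpha) * d``. A larger cross angle or a tighter layer
spacing therefore blue-shifts the reflected color.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PitchModel",
    "pbg_wavelength",
    "layers_per_period",
    "pitch_from_stacking",
    "blueshift_series",
    "DEFAULT_REFRACTIVE_INDEX",
    "DEFAULT_REFLECTION_ANGLE",
]

#: Average refractive index of a dried CNC film.
DEFAULT_REFRACTIVE_INDEX = 1.55
#: Normal-incidence reflection, degrees.
DEFAULT_REFLECTION_ANGLE = 90.0


@dataclass(frozen=True)
class PitchModel:
    """Helix state: pitch (nm), refractive index, reflection angle (deg), and
    optionally the microscopic stacking parameters behind the pitch
    (cross angle in degrees per adjacent layer, center-to-center layer
    spacing in nm)."""

    pitch: float
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    reflection_angle: float = DEFAULT_REFLECTION_ANGLE
    cross_angle: float | None = None
    layer_spacing: float | None = None

    def __post_init__(self) -> None:
        if not self.pitch > 0:
            raise ValueError("pitch must be > 0 nm")
        if not 0 < self.reflection_angle <= 90:
            raise ValueError("reflection_angle must be in (0, 90] degrees")
        if self.cross_angle is not None and not 0 < self.cross_angle < 180:
            raise ValueError("cross_angle must be in (0, 180) degrees")
        if self.layer_spacing is not None and not self.layer_spacing > 0:
            raise ValueError("layer_spacing must be > 0 nm")

    @classmethod
    def from_stacking(
        cls,
        cross_angle: float,
        layer_spacing: float,
        refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
        reflection_angle: float = DEFAULT_REFLECTION_ANGLE,
    ) -> "PitchModel":
        """Build the helix from the layer-stacking parameters."""
        return cls(
            pitch=pitch_from_stacking(cross_angle, layer_spacing),
            refractive_index=refractive_index,
            reflection_angle=reflection_angle,
            cross_angle=cross_angle,
            layer_spacing=layer_spacing,
        )

    @property
    def wavelength(self) -> float:
        """PBG wavelength in nm."""
        return pbg_wavelength(self)


def pbg_wavelength(model: PitchModel) -> float:
    """Reflected band center lambda = n * P * sin(theta), nm.

    Linear in both pitch and refractive index; at normal incidence
    (theta = 90 deg) it reduces to lambda = n * P.
    """
    theta = np.deg2rad(model.reflection_angle)
    return float(model.refractive_index * model.pitch * np.sin(theta))


def layers_per_period(cross_angle):
    """Number of stacked layers completing a 360-degree helical period.

    N = 360 / alpha, strictly decreasing in the cross angle.
    """
    alpha = np.asarray(cross_angle, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= 180):
        raise ValueError("cross_angle must be in (0, 180) degrees")
    out = 360.0 / alpha
    return out if out.ndim else float(out)


def pitch_from_stacking(cross_angle, layer_spacing):
    """Pitch P = (360/alpha) * d in nm: decreasing in alpha, increasing in d."""
    d = np.asarray(layer_spacing, dtype=float)
    if np.any(d <= 0):
        raise ValueError("layer_spacing must be > 0 nm")
    out = layers_per_period(cross_angle) * d
    return out if out.ndim else float(out)


def blueshift_series(
    cross_angles,
    spacings,
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
    reflection_angle: float = DEFAULT_REFLECTION_ANGLE,
) -> np.ndarray:
    """Element-wise PBG wavelengths for a series of stacking states.

    If the cross angles are non-decreasing and the spacings non-increasing
    along the series (the squeeze/charge-screening trend as additive loading
    grows), the wavelength sequence is non-increasing — a monotone blue-shift.
    """
    alphas = np.asarray(cross_angles, dtype=float)
    ds = np.asarray(spacings, dtype=float)
    if alphas.shape != ds.shape:
        raise ValueError(f"length mismatch: {alphas.shape} cross angles vs {ds.shape} spacings")
    pitch = pitch_from_stacking(alphas, ds)
    theta = np.deg2rad(reflection_angle)
    return refractive_index * np.atleast_1d(pitch) * np.sin(theta)
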