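"""Closed-form spherical volume-of-tissue-activated overlap.

Two equal spheres of radius ``r`` whose centers are ``d`` apart intersect
in a lens of volume ``pi * (4r + d) * (2r - d)^2 / 12`` for ``0 <= d < 2r``
and 0 otherwise; the Dice coefficient of equal spheres is the lens volume
divided by the sphere volume. Only the equal-radius case is supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InputError

__all__ = [
    "SphericalVTA",
    "sphere_radius_from_volume",
    "sphere_intersection_volume",
    "dice_after_shift",
    "round_half_away",
]


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (matching conventional reporting)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


@dataclass(frozen=True)
class SphericalVTA:
    """A spherical activation volume; radius and volume kept consistent."""

    volume: float  # mm^3
    radius: float  # mm

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.radius <= 0:
            raise InputError("volume and radius must be positive")
        expected = (4.0 / 3.0) * math.pi * self.radius**3
        if abs(expected - self.volume) > 1e-9 * max(1.0, self.volume):
            raise InputError(
                f"inconsistent sphere: volume {self.volume} vs radius {self.radius}"
            )

    @classmethod
    def from_volume(cls, volume: float) -> "SphericalVTA":
        return cls(volume=volume, radius=sphere_radius_from_volume(volume))


def sphere_radius_from_volume(volume: float) -> float:
    """Radius in mm of a sphere with the given volume in mm^3."""
    if volume <= 0:
        raise InputError(f"volume must be positive, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def sphere_intersection_volume(radius: float, shift: float) -> float:
    """Lens volume (mm^3) of two equal spheres with centers ``shift`` apart."""
    if radius <= 0:
        raise InputError(f"radius must be positive, got {radius}")
    if shift < 0:
        raise InputError(f"shift must be nonnegative, got {shift}")
    if shift >= 2.0 * radius:
        return 0.0
    return math.pi * (4.0 * radius + shift) * (2.0 * radius - shift) ** 2 / 12.0


def dice_after_shift(volume: float, shift: float) -> float:
    """Dice overlap of two equal spheres of the given volume after a center shift."""
    radius = sphere_radius_from_volume(volume)
    return sphere_intersection_volume(radius, shift) / volume
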