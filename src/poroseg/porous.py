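"""Intensity-to-porosity conversion and porous viscous resistance.

The partial volume effect makes a boundary voxel's intensity a linear blend
of pure-fluid and pure-solid intensities, so the fluid fraction (porosity)
of each voxel is recovered by inverting that blend:

    eps = (I_v - I_s) / (I_f - I_s),   clipped to [0, 1].

Each partially occupied voxel is then modelled as a porous medium.  In the
shrunken-voxel picture the solid occupies one slab of the voxel and the
fluid the opposing slab, which yields a purely viscous flow resistance

    P_v = 3 (1 - eps)^2 / (eps^3 d^2) * mu      [kg m^-3 s^-1]

with ``d`` the (isotropic) voxel edge length in metres.  Voxels with
``eps <= eps_min`` (default 0.1) are treated as entirely solid and removed
from the flow domain; ``eps = 1`` voxels carry no resistance.  The classical
packed-bed (Blake-Kozeny) resistance and the Blake number diagnostic are
provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imagepre import VolumetricImage

#: Viscous constant of the shrunken-voxel resistance law.
SHRUNKEN_A = 3.0
#: Inertial constant; creeping-flow calibration finds it negligible.
SHRUNKEN_B = 0.0

#: Default porosity at/below which a voxel counts as entirely solid.
DEFAULT_EPS_MIN = 0.1


@dataclass(frozen=True)
class ConversionSpec:
    """Reference intensities of pure fluid and pure solid.

    Either orientation is allowed: bright fluid (CT angiography lumen) has
    ``I_f > I_s``; dark fluid (air in airways) has ``I_f < I_s``.
    """

    i_fluid: float
    i_solid: float

    def __post_init__(self) -> None:
        if self.i_fluid == self.i_solid:
            raise ValueError("fluid and solid reference intensities must differ")

    @classmethod
    def from_range(cls, i_min: float, i_max: float, fluid_bright: bool = True
                   ) -> "ConversionSpec":
        """Map a coarse intensity range onto (I_f, I_s) by orientation."""
        return cls(i_max, i_min) if fluid_bright else cls(i_min, i_max)


@dataclass(frozen=True)
class FluidProps:
    """Newtonian working fluid: density (kg m^-3) and viscosity (Pa s)."""

    rho: float
    mu: float

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid density and viscosity must be positive")


#: Working-fluid presets; the segmentation outcome is insensitive to the
#: choice as long as the flow stays in the creeping regime.
FLUID_PRESETS = {
    "blood": FluidProps(rho=1030.0, mu=0.004),
    "air": FluidProps(rho=1.18415, mu=1.85508e-5),
    "unit": FluidProps(rho=1000.0, mu=1e-3),
}


@dataclass
class PorosityField:
    """Per-voxel porosity in [0, 1] with a solid mask and spacing (mm)."""

    epsilon: np.ndarray
    spacing_mm: np.ndarray
    solid_mask: np.ndarray | None = None
    eps_min: float | None = None

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        if self.epsilon.min() < 0 or self.epsilon.max() > 1:
            raise ValueError("porosity must lie in [0, 1]")

    @property
    def fluid_mask(self) -> np.ndarray:
        if self.solid_mask is None:
            raise ValueError("porosity field has not been solidified yet")
        return ~self.solid_mask

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing_mm, self.spacing_mm[0]))


@dataclass
class ResistanceField:
    """Per-voxel viscous (and optional inertial) porous resistance.

    ``P_v`` is in kg m^-3 s^-1; ``P_i`` (kg m^-4) defaults to zero because
    the creeping-flow calibration finds the inertial constant negligible.
    ``d`` is the voxel edge length in metres used to evaluate the law.
    """

    P_v: np.ndarray
    d: float
    P_i: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.P_v = np.asarray(self.P_v, dtype=np.float64)
        if np.any(self.P_v < 0):
            raise ValueError("viscous resistance must be non-negative")
        if self.P_i is None:
            self.P_i = np.zeros_like(self.P_v)


def porosity_from_intensity(img: VolumetricImage, spec: ConversionSpec,
                            candidate_mask: np.ndarray | None = None,
                            clip: bool = True) -> PorosityField:
    """Invert the partial-volume blend to get per-voxel porosity.

    Voxels outside ``candidate_mask`` (from coarse thresholding) get
    porosity zero.  Values are clipped to [0, 1]: local intensity can
    overshoot the reference values (noise, calcifications).
    """
    eps = (img.data - spec.i_solid) / (spec.i_fluid - spec.i_solid)
    if clip:
        eps = np.clip(eps, 0.0, 1.0)
    if candidate_mask is not None:
        eps = np.where(candidate_mask, eps, 0.0)
    return PorosityField(eps, img.spacing)


def solidify(pf: PorosityField, eps_min: float = DEFAULT_EPS_MIN) -> PorosityField:
    """Mark voxels with ``eps <= eps_min`` as entirely solid (closed bound).

    Solid voxels are excluded from the flow domain; the resistance law is
    singular as porosity tends to zero, so a minimum porosity is required.
    """
    if not 0 < eps_min < 1:
        raise ValueError("eps_min must lie strictly between 0 and 1")
    solid = pf.epsilon <= eps_min
    return PorosityField(pf.epsilon.copy(), pf.spacing_mm.copy(), solid, eps_min)


def shrunken_viscous_resistance(pf: PorosityField, fluid: FluidProps) -> ResistanceField:
    """Shrunken-voxel viscous resistance ``P_v = 3 (1-eps)^2 mu / (eps^3 d^2)``.

    Requires a solidified, isotropic-spacing porosity field; solid voxels get
    ``P_v = 0`` (they are outside the flow domain), as do fully fluid voxels.
    """
    if pf.solid_mask is None:
        raise ValueError("solidify() the porosity field first")
    if not pf.is_isotropic:
        raise ValueError("resistance law requires isotropic voxel spacing; resample first")
    d = float(pf.spacing_mm[0]) * 1e-3  # m
    eps = pf.epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        pv = SHRUNKEN_A * (1.0 - eps) ** 2 / (eps ** 3 * d * d) * fluid.mu
    pv = np.where(pf.solid_mask, 0.0, pv)
    pv = np.where(eps >= 1.0, 0.0, pv)
    return ResistanceField(pv, d)


def packed_bed_viscous_resistance(eps, fluid: FluidProps, particle_diameter: float):
    """Blake-Kozeny packed-bed viscous resistance (comparison mode only).

    ``P_v = 150 (1-eps)^2 / eps^3 * mu / D_p^2`` for a bed of spheres of
    diameter ``D_p`` (m).  Degenerate at eps in {0, 1}.
    """
    eps = np.asarray(eps, dtype=float)
    if particle_diameter <= 0:
        raise ValueError("particle diameter must be positive")
    if np.any(eps <= 0) or np.any(eps >= 1):
        raise ValueError("packed-bed resistance requires 0 < eps < 1")
    out = 150.0 * (1.0 - eps) ** 2 / eps ** 3 * fluid.mu / particle_diameter ** 2
    return float(out) if out.ndim == 0 else out


def blake_number(speed, eps, d: float, fluid: FluidProps):
    """Blake number ``Bl = (rho u d / mu) * eps / (1 - eps)`` per voxel.

    A porous-media Reynolds analogue; ``Bl << 1`` means viscous resistance
    dominates.  Undefined (reported as +inf) at eps = 1.
    """
    speed = np.asarray(speed, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("Blake number requires eps > 0")
    with np.errstate(divide="ignore"):
        out = (fluid.rho * speed * d / fluid.mu) * np.where(
            eps < 1, eps / (1.0 - eps), np.inf)
    out = np.where((speed == 0) & np.isnan(out), 0.0, out)
    return float(out) if out.ndim == 0 else out


def render_intensity_from_porosity(eps: np.ndarray, spec: ConversionSpec) -> np.ndarray:
    """Forward partial-volume blend ``I = I_s + eps (I_f - I_s)``."""
    return spec.i_solid + np.asarray(eps, float) * (spec.i_fluid - spec.i_solid)
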