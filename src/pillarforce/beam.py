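"""Elliptical-cantilever beam mechanics for force-sensing pillars.

Compliant pillars spanned by an engineered muscle bundle act as force
transducers: the tissue bends each pillar laterally, and the bending
deflection, read off a microscope video, is converted to force through the
cantilever's lateral stiffness.  For a clamped-base beam of height ``h``
with an elliptical cross-section (semi-axes ``a`` and ``b``, ``b`` along
the bending direction) loaded by a point force at height ``h``, small
deflection Euler–Bernoulli theory gives

    I    = pi * a * b**3 / 4          (second moment of area)
    k(h) = 3 * E * I / h**3           (lateral stiffness)
    F    = k * delta                  (Hooke's law)

All public functions take geometry in micrometres and moduli in MPa and
return stiffness in uN/um (numerically equal to N/m) and force in uN.
Internally lengths are converted to metres so that the formulas are in SI;
the conversion lives only in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PillarGeometry",
    "StiffnessResult",
    "InvalidGeometryError",
    "second_moment_elliptical",
    "lateral_stiffness",
    "force_from_deflection",
    "back_calculate_modulus",
    "shear_modulus",
    "deflection_under_load",
    "design_space_sweep",
    "tip_deflection_numeric",
    "SMALL_DEFLECTION_RATIO",
]

_UM = 1e-6  # metres per micrometre
_MPA = 1e6  # Pa per MPa

#: deflection/height ratio beyond which linear beam theory is unreliable
SMALL_DEFLECTION_RATIO = 0.1


class InvalidGeometryError(ValueError):
    """Raised when pillar geometry violates its physical invariants."""


@dataclass(frozen=True)
class PillarGeometry:
    """Elliptical cantilever pillar: dimensions in um, modulus in MPa.

    ``semi_minor_b_um`` is the semi-axis along the bending direction (the
    interpillar axis); the pillar is elongated orthogonal to the muscle
    bundle so that it bends preferentially along the line of action.
    Defaults are the platform's standard pillar: a = 300 um, b = 200 um,
    h = 4 mm, E = 2.414 MPa, nu = 0.49.
    """

    semi_major_a_um: float = 300.0
    semi_minor_b_um: float = 200.0
    height_h_um: float = 4000.0
    youngs_modulus_mpa: float = 2.414
    poisson_nu: float = 0.49

    def __post_init__(self) -> None:
        if not (self.semi_minor_b_um > 0 and self.semi_major_a_um >= self.semi_minor_b_um):
            raise InvalidGeometryError(
                f"require semi_major_a >= semi_minor_b > 0, got "
                f"a={self.semi_major_a_um}, b={self.semi_minor_b_um}"
            )
        if self.height_h_um <= 0:
            raise InvalidGeometryError(f"height must be positive, got {self.height_h_um}")
        if self.youngs_modulus_mpa <= 0:
            raise InvalidGeometryError(
                f"Young's modulus must be positive, got {self.youngs_modulus_mpa}"
            )
        if not 0.0 < self.poisson_nu < 0.5:
            raise InvalidGeometryError(
                f"Poisson ratio must lie in (0, 0.5), got {self.poisson_nu}"
            )

    def with_modulus(self, youngs_modulus_mpa: float) -> "PillarGeometry":
        return replace(self, youngs_modulus_mpa=youngs_modulus_mpa)


@dataclass(frozen=True)
class StiffnessResult:
    """Derived mechanical quantities for one pillar geometry."""

    second_moment_I_m4: float
    stiffness_k_un_per_um: float
    shear_modulus_mu_mpa: float

    def __post_init__(self) -> None:
        if not (
            self.second_moment_I_m4 > 0
            and self.stiffness_k_un_per_um > 0
            and self.shear_modulus_mu_mpa > 0
        ):
            raise ValueError("all stiffness-result fields must be strictly positive")


def second_moment_elliptical(geometry: PillarGeometry) -> float:
    """Second moment of area ``I = pi*a*b^3/4`` of the elliptical section, in m^4.

    ``b`` is the semi-axis along the bending direction, so it enters cubed.
    """
    a = geometry.semi_major_a_um * _UM
    b = geometry.semi_minor_b_um * _UM
    return np.pi * a * b**3 / 4.0


def lateral_stiffness(geometry: PillarGeometry, load_height_um: float | None = None) -> float:
    """Cantilever lateral stiffness ``k = 3EI/h^3`` in uN/um.

    ``load_height_um`` is the height of the applied point load above the
    clamped base; it defaults to the full pillar height (tissue attaches
    near the pillar free end).
    """
    h_um = geometry.height_h_um if load_height_um is None else load_height_um
    if not 0.0 < h_um <= geometry.height_h_um:
        raise ValueError(
            f"load height must lie in (0, {geometry.height_h_um}] um, got {h_um}"
        )
    E = geometry.youngs_modulus_mpa * _MPA
    I = second_moment_elliptical(geometry)
    h = h_um * _UM
    k_si = 3.0 * E * I / h**3  # N/m == uN/um numerically
    return k_si


def force_from_deflection(stiffness_k_un_per_um: float, deflection_um: float) -> float:
    """Hooke's law ``F = k * delta``; force in uN, sign follows the deflection."""
    if stiffness_k_un_per_um <= 0:
        raise ValueError(f"stiffness must be positive, got {stiffness_k_un_per_um}")
    return stiffness_k_un_per_um * np.asarray(deflection_um) * 1.0


def back_calculate_modulus(
    stiffness_k_un_per_um: float,
    geometry: PillarGeometry,
    load_height_um: float | None = None,
) -> float:
    """Invert ``k = 3EI/h^3`` for the material modulus, in MPa.

    The modulus stored on ``geometry`` is ignored; only the section and the
    load height are used.  Round-tripping through :func:`lateral_stiffness`
    is the identity.
    """
    if stiffness_k_un_per_um <= 0:
        raise ValueError(f"stiffness must be positive, got {stiffness_k_un_per_um}")
    h_um = geometry.height_h_um if load_height_um is None else load_height_um
    if not 0.0 < h_um <= geometry.height_h_um:
        raise ValueError(
            f"load height must lie in (0, {geometry.height_h_um}] um, got {h_um}"
        )
    I = second_moment_elliptical(geometry)
    h = h_um * _UM
    E_pa = stiffness_k_un_per_um * h**3 / (3.0 * I)
    return E_pa / _MPA


def shear_modulus(youngs_modulus_mpa: float, poisson_nu: float) -> float:
    """Isotropic shear modulus ``mu = E / (2(1+nu))`` in MPa."""
    if youngs_modulus_mpa <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0.0 < poisson_nu < 0.5:
        raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {poisson_nu}")
    return youngs_modulus_mpa / (2.0 * (1.0 + poisson_nu))


def stiffness_summary(geometry: PillarGeometry) -> StiffnessResult:
    """Bundle I, k and mu for one geometry."""
    return StiffnessResult(
        second_moment_I_m4=second_moment_elliptical(geometry),
        stiffness_k_un_per_um=lateral_stiffness(geometry),
        shear_modulus_mu_mpa=shear_modulus(geometry.youngs_modulus_mpa, geometry.poisson_nu),
    )


def deflection_under_load(geometry: PillarGeometry, force_un: float) -> float:
    """Tip deflection ``delta = F / k(h)`` in um for a point load at the tip.

    Emits a warning when ``|delta|/h`` exceeds the small-deflection limit
    (0.1): beyond that ratio the linear model overstates compliance.
    """
    if not np.isfinite(force_un):
        raise ValueError("force must be finite")
    k = lateral_stiffness(geometry)
    delta_um = force_un / k
    if abs(delta_um) / geometry.height_h_um > SMALL_DEFLECTION_RATIO:
        warnings.warn(
            f"predicted deflection {delta_um:.1f} um exceeds "
            f"{SMALL_DEFLECTION_RATIO:.0%} of pillar height: outside the "
            "small-deflection regime of linear beam theory",
            stacklevel=2,
        )
    return delta_um


def design_space_sweep(
    heights_mm: "list[float] | np.ndarray",
    semi_minor_axes_um: "list[float] | np.ndarray",
    reference_force_un: float = 38.0,
    aspect_ratio: float = 1.5,
    youngs_modulus_mpa: float = 2.414,
    poisson_nu: float = 0.49,
) -> pd.DataFrame:
    """Grid of stiffness and deflection over pillar height and thickness.

    ``semi_minor_axes_um`` are bending-direction semi-axes b; the semi-major
    axis follows the fixed elliptical aspect ratio (default 1.5:1), so the
    standard design grid {150, 200, 250, 300} um contains the platform's
    chosen pillar (a=300, b=200) as a grid point.  The default reference
    load of 38 uN is the per-pillar share of a 76 uN two-pillar static
    contraction.  Returns a DataFrame ordered by (h, b) with columns
    ``h_mm, b_um, k_uN_per_um, delta_um``.
    """
    heights = np.asarray(heights_mm, dtype=float)
    minors = np.asarray(semi_minor_axes_um, dtype=float)
    if heights.size == 0 or minors.size == 0:
        raise ValueError("height and thickness grids must be non-empty")
    rows = []
    for h_mm in np.sort(heights):
        for b in np.sort(minors):
            a = b * aspect_ratio
            geom = PillarGeometry(
                semi_major_a_um=a,
                semi_minor_b_um=b,
                height_h_um=h_mm * 1000.0,
                youngs_modulus_mpa=youngs_modulus_mpa,
                poisson_nu=poisson_nu,
            )
            k = lateral_stiffness(geom)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                delta = deflection_under_load(geom, reference_force_un)
            rows.append(
                {"h_mm": h_mm, "b_um": b, "k_uN_per_um": k, "delta_um": delta}
            )
    return pd.DataFrame(rows)


def tip_deflection_numeric(
    geometry: PillarGeometry, force_un: float, n_points: int = 2001
) -> float:
    """Tip deflection in um by numerical integration of the bending ODE.

    Integrates the Euler–Bernoulli curvature equation
    ``w''(x) = M(x)/(EI)`` with ``M(x) = F (h - x)`` for a clamped base
    (``w(0) = w'(0) = 0``) using cumulative trapezoids, without invoking the
    closed-form ``F h^3 / 3EI``.  Serves as an independent numerical oracle
    for :func:`lateral_stiffness` / :func:`deflection_under_load`.
    """
    E = geometry.youngs_modulus_mpa * _MPA
    I = second_moment_elliptical(geometry)
    h = geometry.height_h_um * _UM
    F = force_un * 1e-6
    x = np.linspace(0.0, h, n_points)
    curvature = F * (h - x) / (E * I)
    slope = cumulative_trapezoid(curvature, x, initial=0.0)
    w = cumulative_trapezoid(slope, x, initial=0.0)
    return w[-1] / _UM
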