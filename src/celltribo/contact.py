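"""Hertzian sphere-on-flat contact and the monolayer-piercing track model.

For a rigid-frame comparison of load conditions across substrates, the
classical Hertz solution for an elastic sphere on an elastic half-space
gives contact radius, indentation and maximum pressure::

    a  = (3 F R / 4 E*)^(1/3)
    d  = a^2 / R
    p0 = 3 F / (2 pi a^2)        with  1/E* = (1-nu1^2)/E1 + (1-nu2^2)/E2

The maximum Hertz pressure between probe and bare substrate, p0, serves as
a severity index for the load condition a cell monolayer experiences.

The piercing model explains why the kill-track width on a stiff substrate
barely grows with load although the Hertz radius scales as F^(1/3): cells
are soft and burst once compressed to a critical thickness h_crit, after
which the substrate carries the load (the monolayer is treated as
load-transparent).  Cells die wherever the sphere-substrate gap
``g(r) = r^2/(2R) - d`` falls below h_crit, so the predicted full width is
``2 * sqrt(2R (h_crit + d))`` with ``d`` the substrate indentation.

Units: interfaces use mN, mm, um and kPa as stated per field; conversions
to SI happen internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "SphereProbe",
    "ContactResult",
    "PiercingModel",
    "ContactError",
    "MATERIALS",
    "effective_modulus",
    "hertz_contact",
    "pierced_track_width",
    "pressure_sweep",
]


class ContactError(ValueError):
    """Raised on invalid contact-mechanics inputs."""


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: Young's modulus [kPa], Poisson ratio."""

    E: float   # kPa
    nu: float

    def __post_init__(self) -> None:
        if not (self.E > 0):
            raise ContactError("Young's modulus must be positive")
        if not (-1.0 < self.nu <= 0.5):
            raise ContactError("Poisson ratio must lie in (-1, 0.5]")


#: Default material table.  The soft silicone modulus follows the casting
#: protocol this pipeline accompanies (73.32 kPa); the others are standard
#: handbook values for the probe and dish materials.
MATERIALS: dict[str, Material] = {
    "pdms_soft": Material(E=73.32, nu=0.5),
    "polystyrene": Material(E=3.3e6, nu=0.35),
    "glass": Material(E=7.0e7, nu=0.22),
    "cell_monolayer": Material(E=5.0, nu=0.5),
}


@dataclass(frozen=True)
class SphereProbe:
    """Spherical probe of radius R [mm] (2 mm glass sphere -> R = 1)."""

    R: float  # mm

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise ContactError("probe radius must be positive")


@dataclass(frozen=True)
class ContactResult:
    """Hertz contact quantities; self-consistency is enforced on creation."""

    a: float       # contact radius [um]
    delta: float   # indentation depth [um]
    p0: float      # maximum pressure [kPa]
    e_star: float  # effective modulus [kPa]
    f: float       # normal force [mN]

    def __post_init__(self) -> None:
        if min(self.a, self.delta, self.p0) < 0:
            raise ContactError("contact quantities cannot be negative")
        if self.a > 0:
            # p0 = 3F/(2 pi a^2) in consistent units: mN / um^2 -> kPa x 1e6
            p0_check = 3.0 * self.f / (2.0 * np.pi * self.a**2) * 1e6
            if abs(p0_check - self.p0) > 1e-9 * max(self.p0, 1.0):
                raise ContactError("p0 inconsistent with 3F/(2 pi a^2)")


@dataclass(frozen=True)
class PiercingModel:
    """Geometry of the pierce-through kill zone.

    ``h_cell`` is the undeformed monolayer thickness, ``h_crit`` the
    compressed thickness at which a cell bursts; both in um and explicit
    inputs, never hidden constants.
    """

    substrate: Material
    probe: SphereProbe
    h_cell: float = 3.0    # um
    h_crit: float = 0.8    # um
    probe_material: Material = MATERIALS["glass"]

    def __post_init__(self) -> None:
        if not (0.0 < self.h_crit <= self.h_cell):
            raise ContactError("require 0 < h_crit <= h_cell")


def effective_modulus(m1: Material, m2: Material) -> float:
    """Effective contact modulus E* [kPa]: 1/E* = sum (1-nu_i^2)/E_i."""
    inv = (1.0 - m1.nu**2) / m1.E + (1.0 - m2.nu**2) / m2.E
    return 1.0 / inv


def hertz_contact(f_mn: float, probe: SphereProbe, e_star_kpa: float) -> ContactResult:
    """Closed-form Hertz contact for normal force ``f_mn`` [mN].

    Returns contact radius [um], indentation [um] and maximum pressure [kPa].
    """
    if f_mn < 0:
        raise ContactError("normal force cannot be negative")
    if e_star_kpa <= 0:
        raise ContactError("effective modulus must be positive")
    f = f_mn * 1e-3          # N
    r = probe.R * 1e-3       # m
    e_star = e_star_kpa * 1e3  # Pa
    if f == 0.0:
        return ContactResult(a=0.0, delta=0.0, p0=0.0, e_star=e_star_kpa, f=0.0)
    a = (3.0 * f * r / (4.0 * e_star)) ** (1.0 / 3.0)   # m
    delta = a**2 / r                                     # m
    p0 = 3.0 * f / (2.0 * np.pi * a**2)                  # Pa
    return ContactResult(
        a=a * 1e6, delta=delta * 1e6, p0=p0 * 1e-3, e_star=e_star_kpa, f=f_mn
    )


def pierced_track_width(f_mn: float, model: PiercingModel) -> dict[str, float]:
    """Predicted kill-track full width [um] once the monolayer is pierced.

    The monolayer is treated as load-transparent: the substrate alone
    carries the load, indenting by the Hertz depth ``delta``.  Cells are
    destroyed wherever the rigid-geometry sphere-substrate gap
    ``g(r) = r^2/(2R) - delta`` is below ``h_crit``.

    Returns a report with the predicted width, the underlying substrate
    contact, the monolayer-contact chord (gap < h_cell) and the assumed
    load sharing.
    """
    contact = hertz_contact(
        f_mn, model.probe, effective_modulus(model.probe_material, model.substrate)
    )
    r_um = model.probe.R * 1e3
    r_kill = np.sqrt(2.0 * r_um * (model.h_crit + contact.delta))
    r_cell = np.sqrt(2.0 * r_um * (model.h_cell + contact.delta))
    return {
        "f_mN": f_mn,
        "width_um": 2.0 * r_kill,
        "cell_contact_width_um": 2.0 * r_cell,
        "substrate_contact_radius_um": contact.a,
        "substrate_indentation_um": contact.delta,
        "p0_substrate_kPa": contact.p0,
        # load-transparent assumption: after piercing the substrate carries all
        "load_fraction_substrate": 1.0,
        "load_fraction_monolayer": 0.0,
    }


def implied_h_crit(width_um: float, probe: SphereProbe,
                  delta_um: float = 0.0) -> float:
    """Invert the kill-width formula for h_crit [um].

    With width = 2 sqrt(2R (h_crit + delta)), a measured width implies
    h_crit = (width/2)^2 / (2R) - delta (delta = 0 for a rigid substrate).
    """
    if width_um < 0:
        raise ContactError("width cannot be negative")
    r_um = probe.R * 1e3
    return (width_um / 2.0) ** 2 / (2.0 * r_um) - delta_um


def pressure_sweep(
    forces_mn: Sequence[float],
    pairings: Sequence[tuple[str, SphereProbe, Material, Material]],
) -> pd.DataFrame:
    """Maximum Hertz pressure for each (force, probe/substrate pairing).

    ``pairings`` holds (label, probe, probe_material, substrate) tuples.
    The resulting table is suitable for plotting damage against p0.
    """
    if not list(forces_mn) or not list(pairings):
        raise ContactError("forces and pairings must be non-empty")
    rows = []
    for label, probe, probe_mat, substrate in pairings:
        e_star = effective_modulus(probe_mat, substrate)
        for f in forces_mn:
            c = hertz_contact(float(f), probe, e_star)
            rows.append(
                {
                    "pairing": label,
                    "f_mN": float(f),
                    "e_star_kPa": e_star,
                    "a_um": c.a,
                    "delta_um": c.delta,
                    "p0_kPa": c.p0,
                }
            )
    return pd.DataFrame(rows)
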