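"""Proton stopping power, slab transport, and WET/rWET validation metrics.

The mass stopping power is the Bethe formula with Bragg additivity over the
elemental constituents (no shell or density-effect corrections by default —
negligible for therapeutic proton energies at the accuracy targeted here).

Slab transport tracks the residual *water-equivalent* range through a
material slab, ``dR/dz = -RSP(E)``, where RSP is the relative (to water)
linear stopping power and the instantaneous energy is recovered from the
residual range through the beam model's range calibration.  Formulating the
transport in range space makes water transport exact by construction
(closure: rWET of water against itself is 1.000 for any thickness).

The relative water-equivalent thickness of a sample of physical thickness
``t`` measured with a beam of range ``R80_w`` in water is

    rWET = (R80_w - R80_m) / t

with ``R80_m`` the range in water behind the slab; the per-material
validation statistic is the percent difference of simulated versus
reference rWET.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam import BeamModel, energy_to_range
from .exceptions import AnalysisError, DomainError
from .materials import ELEMENTS, WATER, Material

__all__ = [
    "RwetResult",
    "mass_stopping_power",
    "relative_stopping_power",
    "slab_transport",
    "slab_wet",
    "rwet_metrics",
]

_K = 0.307075  # MeV cm^2 / mol
_ME_C2 = 0.51099895  # MeV
_MP_C2 = 938.27209  # MeV


@dataclass(frozen=True)
class RwetResult:
    """Relative water-equivalent thickness of one sample."""

    rwet: float
    delta_pct: float | None
    r80_water: float
    r80_material: float
    thickness: float


def mass_stopping_power(material: Material, energy: float) -> float:
    """Proton mass stopping power (MeV cm^2 / g), Bethe with Bragg additivity.

    Valid for 1–300 MeV protons; no shell or density-effect corrections.
    """
    e = float(energy)
    if not (1.0 <= e <= 300.0):
        raise DomainError(f"energy {e} MeV outside supported range [1, 300]")
    gamma = 1.0 + e / _MP_C2
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    me_over_m = _ME_C2 / _MP_C2
    wmax = (
        2.0 * _ME_C2 * beta2 * gamma * gamma
        / (1.0 + 2.0 * gamma * me_over_m + me_over_m * me_over_m)
    )
    i_mev = material.i_value * 1e-6
    arg = 2.0 * _ME_C2 * beta2 * gamma * gamma * wmax / (i_mev * i_mev)
    return _K * material.z_over_a / beta2 * (0.5 * np.log(arg) - beta2)


def relative_stopping_power(material: Material, density: float, energy: float) -> float:
    """Linear stopping power relative to water at unit density."""
    return (
        mass_stopping_power(material, energy) * density
        / (mass_stopping_power(WATER, energy) * 1.0)
    )


def _residual_energy(residual_range: float, model: BeamModel) -> float:
    """Energy from residual water range by the (extrapolated) power law."""
    return (residual_range / model.range_coefficient) ** (1.0 / model.range_exponent)


def slab_transport(
    material: Material,
    density: float,
    thickness: float,
    energy: float,
    model: BeamModel,
    n_steps: int = 200,
) -> float:
    """R80 in water (mm) downstream of a material slab of given thickness.

    Integrates ``dR/dz = -RSP(E(z))`` (RK4) through the slab, with E(z)
    recovered from the residual water range via the model's range
    calibration, then returns the residual range — the depth at which the
    distal 80% level lands in the water phantom behind the slab.

    Raises
    ------
    AnalysisError
        If the beam stops inside the slab; the message reports the residual
        range at the point of failure.
    """
    if thickness <= 0:
        raise DomainError("slab thickness must be > 0")
    if density <= 0:
        raise DomainError("density must be > 0")
    r = energy_to_range(energy, model)
    dz = thickness / n_steps

    def rsp(residual: float) -> float:
        e = _residual_energy(residual, model)
        e = min(max(e, 1.0), 300.0)
        return relative_stopping_power(material, density, e)

    floor = 0.5  # mm residual water range below which the beam is "stopped"
    for _ in range(n_steps):
        if r <= floor:
            raise AnalysisError(
                f"beam stopped inside the slab (residual water range {r:.2f} mm)"
            )
        k1 = rsp(r)
        k2 = rsp(max(r - 0.5 * dz * k1, floor))
        k3 = rsp(max(r - 0.5 * dz * k2, floor))
        k4 = rsp(max(r - dz * k3, floor))
        r -= dz / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if r <= floor:
        raise AnalysisError(
            f"beam stopped inside the slab (residual water range {r:.2f} mm)"
        )
    return float(r)


def slab_wet(
    material: Material,
    density: float,
    thickness: float,
    energy: float,
    model: BeamModel,
) -> float:
    """Water-equivalent thickness (mm) of a slab at a given beam energy."""
    r0 = energy_to_range(energy, model)
    return r0 - slab_transport(material, density, thickness, energy, model)


def rwet_metrics(
    r80_water: float,
    r80_material: float,
    t: float,
    rwet_reference: float | None = None,
) -> RwetResult:
    """Relative WET of a sample and, optionally, its percent deviation from
    a reference (e.g. measured) rWET."""
    if t <= 0:
        raise DomainError("sample thickness must be > 0")
    rwet = (r80_water - r80_material) / t
    delta = None
    if rwet_reference is not None:
        if rwet_reference == 0:
            raise DomainError("reference rWET must be nonzero")
        delta = (rwet - rwet_reference) / rwet_reference * 100.0
    return RwetResult(
        rwet=float(rwet),
        delta_pct=None if delta is None else float(delta),
        r80_water=float(r80_water),
        r80_material=float(r80_material),
        thickness=float(t),
    )
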