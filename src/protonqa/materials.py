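"""Materials, elemental data, and HU-to-tissue conversion tables.

Elemental Z, A, and mean excitation energies follow the standard ICRU-49
style tabulation.  The HU→composition table is a stoichiometric
(Schneider-style) 24-bin segmentation: air, lung, an adipose→muscle
interpolation band for soft tissue, a marrow→cortical-bone interpolation
band for the skeleton, and a single dense-bone bin for everything above
1500 HU.  A second, TPS-style convention resolves the top of the scanner
range with bone up to 2432 HU, aluminium to 2832 HU and iron above —
selecting between the two conventions reproduces the implant-discrepancy
mechanism between an independent dose engine and a TPS.

HU→mass-density calibration curves (per CT protocol) are piecewise-linear
control-point tables; representative defaults for a few protocols are
shipped, and any curve can be loaded from two-column CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELEMENTS",
    "Material",
    "HUCurve",
    "hu_to_density",
    "hu_to_material",
    "schneider_bins",
    "WATER",
    "AIR",
    "LUNG",
    "ADIPOSE",
    "MUSCLE",
    "RED_MARROW",
    "CORTICAL_BONE",
    "DENSE_BONE",
    "IRON",
    "ALUMINUM",
    "DEFAULT_HU_CURVES",
    "SCANNER_HU_MIN",
    "SCANNER_HU_MAX",
]

SCANNER_HU_MIN = -1024
SCANNER_HU_MAX = 3071

# symbol -> (Z, A [g/mol], I [eV])
ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "Al": (13, 26.982, 166.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "Ar": (18, 39.948, 188.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
    "Ti": (22, 47.867, 233.0),
    "Fe": (26, 55.845, 286.0),
}


@dataclass(frozen=True)
class Material:
    """Elemental composition by mass fraction, with mean excitation energy.

    If ``mean_excitation_ev`` is not given it is derived from the elemental
    I-values by the Bragg-additivity log-average
    ``ln I = sum(w Z/A ln I_el) / sum(w Z/A)``.
    """

    name: str
    composition: dict  # element symbol -> mass fraction
    default_density: float  # g/cm^3
    mean_excitation_ev: float | None = None

    def __post_init__(self):
        comp = {k: float(v) for k, v in self.composition.items() if v > 0}
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")
        comp = {k: v / total for k, v in comp.items()}  # exact renormalization
        for el in comp:
            if el not in ELEMENTS:
                raise ValueError(f"{self.name}: unknown element {el}")
        object.__setattr__(self, "composition", comp)
        if self.default_density <= 0:
            raise ValueError("density must be > 0")

    @property
    def z_over_a(self) -> float:
        """Mass-fraction-weighted <Z/A> (mol/g units absorbed into K)."""
        return sum(w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in self.composition.items())

    @property
    def i_value(self) -> float:
        """Mean excitation energy (eV)."""
        if self.mean_excitation_ev is not None:
            return float(self.mean_excitation_ev)
        num = sum(
            w * ELEMENTS[el][0] / ELEMENTS[el][1] * math.log(ELEMENTS[el][2])
            for el, w in self.composition.items()
        )
        return math.exp(num / self.z_over_a)


def _pct(**kwargs) -> dict:
    return {k: v / 100.0 for k, v in kwargs.items()}


WATER = Material("water", _pct(H=11.19, O=88.81), 1.000, mean_excitation_ev=75.0)
AIR = Material("air", _pct(C=0.012, N=75.52, O=23.18, Ar=1.29), 0.0012)
LUNG = Material("lung", _pct(H=10.3, C=10.5, N=3.1, O=74.9, Na=0.2, P=0.2, S=0.3, Cl=0.3, K=0.2), 0.26)
ADIPOSE = Material("adipose", _pct(H=11.4, C=59.8, N=0.7, O=27.8, Na=0.1, S=0.1, Cl=0.1), 0.95)
MUSCLE = Material("muscle", _pct(H=10.2, C=14.3, N=3.4, O=71.0, Na=0.1, P=0.2, S=0.3, Cl=0.1, K=0.4), 1.05)
RED_MARROW = Material("red_marrow", _pct(H=10.5, C=41.4, N=3.4, O=43.9, P=0.1, S=0.2, Cl=0.2, K=0.2, Fe=0.1), 1.03)
CORTICAL_BONE = Material(
    "cortical_bone",
    _pct(H=3.4, C=15.5, N=4.2, O=43.5, Na=0.1, Mg=0.2, P=10.3, S=0.3, Ca=22.5),
    1.92,
)
# the single composition assigned to every voxel above 1500 HU
DENSE_BONE = Material("dense_bone", CORTICAL_BONE.composition, 1.92)
IRON = Material("iron", {"Fe": 1.0}, 7.874)
ALUMINUM = Material("aluminum", {"Al": 1.0}, 2.699)


def _interpolate_material(name: str, a: Material, b: Material, frac: float, density: float) -> Material:
    comp: dict[str, float] = {}
    for el in set(a.composition) | set(b.composition):
        w = (1 - frac) * a.composition.get(el, 0.0) + frac * b.composition.get(el, 0.0)
        if w > 0:
            comp[el] = w
    return Material(name, comp, density)


def _build_schneider_bins() -> list[tuple[int, int, Material]]:
    """24 half-open HU bins [lo, hi) covering the scanner range."""
    bins: list[tuple[int, int, Material]] = [
        (SCANNER_HU_MIN, -950, AIR),
        (-950, -500, Material("lung_inhale", LUNG.composition, 0.26)),
        (-500, -120, Material("lung_exhale", LUNG.composition, 0.50)),
    ]
    # soft tissue: adipose (-120) -> muscle (+120), six 40-HU bins
    soft_edges = np.arange(-120, 121, 40)
    for i, (lo, hi) in enumerate(zip(soft_edges[:-1], soft_edges[1:])):
        frac = ((lo + hi) / 2.0 + 120.0) / 240.0
        dens = 0.95 + frac * (1.05 - 0.95)
        bins.append((int(lo), int(hi), _interpolate_material(f"soft_tissue_{i+1}", ADIPOSE, MUSCLE, frac, dens)))
    # skeletal: marrow (120) -> cortical bone (1500), 100-HU steps
    bone_edges = [120, 200] + list(range(300, 1501, 100))
    for i, (lo, hi) in enumerate(zip(bone_edges[:-1], bone_edges[1:])):
        frac = ((lo + hi) / 2.0 - 120.0) / (1500.0 - 120.0)
        dens = 1.03 + frac * (1.92 - 1.03)
        bins.append((int(lo), int(hi), _interpolate_material(f"skeletal_{i+1}", RED_MARROW, CORTICAL_BONE, frac, dens)))
    bins.append((1500, SCANNER_HU_MAX + 1, DENSE_BONE))
    assert len(bins) == 24
    return bins


_SCHNEIDER_BINS = _build_schneider_bins()


def schneider_bins() -> list[tuple[int, int, Material]]:
    """The embedded 24-bin HU→composition table (half-open [lo, hi) bins)."""
    return list(_SCHNEIDER_BINS)


def hu_to_material(hu: float, convention: str = "schneider") -> Material:
    """Material composition for a HU value.

    ``convention="schneider"`` (default, as used by the independent dose
    engine): every voxel above 1500 HU maps to the dense-bone composition.
    ``convention="tps"``: bone compositions continue to 2432 HU, aluminium
    for 2433–2832 HU, iron above 2833 HU.
    """
    hu = float(np.clip(hu, SCANNER_HU_MIN, SCANNER_HU_MAX))
    if convention == "tps":
        if hu >= 2833:
            return IRON
        if hu >= 2433:
            return ALUMINUM
        if hu >= 1500:
            return CORTICAL_BONE
    elif convention != "schneider":
        raise ValueError("convention must be 'schneider' or 'tps'")
    for lo, hi, mat in _SCHNEIDER_BINS:
        if lo <= hu < hi:
            return mat
    return _SCHNEIDER_BINS[-1][2]


@dataclass(frozen=True)
class HUCurve:
    """HU → mass density calibration curve for one CT protocol."""

    protocol_name: str
    control_points: tuple  # ((HU, g/cm^3), ...)

    def __post_init__(self):
        pts = tuple((float(h), float(d)) for h, d in self.control_points)
        if len(pts) < 2:
            raise ValueError("need at least two control points")
        hus = np.array([p[0] for p in pts])
        dens = np.array([p[1] for p in pts])
        if not np.all(np.diff(hus) > 0):
            raise ValueError("HU control points must be strictly increasing")
        if not np.all(dens > 0):
            raise ValueError("densities must be > 0")
        object.__setattr__(self, "control_points", pts)

    @property
    def hu(self) -> np.ndarray:
        return np.array([p[0] for p in self.control_points])

    @property
    def density(self) -> np.ndarray:
        return np.array([p[1] for p in self.control_points])

    @classmethod
    def from_csv(cls, path: str, protocol_name: str = "custom") -> "HUCurve":
        arr = np.loadtxt(path, delimiter=",")
        return cls(protocol_name, tuple(map(tuple, arr)))

    def to_csv(self, path: str) -> None:
        np.savetxt(path, np.array(self.control_points), delimiter=",", header="HU,density_g_cm3")


def hu_to_density(hu, curve: HUCurve):
    """Piecewise-linear density lookup, clamped at the curve ends."""
    return np.interp(hu, curve.hu, curve.density)


_BASE_POINTS = (
    (-1024.0, 0.00121),
    (-950.0, 0.1),
    (-500.0, 0.50),
    (-120.0, 0.93),
    (0.0, 1.000),
    (120.0, 1.075),
    (1000.0, 1.59),
    (1600.0, 1.96),
    (3071.0, 2.90),
)

# Representative per-protocol curves (control points differ slightly in the
# bone region, as scanner kVp/filtration does between protocols).
DEFAULT_HU_CURVES: dict[str, HUCurve] = {
    "adult head": HUCurve("adult head", _BASE_POINTS),
    "adult h&n": HUCurve("adult h&n", _BASE_POINTS),
    "adult abdomen": HUCurve(
        "adult abdomen",
        tuple((h, d * (1.01 if h >= 1000 else 1.0)) for h, d in _BASE_POINTS),
    ),
    "pediatric head": HUCurve(
        "pediatric head",
        tuple((h, d * (0.99 if h >= 1000 else 1.0)) for h, d in _BASE_POINTS),
    ),
}
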