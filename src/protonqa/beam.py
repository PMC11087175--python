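"""Analytical pencil-beam-scanning dose generator with error injection.

This module emulates, at desk scale, the data a treatment planning system,
an independent Monte Carlo dose engine, or a water-phantom measurement would
supply during commissioning of a scanned proton beam line:

* pristine Bragg curves per clinical energy (Bragg–Kleeman power-law depth
  dose convolved with a Gaussian range-straggling kernel),
* Gaussian spots whose lateral position and size follow a virtual-source
  geometry (per-axis VSAD, divergence growing the spot with air gap),
* spread-out Bragg peak (SOBP) box fields with layer weights solved by
  non-negative least squares,
* controlled perturbations (range shift, output scale, spot-size error,
  position offset, voxel noise) for sensitivity studies.

The accelerator constants are those of a synchrotron-based proton facility:
255 clinical energies from 62.4 to 252.7 MeV spanning R80 ranges in water of
30–380 mm, a 35 mm water-equivalent range shifter, and non-isocentric
delivery described by isocenter-to-surface distances (ISD) of 0–58 cm.
All generated doses are deterministic given (inputs, seed).
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import nnls

from .exceptions import ConfigurationError, DomainError
from .grids import DoseGrid3D, Profile1D

__all__ = [
    "BeamModel",
    "Layer",
    "PlanSpec",
    "GridSpec",
    "Perturbation",
    "KEY_ENERGIES",
    "CALIBRATION_ENERGIES",
    "MAJOR_ENERGIES",
    "RS_VERIFICATION_ENERGIES",
    "energy_to_range",
    "range_to_energy",
    "pristine_depth_dose",
    "generate_spot_field",
    "compute_plan_dose",
    "plan_axis_dose",
    "generate_sobp_plan",
    "apply_perturbation",
]

# Commissioning energy subsets (MeV), from the facility's energy classification.
KEY_ENERGIES = (62.4, 97.4, 148.2, 198.0, 252.7)
CALIBRATION_ENERGIES = (62.4, 81.3, 97.4, 124.7, 148.2, 179.2, 198.0, 224.2, 252.7)
MAJOR_ENERGIES = (
    62.4, 72.4, 81.3, 97.4, 111.6, 124.7, 136.8, 148.2, 159.0, 169.3,
    179.2, 188.7, 198.0, 207.0, 215.7, 224.2, 232.6, 240.8, 248.8, 252.7,
)
RS_VERIFICATION_ENERGIES = (97.4, 124.7, 148.2, 198.0)

_PERTURBATION_KINDS = (
    "range_shift_mm",
    "output_scale",
    "spot_sigma_scale",
    "position_offset_mm",
    "noise_pct",
)


@dataclass(frozen=True)
class BeamModel:
    """Beam-line model: energy-range calibration, spot optics, nozzle geometry.

    The energy→range calibration is a power law ``R80 = alpha * E**p`` with
    (alpha, p) fixed by the clinical endpoints: 62.4 MeV → 30 mm and
    252.7 MeV → 380 mm in water.

    Notes
    -----
    ``nozzle_exit_to_isocenter`` defaults to 648 mm: the nominal nozzle
    window to isocenter distance is specified as 65 cm, but the air gap at
    ISD0 is taken as 64.8 cm and the air-gap rule is linear,
    ``g = nozzle_exit_to_isocenter - 10*ISD_cm + depth``.
    """

    energy_min: float = 62.4          # MeV
    energy_max: float = 252.7         # MeV
    range_at_min: float = 30.0        # mm (R80 in water)
    range_at_max: float = 380.0       # mm
    n_energies: int = 255
    straggling_fraction: float = 0.012   # sigma_R as fraction of R80
    spot_sigma0_low: float = 6.0      # mm at nozzle exit, at energy_min
    spot_sigma0_high: float = 2.5     # mm at nozzle exit, at energy_max
    divergence_sigma_theta: float = 0.003  # rad
    vsad_x: float = 2000.0            # mm
    vsad_y: float = 1800.0            # mm (scanning magnets at different distances)
    nozzle_exit_to_isocenter: float = 648.0  # mm
    rs_wet: float = 35.0              # mm water-equivalent thickness
    rs_position: float = 500.0        # mm upstream of isocenter (metadata)

    def __post_init__(self):
        if not (self.energy_min < self.energy_max):
            raise ConfigurationError("energy_min must be < energy_max")
        if not (0 < self.range_at_min < self.range_at_max):
            raise ConfigurationError("ranges must be positive and increasing")
        if self.rs_wet <= 0:
            raise ConfigurationError("rs_wet must be > 0")
        if min(self.vsad_x, self.vsad_y) <= self.nozzle_exit_to_isocenter:
            raise ConfigurationError("VSAD must exceed the nozzle-to-isocenter distance")

    @property
    def range_exponent(self) -> float:
        return math.log(self.range_at_max / self.range_at_min) / math.log(
            self.energy_max / self.energy_min
        )

    @property
    def range_coefficient(self) -> float:
        """alpha in R = alpha * E**p (mm / MeV**p)."""
        return self.range_at_min / self.energy_min ** self.range_exponent

    @property
    def energy_list(self) -> np.ndarray:
        """The full clinical energy list (MeV), evenly spaced."""
        return np.linspace(self.energy_min, self.energy_max, self.n_energies)

    def spot_sigma0(self, energy: float) -> float:
        """Spot sigma (mm) at the nozzle exit, linear in energy."""
        f = (energy - self.energy_min) / (self.energy_max - self.energy_min)
        return self.spot_sigma0_low + f * (self.spot_sigma0_high - self.spot_sigma0_low)

    def air_gap(self, isd_cm: float, depth_mm: float = 0.0) -> float:
        """Distance (mm) from the nozzle exit window to a plane at ``depth_mm``
        inside a phantom whose surface sits at ISD ``isd_cm``."""
        return self.nozzle_exit_to_isocenter - 10.0 * isd_cm + depth_mm

    def spot_sigma_at(self, energy: float, isd_cm: float, depth_mm: float = 0.0) -> float:
        g = self.air_gap(isd_cm, depth_mm)
        s0 = self.spot_sigma0(energy)
        return math.sqrt(s0 * s0 + (self.divergence_sigma_theta * g) ** 2)


def energy_to_range(energy: float, model: BeamModel) -> float:
    """R80 in water (mm) for a clinical energy (MeV), power-law calibration."""
    e = float(energy)
    if not (model.energy_min - 1e-9 <= e <= model.energy_max + 1e-9):
        raise DomainError(
            f"energy {e} MeV outside clinical range "
            f"[{model.energy_min}, {model.energy_max}]"
        )
    return model.range_coefficient * e ** model.range_exponent


def range_to_energy(r80: float, model: BeamModel) -> float:
    """Inverse of :func:`energy_to_range`."""
    r = float(r80)
    if not (model.range_at_min - 1e-9 <= r <= model.range_at_max + 1e-9):
        raise DomainError(
            f"range {r} mm outside achievable span "
            f"[{model.range_at_min}, {model.range_at_max}]"
        )
    return (r / model.range_coefficient) ** (1.0 / model.range_exponent)


# ---------------------------------------------------------------------------
# Pristine depth dose
# ---------------------------------------------------------------------------

_FINE_DZ = 0.05  # mm, internal sampling of the analytic curve


@functools.lru_cache(maxsize=512)
def _pristine_fine(model: BeamModel, r80: float, sigma_r: float):
    """Peak-normalized depth-dose on a fine internal grid, calibrated so the
    distal 80% crossing sits exactly at ``r80``.

    The raw shape is the Bragg–Kleeman power-law stopping curve
    ``D(z) ~ (R0 - z)**(1/p - 1)`` (cell-averaged analytically across the
    integrable singularity at R0) convolved with a Gaussian range-straggling
    kernel of width ``sigma_r``.
    """
    p = model.range_exponent
    a = 1.0 / p - 1.0  # BK exponent, in (-1, 0)
    r0 = r80
    zmax = r0 + 6.0 * sigma_r + 8.0
    z_edges = np.arange(0.0, zmax + _FINE_DZ, _FINE_DZ)
    # cell-averaged (R0 - z)^a over [z_i, z_{i+1}) for z < R0, 0 beyond
    rem = np.clip(r0 - z_edges, 0.0, None)
    anti = rem ** (a + 1.0) / (a + 1.0)
    raw = (anti[:-1] - anti[1:]) / _FINE_DZ
    z = 0.5 * (z_edges[:-1] + z_edges[1:])
    smooth = gaussian_filter1d(raw, sigma=sigma_r / _FINE_DZ, mode="nearest")
    smooth /= smooth.max()
    # locate the distal 80% crossing by linear interpolation on the fine grid
    peak = int(np.argmax(smooth))
    distal = smooth[peak:]
    below = np.nonzero(distal < 0.8)[0]
    i = below[0]
    z1, z2 = z[peak + i - 1], z[peak + i]
    v1, v2 = distal[i - 1], distal[i]
    r80_found = z1 + (0.8 - v1) / (v2 - v1) * (z2 - z1)
    shift = r80_found - r80  # calibration offset applied at evaluation time
    return z, smooth, shift


def pristine_depth_dose(
    energy: float,
    depths,
    model: BeamModel,
    rs_inserted: bool = False,
    range_shift_mm: float = 0.0,
) -> Profile1D:
    """Pristine (single-energy) Bragg curve sampled at ``depths`` (mm).

    The distal R80 equals ``energy_to_range(energy)`` minus the range-shifter
    WET when ``rs_inserted``, plus any injected ``range_shift_mm``.  Values
    are peak-normalized.  Straggling width is ``straggling_fraction`` times
    the unshifted range (straggling accumulates over the full energy loss,
    range shifter included).
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size >= 2 and not np.all(np.diff(depths) > 0):
        raise DomainError("depths must be strictly increasing")
    r_nominal = energy_to_range(energy, model)
    r_eff = r_nominal - (model.rs_wet if rs_inserted else 0.0) + range_shift_mm
    sigma_r = model.straggling_fraction * r_nominal
    if r_eff < 4.0 * sigma_r:
        raise ConfigurationError(
            f"effective range {r_eff:.1f} mm too shallow for energy {energy} MeV"
        )
    z, vals, shift = _pristine_fine(model, round(r_eff, 9), round(sigma_r, 9))
    out = np.interp(depths + shift, z, vals, left=vals[0], right=0.0)
    return Profile1D(depths, out, kind="depth")


# ---------------------------------------------------------------------------
# Plans and grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Layer:
    """One energy layer: spot positions are nominal (at isocenter), mm; weights MU."""

    energy: float
    spots: np.ndarray  # (n, 3): x_mm, y_mm, weight_MU

    def __post_init__(self):
        spots = np.atleast_2d(np.asarray(self.spots, dtype=float))
        if spots.shape[1] != 3:
            raise ConfigurationError("spots must be (n, 3): x, y, weight")
        if np.any(spots[:, 2] < 0):
            raise ConfigurationError("spot weights must be >= 0")
        object.__setattr__(self, "spots", spots)


@dataclass(frozen=True)
class PlanSpec:
    """A scanned-beam delivery: energy layers of weighted spots.

    ``isd_cm`` is the isocenter-to-surface distance of the phantom/detector
    (0–58 cm, surface moved upstream toward the nozzle).  The trailing fields
    hold injected-error state (all neutral by default) consumed by the dose
    engine; they are set through :func:`apply_perturbation`.
    """

    layers: tuple
    isd_cm: float = 0.0
    rs_inserted: bool = False
    field_label: str = ""
    range_shift_mm: float = 0.0
    sigma_scale: float = 1.0
    position_offset: tuple = (0.0, 0.0)

    def __post_init__(self):
        layers = tuple(self.layers)
        if not layers:
            raise ConfigurationError("plan must contain at least one layer")
        if not (0.0 <= self.isd_cm <= 58.0):
            raise ConfigurationError("isd_cm must be within [0, 58]")
        if self.sigma_scale <= 0:
            raise ConfigurationError("sigma_scale must be > 0")
        if not any(layer.spots.shape[0] for layer in layers):
            raise ConfigurationError("plan must contain at least one spot")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "position_offset", tuple(self.position_offset))

    def total_mu(self) -> float:
        return float(sum(layer.spots[:, 2].sum() for layer in self.layers))


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the scoring grid: origin/spacing/shape, beam axis = z.

    z is depth below the phantom surface; x, y are lateral, with the beam
    axis at x = y = 0.
    """

    origin: tuple = (-50.0, -50.0, 0.0)
    spacing: tuple = (2.0, 2.0, 1.0)
    shape: tuple = (51, 51, 200)

    def coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


@dataclass(frozen=True)
class Perturbation:
    """A single controlled error: exactly one ``kind`` with a magnitude.

    kinds: ``range_shift_mm`` (mm, distal-positive), ``output_scale``
    (multiplicative), ``spot_sigma_scale`` (multiplicative), ``position_offset_mm``
    (mm, scalar applied to both axes or an (dx, dy) pair), ``noise_pct``
    (zero-mean Gaussian, % of local dose, requires a seed).
    """

    kind: str
    magnitude: object

    def __post_init__(self):
        if self.kind not in _PERTURBATION_KINDS:
            raise ConfigurationError(f"unknown perturbation kind: {self.kind!r}")
        if self.kind == "noise_pct" and float(self.magnitude) < 0:
            raise ConfigurationError("noise_pct must be >= 0")


def _layer_field(
    layer: Layer,
    plan: PlanSpec,
    model: BeamModel,
    grid: GridSpec,
    out: np.ndarray,
) -> None:
    """Accumulate one layer's dose into ``out`` (shape = grid.shape)."""
    spots = layer.spots
    xs = spots[:, 0] + plan.position_offset[0]
    ys = spots[:, 1] + plan.position_offset[1]
    w = spots[:, 2]
    if not w.any():
        return
    x = grid.coords(0)
    y = grid.coords(1)
    z = grid.coords(2)
    curve = pristine_depth_dose(
        layer.energy, z, model,
        rs_inserted=plan.rs_inserted, range_shift_mm=plan.range_shift_mm,
    ).values
    # warn about spots whose projected center leaves the lateral grid
    kx_surf = (model.vsad_x - 10.0 * plan.isd_cm) / model.vsad_x
    ky_surf = (model.vsad_y - 10.0 * plan.isd_cm) / model.vsad_y
    out_of_grid = (
        (xs * kx_surf < x[0]) | (xs * kx_surf > x[-1])
        | (ys * ky_surf < y[0]) | (ys * ky_surf > y[-1])
    )
    if out_of_grid.any():
        warnings.warn(
            f"{int(out_of_grid.sum())} spot(s) project outside the lateral grid; "
            "their contribution is truncated",
            stacklevel=3,
        )
    for iz in range(z.size):
        if curve[iz] <= 0:
            continue
        d = 10.0 * plan.isd_cm - z[iz]  # distance upstream of isocenter
        kx = (model.vsad_x - d) / model.vsad_x
        ky = (model.vsad_y - d) / model.vsad_y
        sig = model.spot_sigma_at(layer.energy, plan.isd_cm, z[iz]) * plan.sigma_scale
        gx = np.exp(-((x[:, None] - kx * xs[None, :]) ** 2) / (2.0 * sig * sig))
        gy = np.exp(-((y[:, None] - ky * ys[None, :]) ** 2) / (2.0 * sig * sig))
        norm = curve[iz] / (2.0 * math.pi * sig * sig)
        out[:, :, iz] += norm * (gx @ (w[:, None] * gy.T))


def generate_spot_field(plan: PlanSpec, model: BeamModel, grid_spec: GridSpec) -> DoseGrid3D:
    """Superpose all spots of a plan onto a 3D grid.

    Each spot contributes (pristine depth dose) x (2D Gaussian).  At a plane
    a distance ``d`` upstream of the isocenter the lateral center of a spot
    with nominal deflection ``x_iso`` is ``x_iso*(VSAD-d)/VSAD`` per axis and
    its sigma is ``sqrt(sigma0^2 + sigma_theta^2*g^2)`` with ``g`` the air
    gap from the nozzle exit.  Superposition is linear in the spot weights.
    """
    out = np.zeros(grid_spec.shape, dtype=float)
    for layer in plan.layers:
        _layer_field(layer, plan, model, grid_spec, out)
    return DoseGrid3D(grid_spec.origin, grid_spec.spacing, out, frame="z")


def compute_plan_dose(plan: PlanSpec, model: BeamModel, grid_spec: GridSpec) -> DoseGrid3D:
    """Deterministic plan dose: sum of the spot fields of every layer."""
    return generate_spot_field(plan, model, grid_spec)


def plan_axis_dose(plan: PlanSpec, model: BeamModel, depths, x: float = 0.0, y: float = 0.0) -> Profile1D:
    """Dose along a line parallel to the beam axis at lateral (x, y), without
    rasterizing a full 3D grid (used for SOBP design and flatness checks)."""
    depths = np.asarray(depths, dtype=float)
    total = np.zeros_like(depths)
    for layer in plan.layers:
        spots = layer.spots
        xs = spots[:, 0] + plan.position_offset[0]
        ys = spots[:, 1] + plan.position_offset[1]
        w = spots[:, 2]
        if not w.any():
            continue
        curve = pristine_depth_dose(
            layer.energy, depths, model,
            rs_inserted=plan.rs_inserted, range_shift_mm=plan.range_shift_mm,
        ).values
        for iz, z in enumerate(depths):
            if curve[iz] <= 0:
                continue
            d = 10.0 * plan.isd_cm - z
            kx = (model.vsad_x - d) / model.vsad_x
            ky = (model.vsad_y - d) / model.vsad_y
            sig = model.spot_sigma_at(layer.energy, plan.isd_cm, z) * plan.sigma_scale
            g = np.exp(
                -((x - kx * xs) ** 2 + (y - ky * ys) ** 2) / (2.0 * sig * sig)
            )
            total[iz] += curve[iz] / (2.0 * math.pi * sig * sig) * float(np.dot(w, g))
    return Profile1D(depths, total, kind="depth")


def generate_sobp_plan(
    box_size,
    center_depth_wed: float,
    target_dose: float,
    model: BeamModel,
    spot_spacing: float = 2.0,
    isd_cm: float = 0.0,
    field_label: str = "sobp-box",
) -> PlanSpec:
    """Design a cubic SOBP field: energy layers + uniform lateral spot grid,
    with layer weights solved by non-negative least squares so the
    central-axis dose is flat at ``target_dose`` across the box depth span.

    Shallow boxes whose proximal edge lies above the minimum achievable
    range automatically get the range shifter inserted.
    """
    box_size = np.asarray(box_size, dtype=float)
    if box_size.shape != (3,) or np.any(box_size <= 0):
        raise ConfigurationError("box_size must be a positive (sx, sy, sz) triple")
    sx, sy, sz = box_size
    proximal = center_depth_wed - sz / 2.0
    distal = center_depth_wed + sz / 2.0
    if proximal < 0:
        raise ConfigurationError("proximal box edge above the phantom surface")
    rs = proximal < model.range_at_min
    wet_offset = model.rs_wet if rs else 0.0
    if distal + wet_offset > model.range_at_max:
        raise ConfigurationError("distal box edge beyond the maximum achievable range")

    sigma_distal = model.straggling_fraction * (distal + wet_offset)
    layer_step = max(1.0, 0.8 * sigma_distal)
    r80s = np.arange(proximal, distal + 1e-9, layer_step)
    if r80s[-1] < distal - 1e-9:
        r80s = np.append(r80s, distal)
    energies = [range_to_energy(r + wet_offset, model) for r in r80s]

    half_x = sx / 2.0
    half_y = sy / 2.0
    gx = np.arange(-half_x, half_x + 1e-9, spot_spacing)
    gy = np.arange(-half_y, half_y + 1e-9, spot_spacing)
    gx -= gx.mean()
    gy -= gy.mean()
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    spot_xy = np.column_stack([xx.ravel(), yy.ravel()])

    # design matrix: central-axis dose per unit spot weight, per layer
    z_samples = np.arange(proximal, distal + 1e-9, 1.0)
    A = np.zeros((z_samples.size, len(energies)))
    for j, e in enumerate(energies):
        layer = Layer(e, np.column_stack([spot_xy, np.ones(len(spot_xy))]))
        single = PlanSpec((layer,), isd_cm=isd_cm, rs_inserted=rs)
        A[:, j] = plan_axis_dose(single, model, z_samples).values
    weights, _ = nnls(A, np.full(z_samples.size, float(target_dose)))

    layers = tuple(
        Layer(e, np.column_stack([spot_xy, np.full(len(spot_xy), wgt)]))
        for e, wgt in zip(energies, weights)
    )
    return PlanSpec(layers, isd_cm=isd_cm, rs_inserted=rs, field_label=field_label)


def apply_perturbation(obj, perturbation: Perturbation, model: BeamModel | None = None, seed: int | None = None):
    """Inject a controlled error into a plan or a dose grid (returns same type).

    Plans: ``range_shift_mm``, ``output_scale``, ``spot_sigma_scale``,
    ``position_offset_mm``.  Grids: ``range_shift_mm`` (translation along the
    depth axis), ``output_scale``, ``noise_pct`` (seeded).
    """
    kind = perturbation.kind
    m = perturbation.magnitude
    if isinstance(obj, PlanSpec):
        if kind == "range_shift_mm":
            return replace(obj, range_shift_mm=obj.range_shift_mm + float(m))
        if kind == "output_scale":
            scale = float(m)
            layers = tuple(
                Layer(lyr.energy, np.column_stack([lyr.spots[:, :2], lyr.spots[:, 2] * scale]))
                for lyr in obj.layers
            )
            return replace(obj, layers=layers)
        if kind == "spot_sigma_scale":
            return replace(obj, sigma_scale=obj.sigma_scale * float(m))
        if kind == "position_offset_mm":
            off = (float(m), float(m)) if np.isscalar(m) else (float(m[0]), float(m[1]))
            return replace(
                obj,
                position_offset=(obj.position_offset[0] + off[0], obj.position_offset[1] + off[1]),
            )
        raise ConfigurationError(f"perturbation {kind!r} not applicable to a plan")
    if isinstance(obj, DoseGrid3D):
        if kind == "output_scale":
            return obj.with_values(obj.values * float(m))
        if kind == "noise_pct":
            if seed is None:
                raise ConfigurationError("noise_pct requires an explicit seed")
            rng = np.random.default_rng(seed)
            noisy = obj.values * (1.0 + float(m) / 100.0 * rng.standard_normal(obj.values.shape))
            return obj.with_values(np.clip(noisy, 0.0, None))
        if kind == "range_shift_mm":
            shift = float(m)
            if shift == 0.0:
                return obj
            a = obj.depth_axis
            coords = obj.axis_coords(a)
            moved = np.moveaxis(obj.values, a, -1)
            shifted = np.empty_like(moved)
            flat = moved.reshape(-1, coords.size)
            sflat = shifted.reshape(-1, coords.size)
            for i in range(flat.shape[0]):
                sflat[i] = np.interp(coords - shift, coords, flat[i], left=flat[i][0], right=0.0)
            return obj.with_values(np.moveaxis(shifted, -1, a))
        raise ConfigurationError(f"perturbation {kind!r} not applicable to a dose grid")
    raise ConfigurationError(f"cannot perturb object of type {type(obj).__name__}")
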