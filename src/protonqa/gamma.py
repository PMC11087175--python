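"""3D gamma-index analysis with clinical pass/warning/fail classification.

The gamma index compares an evaluated dose distribution against a reference
on a combined dose-difference / distance-to-agreement (DTA) metric: for each
reference voxel above the low-dose threshold,

    gamma(r_ref) = min_r sqrt( |r - r_ref|^2 / DTA^2
                               + (D_eval(r) - D_ref(r_ref))^2 / (dd * Dmax)^2 )

with the evaluated dose trilinearly interpolated, a *global* dose
normalization to the reference maximum, and the spatial search restricted to
a sphere of ``search_cap * DTA`` sampled on a subvoxel lattice of step
``DTA/10``.  Voxels whose minimum exceeds the cap are reported as capped and
count as failing.  The gamma pass rate (GPR) is the percentage of evaluated
voxels with gamma <= 1; clinical classification compares the GPR with
warning/fail levels (defaults 95% / 90%).

Per-protocol clinical criteria: 2%/2 mm for head, head-and-neck, and
pediatric CT protocols; 3%/3 mm for the adult abdomen protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import AnalysisError, ConfigurationError
from .grids import DoseGrid3D

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "RegistrationError",
    "criteria_for_protocol",
    "dose_difference_map",
    "gamma_map",
    "gamma_pass_rate",
    "classify_result",
]

_PASS_EPS = 1e-9  # floating-point guard on the gamma <= 1 comparison


class RegistrationError(ValueError):
    """Grids are not co-registered (geometry mismatch)."""


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria and clinical decision levels."""

    dose_diff_pct: float = 2.0       # % of the global normalization dose
    dta_mm: float = 2.0
    low_dose_threshold_pct: float = 10.0  # % of reference max, voxels below are ignored
    normalization: str = "global-to-reference-max"
    warning_level_pct: float = 95.0
    fail_level_pct: float = 90.0
    protocol: str = "default"
    search_cap: float = 2.0          # search radius in units of DTA; gamma capped here
    search_steps_per_dta: int = 10   # subvoxel lattice resolution

    def __post_init__(self):
        if min(self.dose_diff_pct, self.dta_mm, self.low_dose_threshold_pct) <= 0:
            raise ConfigurationError("criteria must be positive")
        if not (self.fail_level_pct <= self.warning_level_pct <= 100.0):
            raise ConfigurationError("need fail <= warning <= 100")
        if self.normalization != "global-to-reference-max":
            raise ConfigurationError("only global-to-reference-max normalization is supported")


# clinical criteria per CT protocol (warning/fail levels are common to all)
_PROTOCOL_TABLE = {
    "default": (2.0, 2.0),
    "adult head": (2.0, 2.0),
    "adult h&n": (2.0, 2.0),
    "adult abdomen": (3.0, 3.0),
    "pediatric head": (2.0, 2.0),
    "pediatric abdomen": (2.0, 2.0),
    "infant body": (2.0, 2.0),
}


def criteria_for_protocol(protocol: str) -> GammaCriteria:
    """Clinical gamma criteria for a CT protocol label."""
    key = protocol.lower()
    if key not in _PROTOCOL_TABLE:
        raise ConfigurationError(f"unknown CT protocol: {protocol!r}")
    dd, dta = _PROTOCOL_TABLE[key]
    return GammaCriteria(dose_diff_pct=dd, dta_mm=dta, protocol=key)


@dataclass(frozen=True)
class GammaResult:
    """Gamma map plus summary; the map shares the reference geometry and is
    NaN below the low-dose threshold."""

    gamma: np.ndarray
    gpr: float
    n_evaluated: int
    n_capped: int
    criteria: GammaCriteria
    classification: str | None = None


def dose_difference_map(reference: DoseGrid3D, evaluated: DoseGrid3D) -> np.ndarray:
    """Per-voxel dose difference in % of the reference maximum.

    Returned as a plain array on the reference geometry (difference maps are
    signed, unlike dose grids).
    """
    if not reference.same_geometry(evaluated):
        raise RegistrationError("dose grids are not co-registered")
    dmax = float(reference.values.max())
    if dmax <= 0:
        raise AnalysisError("reference grid has no positive dose")
    return (evaluated.values - reference.values) / dmax * 100.0


def _search_lattice(criteria: GammaCriteria):
    """Offsets (sorted by distance) covering the search sphere."""
    n = int(round(criteria.search_cap * criteria.search_steps_per_dta))
    k = np.arange(-n, n + 1, dtype=float)
    # (k * dta) / steps keeps integer multiples of the DTA exact in floating point
    step_coords = (k * criteria.dta_mm) / criteria.search_steps_per_dta
    ox, oy, oz = np.meshgrid(step_coords, step_coords, step_coords, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    dist2 = (offsets**2).sum(axis=1)
    cap_r2 = (criteria.search_cap * criteria.dta_mm) ** 2 * (1 + 1e-12)
    keep = dist2 <= cap_r2
    offsets, dist2 = offsets[keep], dist2[keep]
    order = np.argsort(dist2, kind="stable")
    return offsets[order], dist2[order]


def _gamma_kernel_numpy(ref_pos, ref_dose, ev_values, ev_origin, ev_spacing, offsets, dist2, dta2, dd2):
    from scipy.ndimage import map_coordinates

    best = np.full(ref_pos.shape[0], np.inf)
    shape = np.array(ev_values.shape, dtype=float)
    for j in range(offsets.shape[0]):
        dterm = dist2[j] / dta2
        if dterm >= best.max():
            continue
        idx = (ref_pos + offsets[j] - ev_origin) / ev_spacing
        valid = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
        if not valid.any():
            continue
        ev = map_coordinates(ev_values, idx[valid].T, order=1, mode="nearest")
        g2 = dterm + (ev - ref_dose[valid]) ** 2 / dd2
        b = best[valid]
        best[valid] = np.minimum(b, g2)
    return np.sqrt(best)


try:
    import numba

    @numba.njit(cache=False, fastmath=False)
    def _gamma_kernel_numba(ref_pos, ref_dose, ev_values, ev_origin, ev_spacing, offsets, dist2, dta2, dd2):  # pragma: no cover - exercised via gamma_map
        m = ref_pos.shape[0]
        nx, ny, nz = ev_values.shape
        out = np.empty(m)
        for i in range(m):
            best = np.inf
            for j in range(offsets.shape[0]):
                dterm = dist2[j] / dta2
                if dterm >= best:
                    break  # offsets sorted by distance: no better minimum ahead
                fx = (ref_pos[i, 0] + offsets[j, 0] - ev_origin[0]) / ev_spacing[0]
                fy = (ref_pos[i, 1] + offsets[j, 1] - ev_origin[1]) / ev_spacing[1]
                fz = (ref_pos[i, 2] + offsets[j, 2] - ev_origin[2]) / ev_spacing[2]
                if fx < 0 or fy < 0 or fz < 0 or fx > nx - 1 or fy > ny - 1 or fz > nz - 1:
                    continue
                ix = int(fx)
                iy = int(fy)
                iz = int(fz)
                if ix >= nx - 1:
                    ix = nx - 2 if nx > 1 else 0
                if iy >= ny - 1:
                    iy = ny - 2 if ny > 1 else 0
                if iz >= nz - 1:
                    iz = nz - 2 if nz > 1 else 0
                tx = fx - ix
                ty = fy - iy
                tz = fz - iz
                if nx == 1:
                    tx = 0.0
                if ny == 1:
                    ty = 0.0
                if nz == 1:
                    tz = 0.0
                ix1 = min(ix + 1, nx - 1)
                iy1 = min(iy + 1, ny - 1)
                iz1 = min(iz + 1, nz - 1)
                c00 = ev_values[ix, iy, iz] * (1 - tx) + ev_values[ix1, iy, iz] * tx
                c10 = ev_values[ix, iy1, iz] * (1 - tx) + ev_values[ix1, iy1, iz] * tx
                c01 = ev_values[ix, iy, iz1] * (1 - tx) + ev_values[ix1, iy, iz1] * tx
                c11 = ev_values[ix, iy1, iz1] * (1 - tx) + ev_values[ix1, iy1, iz1] * tx
                ev = (c00 * (1 - ty) + c10 * ty) * (1 - tz) + (c01 * (1 - ty) + c11 * ty) * tz
                dd = ev - ref_dose[i]
                g2 = dterm + dd * dd / dd2
                if g2 < best:
                    best = g2
            out[i] = np.sqrt(best)
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def gamma_map(
    reference: DoseGrid3D,
    evaluated: DoseGrid3D,
    criteria: GammaCriteria = GammaCriteria(),
    engine: str = "auto",
) -> GammaResult:
    """Compute the 3D gamma map of ``evaluated`` against ``reference``.

    The two grids must share a frame of reference but may have different
    geometry (the evaluated grid is interpolated).  Reference voxels below
    the low-dose threshold are excluded from the analysis (NaN in the map).
    """
    ref_v = reference.values
    dmax = float(ref_v.max())
    if dmax <= 0:
        raise AnalysisError("reference grid has no positive dose")
    threshold = criteria.low_dose_threshold_pct / 100.0 * dmax
    mask = ref_v > threshold
    n_eval = int(mask.sum())
    if n_eval == 0:
        raise AnalysisError("no reference voxels above the low-dose threshold")

    idx = np.argwhere(mask)
    ref_pos = reference.origin + idx * reference.spacing
    ref_dose = ref_v[mask]
    offsets, dist2 = _search_lattice(criteria)
    dta2 = criteria.dta_mm**2
    dd2 = (criteria.dose_diff_pct / 100.0 * dmax) ** 2

    use_numba = _HAVE_NUMBA and engine in ("auto", "numba")
    if engine == "numpy":
        use_numba = False
    kernel = _gamma_kernel_numba if use_numba else _gamma_kernel_numpy
    gamma_vals = kernel(
        np.ascontiguousarray(ref_pos, dtype=float),
        np.ascontiguousarray(ref_dose, dtype=float),
        np.ascontiguousarray(evaluated.values, dtype=float),
        np.asarray(evaluated.origin, dtype=float),
        np.asarray(evaluated.spacing, dtype=float),
        np.ascontiguousarray(offsets),
        np.ascontiguousarray(dist2),
        float(dta2),
        float(dd2),
    )

    gmap = np.full(ref_v.shape, np.nan)
    gmap[mask] = gamma_vals
    n_capped = int(np.sum(gamma_vals > criteria.search_cap))
    n_pass = int(np.sum(gamma_vals <= 1.0 + _PASS_EPS))
    gpr = 100.0 * n_pass / n_eval
    return GammaResult(
        gamma=gmap,
        gpr=gpr,
        n_evaluated=n_eval,
        n_capped=n_capped,
        criteria=criteria,
    )


def gamma_pass_rate(result: GammaResult) -> float:
    """GPR (%) recomputed from the gamma map: evaluated voxels with
    gamma <= 1; capped/unresolved voxels count as failing."""
    vals = result.gamma[np.isfinite(result.gamma)]
    if vals.size == 0:
        raise AnalysisError("gamma map holds no evaluated voxels")
    return float(100.0 * np.sum(vals <= 1.0 + _PASS_EPS) / vals.size)


def classify_result(gpr: float, criteria: GammaCriteria) -> str:
    """Map a GPR to {pass, warning, fail} using the clinical levels."""
    if not (0.0 <= gpr <= 100.0):
        raise ValueError("GPR must be within [0, 100]")
    if gpr >= criteria.warning_level_pct:
        return "pass"
    if gpr >= criteria.fail_level_pct:
        return "warning"
    return "fail"


def classify(result: GammaResult) -> GammaResult:
    """Return a copy of ``result`` with the clinical classification filled in."""
    return replace(result, classification=classify_result(result.gpr, result.criteria))
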