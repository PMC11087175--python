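"""1D commissioning metrics: R80, BPW80, distal gradient, reference doses.

R80 is the depth at which the dose falls to 80% of the Bragg-peak maximum on
the distal fall-off — the clinical "range".  BPW80 is the peak width between
the proximal and distal 80% crossings.  Level crossings use linear
interpolation between the bracketing samples (standard commissioning
practice; monotone-safe).

A sampling safeguard flags profiles whose peak is narrower than twice the
sampling step: on such curves the extracted metrics are unreliable
(Nyquist), and the remedy is to re-extract along the finest grid axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AnalysisError, ConfigurationError, DomainError
from .grids import DoseGrid3D, Profile1D, extract_axis_profile

__all__ = [
    "DepthDoseMetrics",
    "integrate_depth_dose",
    "analyze_depth_dose",
    "reference_point_dose",
]


@dataclass(frozen=True)
class DepthDoseMetrics:
    """Extracted Bragg-curve quantities (all depths in mm)."""

    r80: float
    bpw80: float
    distal_gradient_at: tuple  # (depth mm, gradient in % of max per mm)
    peak_depth: float
    sampling_ok: bool
    resolution_used: float
    tie_broken: bool = False  # multiple maxima within 0.1%, most distal used


def integrate_depth_dose(grid: DoseGrid3D) -> Profile1D:
    """Integrated radial profile as a function of depth (IRPD), Gy*mm^2.

    Sums every plane perpendicular to the grid's depth axis times the voxel
    cross-area; for a single pencil beam this is sigma-independent.
    """
    if grid.frame not in ("x", "y", "z"):
        raise ConfigurationError("grid frame does not identify a depth axis")
    return extract_axis_profile(grid, axis=grid.depth_axis, mode="integrated")


def _cross_down(x: np.ndarray, v: np.ndarray, level: float) -> float:
    """First downward crossing of `level`, linear interpolation (v starts >= level)."""
    below = np.nonzero(v < level)[0]
    i = below[0]
    return float(x[i - 1] + (level - v[i - 1]) / (v[i] - v[i - 1]) * (x[i] - x[i - 1]))


def analyze_depth_dose(profile: Profile1D) -> DepthDoseMetrics:
    """Extract R80, BPW80 and the distal gradient from a depth-dose profile.

    Raises
    ------
    AnalysisError
        If the curve is truncated (no distal 80% crossing) or has no
        proximal 80% crossing (entrance plateau above 80%, flagged case).
    """
    z = profile.positions
    v = profile.values
    if z.size < 3:
        raise AnalysisError("profile too short to analyze")
    vmax = float(v.max())
    if vmax <= 0:
        raise AnalysisError("profile has no positive dose")
    rel = v / vmax
    peaks = np.nonzero(rel >= 1.0 - 1e-3)[0]
    tie_broken = peaks.size > 1
    ipeak = int(peaks[-1])  # tie broken to most distal
    peak_depth = float(z[ipeak])

    distal = rel[ipeak:]
    if distal.min() >= 0.8:
        raise AnalysisError("no distal 80% crossing: profile truncated before fall-off")
    r80 = _cross_down(z[ipeak:], distal, 0.8)

    # proximal crossing: scan from the peak backwards (rising edge)
    proximal = rel[: ipeak + 1][::-1]
    if proximal.min() >= 0.8:
        raise AnalysisError(
            "no proximal 80% crossing: entrance plateau above 80% of maximum"
        )
    zp = z[: ipeak + 1][::-1]
    prox80 = _cross_down(zp, proximal, 0.8)
    bpw80 = r80 - prox80

    # distal gradient at R80, central differences, % of max per mm
    grad = np.gradient(rel, z) * 100.0
    g_at = float(np.interp(r80, z, grad))
    resolution = float(np.median(np.diff(z)))
    sampling_ok = bpw80 >= 2.0 * resolution
    return DepthDoseMetrics(
        r80=float(r80),
        bpw80=float(bpw80),
        distal_gradient_at=(float(r80), g_at),
        peak_depth=peak_depth,
        sampling_ok=bool(sampling_ok),
        resolution_used=resolution,
        tie_broken=tie_broken,
    )


def reference_point_dose(
    grid: DoseGrid3D,
    depth: float,
    averaging_diameter: float = 40.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """Mean dose (Gy) over a central-axis disc at a given depth, plus the
    local depth gradient (% of that dose per mm) for uncertainty context.

    Emulates a large-area plane-parallel chamber reading in a scanned
    reference field.  The dose plane is linearly interpolated between the
    bracketing depth slices; the disc average uses a dense Cartesian
    sub-sampling (0.5 mm pitch) with bilinear lateral interpolation.
    """
    from scipy.interpolate import RegularGridInterpolator

    a = grid.depth_axis
    lat = [i for i in range(3) if i != a]
    zc = grid.axis_coords(a)
    if not (zc[0] <= depth <= zc[-1]):
        raise DomainError(f"depth {depth} mm outside grid [{zc[0]}, {zc[-1]}]")
    radius = averaging_diameter / 2.0
    for i, c in zip(lat, center):
        coords = grid.axis_coords(i)
        if c - radius < coords[0] or c + radius > coords[-1]:
            raise DomainError("averaging disc exceeds the lateral grid")

    interp = RegularGridInterpolator(
        tuple(grid.axis_coords(i) for i in range(3)), grid.values, method="linear"
    )
    step = min(0.5, radius / 4.0)
    offsets = np.arange(-radius, radius + step / 2, step)
    uu, vv = np.meshgrid(offsets, offsets, indexing="ij")
    inside = uu**2 + vv**2 <= radius**2

    def disc_mean(at_depth: float) -> float:
        pts = np.zeros((int(inside.sum()), 3))
        pts[:, lat[0]] = center[0] + uu[inside]
        pts[:, lat[1]] = center[1] + vv[inside]
        pts[:, a] = at_depth
        return float(interp(pts).mean())

    dose = disc_mean(depth)
    dz = float(grid.spacing[a])
    d_lo = max(depth - dz, zc[0])
    d_hi = min(depth + dz, zc[-1])
    slope = (disc_mean(d_hi) - disc_mean(d_lo)) / (d_hi - d_lo)
    gradient_pct_per_mm = slope / dose * 100.0 if dose > 0 else float("nan")
    return dose, gradient_pct_per_mm
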