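"""2D spot analysis: centroid, per-axis FWHM, and VSAD recovery.

A scanned pencil beam observed in air at a measurement plane is (close to) a
2D Gaussian.  The centroid is the intensity-weighted mean after background
subtraction; the FWHM per axis comes from the half-maximum crossings of the
through-centroid profile with linear interpolation (robust to non-Gaussian
tails; a Gaussian-fit mode is available).

The virtual source-to-axis distance (VSAD) governs how a spot's lateral
position scales with the measurement plane: a spot with nominal deflection
``x_iso`` observed a distance ``d`` upstream of the isocenter sits at
``x_iso * (VSAD - d) / VSAD``.  :func:`fit_vsad` recovers VSAD per axis by
least squares over observations at several planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import AnalysisError

__all__ = ["SpotMetrics", "VsadFit", "analyze_spot", "fit_vsad"]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class SpotMetrics:
    centroid: tuple  # (x mm, y mm)
    fwhm: tuple      # (x mm, y mm)
    plane_isd: float = 0.0  # cm, bookkeeping


@dataclass(frozen=True)
class VsadFit:
    vsad: float          # mm
    residual_rms: float  # mm
    n_planes: int


def _profile_fwhm(coords: np.ndarray, vals: np.ndarray) -> float:
    """FWHM of a single-peaked 1D profile via half-max crossings."""
    vmax = float(vals.max())
    if vmax <= 0:
        raise AnalysisError("profile has no positive signal")
    half = 0.5 * vmax
    ipeak = int(np.argmax(vals))
    left = vals[: ipeak + 1]
    right = vals[ipeak:]
    if left.min() > half or right.min() > half:
        raise AnalysisError("profile does not fall below half maximum on both sides")
    il = np.nonzero(left < half)[0][-1]
    xl = coords[il] + (half - vals[il]) / (vals[il + 1] - vals[il]) * (
        coords[il + 1] - coords[il]
    )
    ir = ipeak + np.nonzero(right < half)[0][0]
    xr = coords[ir - 1] + (half - vals[ir - 1]) / (vals[ir] - vals[ir - 1]) * (
        coords[ir] - coords[ir - 1]
    )
    return float(xr - xl)


def analyze_spot(
    plane: np.ndarray,
    x_coords: np.ndarray,
    y_coords: np.ndarray,
    plane_isd: float = 0.0,
    method: str = "half-max",
) -> SpotMetrics:
    """Analyze a single-spot 2D dose plane.

    Parameters
    ----------
    plane : (nx, ny) ndarray
        Dose values, indexed [ix, iy].
    x_coords, y_coords : 1D ndarray
        Pixel-center coordinates (mm).
    method : {"half-max", "gauss-fit"}
        FWHM extraction: half-maximum crossings of the through-centroid
        profiles (default) or a least-squares Gaussian fit per axis.

    Raises
    ------
    AnalysisError
        If the spot is clipped by the plane edge (boundary signal >= 1% of
        the maximum after background subtraction).
    """
    plane = np.asarray(plane, dtype=float)
    x_coords = np.asarray(x_coords, dtype=float)
    y_coords = np.asarray(y_coords, dtype=float)
    if plane.shape != (x_coords.size, y_coords.size):
        raise ValueError("plane shape must be (len(x_coords), len(y_coords))")

    sig = plane - plane.min()  # noise-floor robustness
    vmax = float(sig.max())
    if vmax <= 0:
        raise AnalysisError("plane contains no signal")
    boundary = np.concatenate([sig[0, :], sig[-1, :], sig[:, 0], sig[:, -1]])
    if boundary.max() >= 0.01 * vmax:
        raise AnalysisError("spot clipped by the plane edge (>= 1% of max on boundary)")

    total = sig.sum()
    cx = float((sig.sum(axis=1) * x_coords).sum() / total)
    cy = float((sig.sum(axis=0) * y_coords).sum() / total)

    # through-centroid profiles, bilinear along the crossing row/column
    ix = np.clip(np.searchsorted(x_coords, cx) - 1, 0, x_coords.size - 2)
    fx = (cx - x_coords[ix]) / (x_coords[ix + 1] - x_coords[ix])
    prof_y = (1 - fx) * sig[ix, :] + fx * sig[ix + 1, :]
    iy = np.clip(np.searchsorted(y_coords, cy) - 1, 0, y_coords.size - 2)
    fy = (cy - y_coords[iy]) / (y_coords[iy + 1] - y_coords[iy])
    prof_x = (1 - fy) * sig[:, iy] + fy * sig[:, iy + 1]

    if method == "half-max":
        fwhm_x = _profile_fwhm(x_coords, prof_x)
        fwhm_y = _profile_fwhm(y_coords, prof_y)
    elif method == "gauss-fit":
        import warnings

        from scipy.optimize import OptimizeWarning, curve_fit

        def gauss(x, a, mu, s):
            return a * np.exp(-((x - mu) ** 2) / (2 * s * s))

        p0x = [prof_x.max(), cx, 3.0]
        p0y = [prof_y.max(), cy, 3.0]
        with warnings.catch_warnings():
            # a perfect (zero-residual) fit has a singular covariance
            warnings.simplefilter("ignore", OptimizeWarning)
            (ax_, mx_, sx_), _ = curve_fit(gauss, x_coords, prof_x, p0=p0x)
            (ay_, my_, sy_), _ = curve_fit(gauss, y_coords, prof_y, p0=p0y)
        fwhm_x = FWHM_PER_SIGMA * abs(sx_)
        fwhm_y = FWHM_PER_SIGMA * abs(sy_)
    else:
        raise ValueError("method must be 'half-max' or 'gauss-fit'")
    return SpotMetrics(centroid=(cx, cy), fwhm=(float(fwhm_x), float(fwhm_y)), plane_isd=plane_isd)


def fit_vsad(observations) -> VsadFit:
    """Fit the virtual source-to-axis distance from spot positions.

    Parameters
    ----------
    observations : iterable of (d, nominal, measured)
        ``d`` is the plane distance upstream of the isocenter (mm), ``nominal``
        the deflection at isocenter (mm), ``measured`` the observed centroid
        (mm).  The model is ``measured = nominal * (VSAD - d) / VSAD``.

    Notes
    -----
    Linear in ``1/VSAD``: ``nominal - measured = (nominal * d) / VSAD``, so
    the least-squares solution is closed-form.  Scale-equivariant: scaling
    all nominal and measured positions leaves VSAD unchanged.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observations must be (d, nominal, measured) triples")
    d, nominal, measured = obs.T
    if np.unique(d).size < 2:
        raise AnalysisError("need observations at >= 2 planes to fit VSAD")
    a = nominal * d
    if not np.any(nominal != 0):
        raise AnalysisError("all nominal deflections are zero: VSAD indeterminate")
    denom = float(np.dot(a, a))
    if denom == 0.0:
        raise AnalysisError("VSAD indeterminate: no deflected spot off the isocenter plane")
    inv_vsad = float(np.dot(a, nominal - measured)) / denom
    if inv_vsad <= 0:
        raise AnalysisError("fitted VSAD not positive: inconsistent observations")
    vsad = 1.0 / inv_vsad
    resid = measured - nominal * (vsad - d) / vsad
    return VsadFit(vsad=vsad, residual_rms=float(np.sqrt(np.mean(resid**2))), n_planes=int(np.unique(d).size))
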