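"""Commissioning stages and PSQA workflows with tolerance checking.

The validation of an independent dose engine against its baseline proceeds
in three stages of increasing delivery complexity:

* **1D** — single static pencil beams: R80 and BPW80 in water, with and
  without the range shifter;
* **2D** — single scanned layers: spot FWHM and centroid at several
  isocenter-to-surface distances (ISDs), VSAD recovery from spot positions;
* **3D** — modulated deliveries: central-axis point doses in SOBP boxes and
  the mean 3D dose deviation, from which the output (particles-per-MU)
  rescaling factor is determined.

Each stage tabulates candidate-minus-baseline deviations with pass flags
from a :class:`ToleranceTable`.  Patient-specific QA cases are evaluated
either with a 3D gamma analysis (clinical workflow) or with a block of
point-dose comparisons in water (PSQA workflow).

This module also hosts the small closed-form QA conversions used when
choosing clinical simulation parameters: equivalent statistical uncertainty
between scoring-voxel volumes and the rWET→range-shift conversion.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import beam as _beam
from .beam import (
    BeamModel,
    GridSpec,
    KEY_ENERGIES,
    Perturbation,
    PlanSpec,
    RS_VERIFICATION_ENERGIES,
    apply_perturbation,
    compute_plan_dose,
    energy_to_range,
    generate_sobp_plan,
    pristine_depth_dose,
)
from .depthdose import analyze_depth_dose, reference_point_dose
from .exceptions import AnalysisError, ConfigurationError, DomainError
from .gamma import GammaCriteria, classify_result, criteria_for_protocol, gamma_map
from .grids import DoseGrid3D, Profile1D
from .spots import analyze_spot, fit_vsad

__all__ = [
    "ToleranceTable",
    "OutputScaling",
    "CommissioningReport",
    "SyntheticSource",
    "run_beam_model_validation",
    "determine_output_scaling",
    "apply_output_scaling",
    "run_psqa_case",
    "write_report",
    "read_report",
    "scoring_voxel_volume",
    "equivalent_uncertainty_pct",
    "range_shift_from_rwet",
    "default_point_layout",
]


@dataclass(frozen=True)
class ToleranceTable:
    """Stage tolerances (derived from typical clinical agreement envelopes:
    ranges within ±0.3 mm, peak widths within ±0.1 mm, spot sizes within
    ±5% of baseline); all user-overridable."""

    r80_mm: float = 0.3
    bpw80_mm: float = 0.1
    fwhm_pct: float = 5.0
    centroid_mm: float = 0.5
    vsad_pct: float = 2.0
    ref_dose_pct: float = 2.0
    point_dose_pct: float = 2.0

    def __post_init__(self):
        if any(v <= 0 for v in asdict(self).values()):
            raise ConfigurationError("all tolerances must be positive")


@dataclass(frozen=True)
class OutputScaling:
    """Output (particles-per-MU) rescaling determined from 3D dose deviations.

    ``scaling_factor_pct`` is the additive percent correction applied to the
    candidate dose; it equals minus the mean of the input deviations, so a
    candidate overshooting by +1.8% on average receives a −1.8% factor.
    """

    scaling_factor_pct: float
    input_deviations: tuple
    residual_mean_pct: float


@dataclass
class CommissioningReport:
    """Stage tables (pandas DataFrames), gamma summaries, and provenance."""

    tables: dict = field(default_factory=dict)
    gamma_summaries: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    stage_status: dict = field(default_factory=dict)

    def all_pass(self, stage: str | None = None) -> bool:
        names = [stage] if stage else list(self.tables)
        ok = True
        for name in names:
            t = self.tables.get(name)
            if t is None or t.empty:
                continue
            ok &= bool(t["pass"].all())
        return ok


# ---------------------------------------------------------------------------
# Synthetic dose sources
# ---------------------------------------------------------------------------

class SyntheticSource:
    """Provides 1D/2D/3D doses from the analytic beam generator, optionally
    with injected perturbations — stands in for a TPS export, an independent
    dose engine, or a set of measurements."""

    def __init__(
        self,
        model: BeamModel,
        perturbations: tuple = (),
        noise_seed: int | None = None,
        label: str = "synthetic",
    ):
        self.model = model
        self.label = label
        self.noise_seed = noise_seed
        self.range_shift_mm = 0.0
        self.output_scale = 1.0
        self.sigma_scale = 1.0
        self.position_offset = (0.0, 0.0)
        self.noise_pct = 0.0
        for p in perturbations:
            if p.kind == "range_shift_mm":
                self.range_shift_mm += float(p.magnitude)
            elif p.kind == "output_scale":
                self.output_scale *= float(p.magnitude)
            elif p.kind == "spot_sigma_scale":
                self.sigma_scale *= float(p.magnitude)
            elif p.kind == "position_offset_mm":
                m = p.magnitude
                off = (float(m), float(m)) if np.isscalar(m) else (float(m[0]), float(m[1]))
                self.position_offset = (
                    self.position_offset[0] + off[0],
                    self.position_offset[1] + off[1],
                )
            elif p.kind == "noise_pct":
                if noise_seed is None:
                    raise ConfigurationError("noise_pct perturbation requires noise_seed")
                self.noise_pct = float(p.magnitude)

    def _rng(self, *key) -> np.random.Generator:
        ss = np.random.SeedSequence(self.noise_seed or 0, spawn_key=tuple(int(k) for k in key))
        return np.random.default_rng(ss)

    def depth_dose(self, energy: float, isd_cm: float = 0.0, rs: bool = False, dz: float = 0.2) -> Profile1D:
        r_eff = energy_to_range(energy, self.model) - (self.model.rs_wet if rs else 0.0)
        depths = np.arange(0.0, r_eff + 20.0, dz)
        prof = pristine_depth_dose(
            energy, depths, self.model, rs_inserted=rs, range_shift_mm=self.range_shift_mm
        )
        vals = prof.values * self.output_scale
        if self.noise_pct > 0:
            rng = self._rng(1, round(energy * 10), int(rs), round(isd_cm))
            vals = np.clip(vals * (1 + self.noise_pct / 100 * rng.standard_normal(vals.shape)), 0, None)
        return Profile1D(depths, vals, kind="depth")

    def spot_plane(self, energy: float, isd_cm: float, nominal: tuple = (0.0, 0.0), pixel: float = 0.68):
        """In-air single-spot plane at an ISD: (plane, x_coords, y_coords)."""
        m = self.model
        d = 10.0 * isd_cm  # plane distance upstream of isocenter
        kx = (m.vsad_x - d) / m.vsad_x
        ky = (m.vsad_y - d) / m.vsad_y
        cx = nominal[0] * kx + self.position_offset[0]
        cy = nominal[1] * ky + self.position_offset[1]
        g = m.nozzle_exit_to_isocenter - d
        s0 = m.spot_sigma0(energy)
        sig = float(np.hypot(s0, m.divergence_sigma_theta * g)) * self.sigma_scale
        half = 5.0 * sig
        x = np.arange(cx - half, cx + half + pixel / 2, pixel)
        y = np.arange(cy - half, cy + half + pixel / 2, pixel)
        plane = np.exp(-((x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2) / (2 * sig * sig))
        plane = plane * self.output_scale
        if self.noise_pct > 0:
            rng = self._rng(2, round(energy * 10), round(isd_cm))
            plane = np.clip(plane * (1 + self.noise_pct / 100 * rng.standard_normal(plane.shape)), 0, None)
        return plane, x, y

    def plan_dose(self, plan: PlanSpec, grid_spec: GridSpec) -> DoseGrid3D:
        p = plan
        if self.range_shift_mm:
            p = apply_perturbation(p, Perturbation("range_shift_mm", self.range_shift_mm))
        if self.output_scale != 1.0:
            p = apply_perturbation(p, Perturbation("output_scale", self.output_scale))
        if self.sigma_scale != 1.0:
            p = apply_perturbation(p, Perturbation("spot_sigma_scale", self.sigma_scale))
        if self.position_offset != (0.0, 0.0):
            p = apply_perturbation(p, Perturbation("position_offset_mm", self.position_offset))
        grid = compute_plan_dose(p, self.model, grid_spec)
        if self.noise_pct > 0:
            rng = self._rng(3)
            grid = apply_perturbation(
                grid, Perturbation("noise_pct", self.noise_pct), seed=int(rng.integers(2**31))
            )
        return grid


# ---------------------------------------------------------------------------
# Stage A: beam model validation
# ---------------------------------------------------------------------------

def _stage_1d(baseline, candidate, tol: ToleranceTable, energies, isds) -> pd.DataFrame:
    rows = []
    cases = [(e, isd, False) for e in energies for isd in isds]
    cases += [(e, 50.0, True) for e in RS_VERIFICATION_ENERGIES]
    for energy, isd, rs in cases:
        mb = analyze_depth_dose(baseline.depth_dose(energy, isd, rs))
        mc = analyze_depth_dose(candidate.depth_dose(energy, isd, rs))
        for metric, b, c, t in (
            ("r80_mm", mb.r80, mc.r80, tol.r80_mm),
            ("bpw80_mm", mb.bpw80, mc.bpw80, tol.bpw80_mm),
        ):
            dev = c - b
            rows.append(
                dict(energy_mev=energy, isd_cm=isd, rs=rs, metric=metric,
                     baseline=b, candidate=c, deviation=dev, tolerance=t,
                     sampling_ok=mb.sampling_ok and mc.sampling_ok,
                     **{"pass": abs(dev) <= t})
            )
    return pd.DataFrame(rows)


def _stage_2d(baseline, candidate, tol: ToleranceTable, energies, isds) -> pd.DataFrame:
    rows = []
    for energy in energies:
        for isd in isds:
            pb, xb, yb = baseline.spot_plane(energy, isd)
            pc, xc, yc = candidate.spot_plane(energy, isd)
            sb = analyze_spot(pb, xb, yb, plane_isd=isd)
            sc = analyze_spot(pc, xc, yc, plane_isd=isd)
            for ax in (0, 1):
                dev_pct = (sc.fwhm[ax] - sb.fwhm[ax]) / sb.fwhm[ax] * 100.0
                rows.append(
                    dict(energy_mev=energy, isd_cm=isd, metric=f"fwhm_{'xy'[ax]}_pct",
                         baseline=sb.fwhm[ax], candidate=sc.fwhm[ax],
                         deviation=dev_pct, tolerance=tol.fwhm_pct,
                         **{"pass": abs(dev_pct) <= tol.fwhm_pct})
                )
                dev_mm = sc.centroid[ax] - sb.centroid[ax]
                rows.append(
                    dict(energy_mev=energy, isd_cm=isd, metric=f"centroid_{'xy'[ax]}_mm",
                         baseline=sb.centroid[ax], candidate=sc.centroid[ax],
                         deviation=dev_mm, tolerance=tol.centroid_mm,
                         **{"pass": abs(dev_mm) <= tol.centroid_mm})
                )
    # VSAD recovery from deflected spots across planes
    energy = energies[len(energies) // 2]
    deflection = 50.0
    for ax, nominal in ((0, (deflection, 0.0)), (1, (0.0, deflection))):
        obs_b, obs_c = [], []
        for isd in isds:
            d = 10.0 * isd
            pb, xb, yb = baseline.spot_plane(energy, isd, nominal=nominal)
            pc, xc, yc = candidate.spot_plane(energy, isd, nominal=nominal)
            cb = analyze_spot(pb, xb, yb).centroid[ax]
            cc = analyze_spot(pc, xc, yc).centroid[ax]
            obs_b.append((d, deflection, cb))
            obs_c.append((d, deflection, cc))
        fb = fit_vsad(obs_b)
        fc = fit_vsad(obs_c)
        dev_pct = (fc.vsad - fb.vsad) / fb.vsad * 100.0
        rows.append(
            dict(energy_mev=energy, isd_cm=np.nan, metric=f"vsad_{'xy'[ax]}_pct",
                 baseline=fb.vsad, candidate=fc.vsad, deviation=dev_pct,
                 tolerance=tol.vsad_pct, **{"pass": abs(dev_pct) <= tol.vsad_pct})
        )
    return pd.DataFrame(rows)


def _stage_3d(baseline, candidate, tol: ToleranceTable, box) -> pd.DataFrame:
    size, center_wed, grid_spec = box
    plan = generate_sobp_plan(size, center_wed, target_dose=2.0, model=baseline.model,
                              spot_spacing=4.0)
    gb = baseline.plan_dose(plan, grid_spec)
    gc = candidate.plan_dose(plan, grid_spec)
    rows = []
    half = size[2] / 2.0
    for depth in np.linspace(center_wed - 0.6 * half, center_wed + 0.6 * half, 3):
        db, _ = reference_point_dose(gb, depth, averaging_diameter=10.0)
        dc, _ = reference_point_dose(gc, depth, averaging_diameter=10.0)
        dev = (dc - db) / db * 100.0
        rows.append(
            dict(metric="sobp_point_dose_pct", depth_mm=float(depth), baseline=db,
                 candidate=dc, deviation=dev, tolerance=tol.point_dose_pct,
                 **{"pass": abs(dev) <= tol.point_dose_pct})
        )
    high = gb.values > 0.5 * gb.values.max()
    mean_dev = float(np.mean((gc.values[high] - gb.values[high]) / gb.values[high]) * 100.0)
    rows.append(
        dict(metric="mean_3d_dose_pct", depth_mm=np.nan, baseline=0.0,
             candidate=mean_dev, deviation=mean_dev, tolerance=tol.ref_dose_pct,
             **{"pass": abs(mean_dev) <= tol.ref_dose_pct})
    )
    return pd.DataFrame(rows)


def run_beam_model_validation(
    baseline_source: SyntheticSource,
    candidate_source: SyntheticSource,
    tolerances: ToleranceTable = ToleranceTable(),
    energies=KEY_ENERGIES,
    isds_1d=(0.0, 50.0),
    isds_2d=(0.0, 40.0, 50.0, 58.0),
    box=((60.0, 60.0, 60.0), 120.0, None),
    include_3d: bool = True,
    seed: int | None = None,
) -> CommissioningReport:
    """Run the 1D → 2D → 3D beam-model validation and tabulate deviations.

    ``box`` is (size_mm, center_depth_wed_mm, grid_spec); a default scoring
    grid is derived from the box when grid_spec is None.
    """
    energies = tuple(float(e) for e in energies)
    if not energies:
        raise ConfigurationError("no energies requested")
    report = CommissioningReport()
    report.tables["1d"] = _stage_1d(baseline_source, candidate_source, tolerances, energies, isds_1d)
    report.stage_status["1d"] = "run"
    report.tables["2d"] = _stage_2d(baseline_source, candidate_source, tolerances, energies, isds_2d)
    report.stage_status["2d"] = "run"
    if include_3d:
        size, center, grid_spec = box
        if grid_spec is None:
            sx, sy, sz = size
            grid_spec = GridSpec(
                origin=(-sx / 2 - 20, -sy / 2 - 20, 0.0),
                spacing=(4.0, 4.0, 2.0),
                shape=(int(sx / 4) + 11, int(sy / 4) + 11, int((center + sz / 2 + 20) / 2)),
            )
        report.tables["3d"] = _stage_3d(
            baseline_source, candidate_source, tolerances, (np.asarray(size, float), center, grid_spec)
        )
        report.stage_status["3d"] = "run"
    else:
        report.stage_status["3d"] = "skipped"
    config = dict(
        energies=list(energies), isds_1d=list(isds_1d), isds_2d=list(isds_2d),
        tolerances=asdict(tolerances), include_3d=include_3d,
        baseline=baseline_source.label, candidate=candidate_source.label,
    )
    report.provenance = dict(
        seed=seed,
        config_hash=hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest(),
        config=config,
    )
    return report


# ---------------------------------------------------------------------------
# Output rescaling
# ---------------------------------------------------------------------------

def determine_output_scaling(deviations) -> OutputScaling:
    """Average 3D dose deviations (%) into an output rescaling factor.

    The factor is the additive percent correction applied to the candidate
    dose (equivalently a rescaling of the particles-per-MU in the beam
    model): ``factor = -mean(deviations)``; the residual mean deviation
    after correction is reported.
    """
    devs = tuple(float(d) for d in deviations)
    if not devs:
        raise DomainError("need at least one dose deviation")
    factor = -float(np.mean(devs))
    residual = float(np.mean([d + factor for d in devs]))
    return OutputScaling(scaling_factor_pct=factor, input_deviations=devs, residual_mean_pct=residual)


def apply_output_scaling(grid: DoseGrid3D, scaling: OutputScaling) -> DoseGrid3D:
    """Apply the additive percent correction to a candidate dose grid."""
    return grid.with_values(grid.values * (1.0 + scaling.scaling_factor_pct / 100.0))


# ---------------------------------------------------------------------------
# PSQA workflows
# ---------------------------------------------------------------------------

def default_point_layout(grid: DoseGrid3D) -> np.ndarray:
    """Default 24-chamber block layout (mm): a 4 x 3 lateral grid at two
    measurement depths, centered on the beam axis inside the grid."""
    a = grid.depth_axis
    zc = grid.axis_coords(a)
    z1 = zc[0] + 0.4 * (zc[-1] - zc[0])
    z2 = zc[0] + 0.6 * (zc[-1] - zc[0])
    xs = np.array([-30.0, -10.0, 10.0, 30.0])
    ys = np.array([-20.0, 0.0, 20.0])
    pts = []
    for z in (z1, z2):
        for x in xs:
            for y in ys:
                p = [0.0, 0.0, 0.0]
                lat = [i for i in range(3) if i != a]
                p[lat[0]] = x
                p[lat[1]] = y
                p[a] = z
                pts.append(p)
    return np.asarray(pts)


def run_psqa_case(
    tps_grid: DoseGrid3D,
    idc_grid: DoseGrid3D,
    protocol: str = "default",
    mode: str = "clinical",
    criteria: GammaCriteria | None = None,
    points: np.ndarray | None = None,
) -> dict:
    """Evaluate one PSQA case.

    ``clinical`` mode: 3D gamma map of the independent calculation against
    the TPS dose with the protocol's criteria, GPR, and classification.
    ``water-phantom-points`` mode: point-dose differences (%) at a block of
    chamber positions, reported as mean ± SD.
    """
    if criteria is None:
        criteria = criteria_for_protocol(protocol)
    if mode == "clinical":
        result = gamma_map(tps_grid, idc_grid, criteria)
        classification = classify_result(result.gpr, criteria)
        return dict(
            mode=mode, protocol=criteria.protocol,
            criteria=f"{criteria.dose_diff_pct:g}%/{criteria.dta_mm:g}mm",
            gpr_pct=result.gpr, n_evaluated=result.n_evaluated,
            n_capped=result.n_capped, classification=classification,
        )
    if mode == "water-phantom-points":
        from scipy.interpolate import RegularGridInterpolator

        if points is None:
            points = default_point_layout(tps_grid)
        coords = tuple(tps_grid.axis_coords(i) for i in range(3))
        f_tps = RegularGridInterpolator(coords, tps_grid.values)
        f_idc = RegularGridInterpolator(
            tuple(idc_grid.axis_coords(i) for i in range(3)), idc_grid.values
        )
        d_tps = f_tps(points)
        d_idc = f_idc(points)
        ok = d_tps > 0
        if not ok.any():
            raise AnalysisError("all chamber points sit in zero dose")
        dev = (d_idc[ok] - d_tps[ok]) / d_tps[ok] * 100.0
        return dict(
            mode=mode, protocol=protocol, n_points=int(ok.sum()),
            mean_dev_pct=float(dev.mean()), sd_dev_pct=float(dev.std(ddof=1)) if dev.size > 1 else 0.0,
            max_abs_dev_pct=float(np.abs(dev).max()),
        )
    raise ConfigurationError("mode must be 'clinical' or 'water-phantom-points'")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report: CommissioningReport, path: str, format: str = "structured") -> list:
    """Serialize a report: ``structured`` writes one JSON file; ``tabular``
    additionally writes one CSV per stage table.  Returns written paths."""
    os.makedirs(path, exist_ok=True)
    payload = {
        "stage_status": report.stage_status,
        "provenance": report.provenance,
        "gamma_summaries": report.gamma_summaries,
        "tables": {
            name: json.loads(df.to_json(orient="split", index=False))
            for name, df in report.tables.items()
        },
    }
    written = []
    jpath = os.path.join(path, "report.json")
    with open(jpath, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    written.append(jpath)
    if format == "tabular":
        for name, df in report.tables.items():
            cpath = os.path.join(path, f"stage_{name}.csv")
            df.to_csv(cpath, index=False)
            written.append(cpath)
    elif format != "structured":
        raise ConfigurationError("format must be 'structured' or 'tabular'")
    return written


def read_report(path: str) -> CommissioningReport:
    """Parse a structured report back into a :class:`CommissioningReport`."""
    with open(os.path.join(path, "report.json")) as fh:
        payload = json.load(fh)
    report = CommissioningReport(
        gamma_summaries=payload.get("gamma_summaries", []),
        provenance=payload.get("provenance", {}),
        stage_status=payload.get("stage_status", {}),
    )
    for name, blob in payload.get("tables", {}).items():
        report.tables[name] = pd.DataFrame(blob["data"], columns=blob["columns"])
    return report


# ---------------------------------------------------------------------------
# Clinical-parameter conversions
# ---------------------------------------------------------------------------

def scoring_voxel_volume(slice_thickness_mm: float, lateral_resolution_mm: float) -> float:
    """Scoring voxel volume (mm^3) when dose is scored on the CT grid."""
    return slice_thickness_mm * lateral_resolution_mm**2


def equivalent_uncertainty_pct(u_ref_pct: float, v_ref_mm3: float, v_mm3: float) -> float:
    """Statistical uncertainty in a voxel of volume ``v`` equivalent to
    ``u_ref`` in a voxel of volume ``v_ref`` at fixed fluence: the per-voxel
    particle count scales with volume and the uncertainty with 1/sqrt(N)."""
    if min(u_ref_pct, v_ref_mm3, v_mm3) <= 0:
        raise DomainError("arguments must be positive")
    return u_ref_pct * float(np.sqrt(v_ref_mm3 / v_mm3))


def range_shift_from_rwet(delta_rwet_pct: float, wed_mm: float) -> float:
    """Range difference (mm) produced by a systematic rWET deviation over a
    given water-equivalent distance (e.g. 2% over 100 mm → 2 mm)."""
    return delta_rwet_pct / 100.0 * wed_mm
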