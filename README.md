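# protonqa

Commissioning and patient-specific QA (PSQA) toolkit for scanned proton
beams, aimed at medical physicists who validate an independent dose
calculation (IDC) engine against a treatment planning system (TPS) and
against beam-line measurements.

When a clinic replaces measurement-based PSQA with an independent
recalculation of each plan, the IDC itself must first be commissioned: its
beam model, its CT calibration, and its dose-comparison tooling all need
quantitative validation with defined tolerances. `protonqa` implements that
workflow end to end:

* **1D** — Bragg-curve metrics: the clinical range R80 (depth of the distal
  80 %-of-maximum crossing), the peak width BPW80 (distance between the
  proximal and distal 80 % crossings), and the distal dose gradient, with an
  under-sampling safeguard for peaks narrower than twice the scoring step;
* **2D** — spot optics: centroid and per-axis FWHM of pencil-beam spots at
  arbitrary air gaps, and recovery of the virtual source-to-axis distance
  (VSAD) from spot positions across measurement planes,
  `x_meas = x_nom (VSAD − d)/VSAD`;
* **CT calibration** — Schneider-style stoichiometric HU→density→composition
  conversion (24 half-open HU bins, dense bone above 1500 HU, plus a
  TPS-style alternative with Al/Fe at the top of the scanner range), Bethe
  mass stopping powers with Bragg additivity, slab transport in residual
  water-equivalent range, and relative water-equivalent thickness
  `rWET = (R80,w − R80,m)/t`;
* **3D gamma analysis** — the gamma index
  `γ(r) = min_r' √(|r'−r|²/DTA² + ΔD²/(dd·Dmax)²)` with global normalization
  to the reference maximum, a 10 % low-dose threshold, per-protocol clinical
  criteria (2 %/2 mm; 3 %/3 mm for adult abdomen) and 95 %/90 %
  warning/fail levels on the gamma pass rate (GPR);
* **orchestration** — tolerance-checked commissioning reports, the output
  (particles-per-MU) rescaling step, and clinical / water-phantom PSQA case
  evaluation;
* **synthetic beam generator** — an analytical pencil-beam-scanning dose
  model (Bragg–Kleeman depth dose with Gaussian range straggling, Gaussian
  spots with virtual-source projection, NNLS-weighted SOBP boxes) with
  controlled error injection (range shift, output scale, spot-size error,
  position offset, noise), standing in for TPS/IDC/measurement data so the
  whole pipeline is testable at desk scale.

Dose grids are exchanged as DICOM RT Dose or a self-describing `.npz`
container; profiles and calibration curves as CSV.

## Worked example

```python
import numpy as np
from protonqa import *

model = BeamModel()                      # 62.4–252.7 MeV -> R80 30–380 mm
z = np.arange(0.0, 160.0, 0.2)
m = analyze_depth_dose(pristine_depth_dose(148.2, z, model))
print(m.r80, m.bpw80)                    # 144.24 mm, 3.76 mm

# inject a +2 mm range error into the "IDC" and validate against baseline
from protonqa.commissioning import SyntheticSource, run_beam_model_validation
baseline = SyntheticSource(model, label="tps")
candidate = SyntheticSource(model, (Perturbation("range_shift_mm", 2.0),), label="idc")
report = run_beam_model_validation(baseline, candidate, energies=(97.4, 148.2), include_3d=False)
print(report.tables["1d"].query("metric == 'r80_mm'")[["energy_mev", "isd_cm", "rs", "deviation", "pass"]])
```

prints (excerpt)

```
R80   = 144.24 mm   (calibrated range: 144.23 mm)
BPW80 = 3.76 mm, peak at 142.8 mm, sampling ok: True

 energy_mev  isd_cm    rs  deviation  tolerance  pass
       97.4     0.0 False        2.0        0.3 False
      148.2     0.0 False        2.0        0.3 False
       97.4    50.0  True        2.0        0.3 False
```

Every 1D range row shows the injected +2.0 mm deviation and fails the
±0.3 mm tolerance — the commissioning suite detects the error, while the 2D
spot rows (blind to a pure range error) stay green. The same objects drive
gamma analysis of 3D cases:

```python
res = gamma_map(reference_grid, evaluated_grid, criteria_for_protocol("adult head"))
print(res.gpr, classify_result(res.gpr, res.criteria))   # e.g. 99.7 'pass'
```

A thin CLI wraps these functions: `protonqa generate depth-dose`,
`protonqa analyze depth-dose`, `protonqa validate`, `protonqa ctcal`,
`protonqa psqa` (see `--help`).

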