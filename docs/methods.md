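# Methods

## Scope and design

`protonqa` validates an independent dose calculation (IDC) for scanned
proton beams the way a clinic commissions one: by comparing a *candidate*
dose source against a *baseline* source in stages of increasing delivery
complexity (1D pencil beams → 2D scanned layers → 3D modulated fields),
then validating the CT calibration chain, and finally exercising the
gamma-analysis and PSQA machinery with defined tolerances. Because real
TPS exports, Monte Carlo doses, and water-phantom measurements are not
shippable, both sources are backed by an analytical beam generator whose
errors can be injected deliberately; the pipeline's job is to detect them.

Monte Carlo transport itself is out of scope: engine settings (energy
cut-offs, step limits) would be metadata, never executed. Plan files use
the package's own plan objects, not DICOM RT Ion Plan; structure sets and
DVH-based evaluation are likewise out of scope.

## Synthetic beam model

**Energy–range calibration.** A power law `R80 = α E^p` with (α, p) fixed by
the clinical endpoints 62.4 MeV → 30 mm and 252.7 MeV → 380 mm in water
(p ≈ 1.815, the usual Bragg–Kleeman exponent range for therapeutic
protons). 255 clinical energies span the interval. Monotonicity and exact
endpoint reproduction are tested properties.

**Depth dose.** The pristine curve is the Bragg–Kleeman stopping profile
`D(z) ∝ (R − z)^(1/p − 1)`, cell-averaged analytically across its integrable
singularity and convolved numerically (0.05 mm internal grid) with a
Gaussian range-straggling kernel of width `σ_R = 1.2 % · R80` — a standard
straggling fraction for water. The distal 80 % crossing of the convolved
curve is located by dense root finding and the depth axis recalibrated so
R80 equals the power-law range *exactly*; this keeps the generator's
metrics controllable without the full Bortfeld closed form, which would add
fidelity the metric pipeline does not need. Consequences worth knowing:

* the entrance-to-peak dose ratio (~0.14) is lower than measured Bragg
  curves because nuclear build-up is not modeled;
* no beam energy spread (synchrotron momentum spread) is added, so
  low-energy peaks are narrower than measured ones: BPW80(62.4 MeV) ≈
  0.78 mm analytically. A 0.68 mm sampling step is therefore honestly
  flagged as under-sampled at the lowest energies (the flag triggers when
  BPW80 < 2 × step); sub-0.05 mm R80 agreement with the dense oracle needs
  ≈ 0.1 mm sampling in this model.

**Range shifter.** `rs_wet = 35 mm` water-equivalent thickness. Inserting it
reduces the effective range by exactly `rs_wet` at every energy (straggling
is still computed from the unshifted range, since straggling accumulates
over the full energy loss). The same 35 mm figure is reproduced
independently by slab transport (below), which is how the acceptance script
reports it.

**Spot model and geometry.** Each spot is a 2D Gaussian times the pristine
depth dose, normalized so the lateral integral equals the depth-dose value
(making integrated radial profiles σ-independent). Spot σ at the nozzle
exit falls linearly from 6.0 mm (62.4 MeV) to 2.5 mm (252.7 MeV), and grows
with air gap g as `σ(g) = √(σ0² + σθ² g²)` with divergence σθ = 3 mrad —
monotone spot growth with air gap, qualitatively matching beam-line
commissioning data. Lateral positions project from per-axis virtual sources:
`x(d) = x_iso (VSAD − d)/VSAD` at a plane d upstream of the isocenter, with
deliberately different defaults VSAD_x = 2000 mm and VSAD_y = 1800 mm so
per-axis fits cannot silently share state. Non-isocentric setups are
parameterized by the isocenter-to-surface distance (ISD, 0–58 cm); the air
gap rule is linear, `g = g0 − 10·ISD_cm + depth` with `g0 = 648 mm`. The
nominal nozzle-to-isocenter distance is specified as 65 cm while the quoted
air gap at ISD0 is 64.8 cm; these cannot both hold with a linear rule, so
the package adopts 648 mm as the air-gap origin and documents the choice
here. Scattering inside the phantom is not modeled beyond this geometric
divergence.

**SOBP boxes.** Energy layers are spaced ~0.8 × σ_R apart across the box
depth span (range-shifter auto-inserted when the proximal edge lies above
the 30 mm minimum range); spots form a uniform 2 mm-default lateral grid;
per-layer weights are solved by non-negative least squares against a flat
central-axis target. The solved plateau is flat within ±1 % in the tested
configurations (the acceptance band is ±2 % over the central 80 %).

**Perturbations.** Exactly one kind per perturbation: `range_shift_mm`
(translates the depth dose distally), `output_scale` (multiplies dose or
spot weights), `spot_sigma_scale`, `position_offset_mm`, and `noise_pct`
(zero-mean Gaussian, % of local dose, requiring an explicit integer seed —
there is no global random state). All generated doses are deterministic
given inputs and seed.

## Metric extraction

Level crossings (R80, proximal/distal 80 %, FWHM half-maximum) use linear
interpolation between bracketing samples — monotone-safe and standard
commissioning practice; a Gaussian-fit FWHM mode exists for cross-checking.
The distal gradient is reported in % of the profile maximum per mm. Ties
among near-equal maxima (within 0.1 %) resolve to the most distal sample
and are flagged. Profiles whose entrance plateau never drops below 80 %
have no defined BPW80 and raise an analysis error rather than guessing a
proximal bound. Reference point doses average over a disc (default 40 mm
diameter, emulating a large-area plane-parallel chamber; the averaging rule
is a package choice) with bilinear in-plane interpolation, and report the
local depth gradient alongside the dose because positioning uncertainty
dominates low-energy reference dosimetry.

Spot centroids are intensity-weighted means after subtracting the plane
minimum (noise-floor robustness); spots with ≥1 % of maximum signal on the
plane boundary are rejected as clipped. VSAD is linear in 1/VSAD and fitted
per axis in closed form; no correction for systematic sub-millimeter
centering offsets is applied.

## CT calibration and stopping power

HU→density conversion is piecewise-linear interpolation over per-protocol
control points, clamped at the curve ends (scanner range −1024…3071 HU).
HU→composition uses an embedded 24-bin stoichiometric table in the Schneider
tradition: air, two lung bins, six soft-tissue bins interpolating
adipose→muscle over −120…120 HU, thirteen skeletal bins interpolating red
marrow→cortical bone over 120…1500 HU, and a single dense-bone bin for
everything above 1500 HU (half-open bins, boundary belongs to the upper
bin). The exact bin boundaries used by any particular commercial engine
below 1500 HU are not public; the package uses this documented segmentation
and exposes the table. A second, TPS-style convention resolves the top of
the range with bone to 2432 HU, aluminium to 2832 HU and iron above —
switching conventions reproduces the implant-discrepancy mechanism (a
saturated 3071 HU voxel treated as dense bone stops ~27 % more per unit
mass than the same voxel treated as iron, so the engine using the bone
convention undershoots near implants).

Mass stopping power is the Bethe formula (spin-0 projectile, full W_max
term) without shell or density-effect corrections, which contribute well
below the 1 % level at 60–250 MeV; elemental Z, A and I-values follow the
standard ICRU-49-style tabulation, mixtures combine by Bragg additivity
(mass-fraction-weighted elemental stopping powers; equivalently a
log-average I). Water carries its standard tabulated I = 75 eV; at 150 MeV
the computed value agrees with the tabulated 5.445 MeV cm²/g to ~0.01 %.

Slab transport integrates `dR/dz = −RSP(E)` (RK4, 200 steps) on the
*residual water-equivalent range*, recovering E from the residual range via
the (extrapolated) power-law calibration. Formulating transport in range
space makes water-on-water closure exact (rWET ≡ 1.000 for any thickness) —
the invariant underpinning the rWET validation stage. WET of tissue-like
slabs varies by < 1 % across 97.4–198.0 MeV, the approximation that lets a
single rWET describe a sample. The clinic-facing corollary, used when
interpreting systematic rWET offsets, is the linear conversion
`Δrange = ΔrWET% × WED`, e.g. 2 % over 10 cm → 2 mm. Reproducing any
facility's *measured* rWET deviations is a non-goal (their samples and
measurements are proprietary); the mechanism is what is modeled.

## Gamma analysis

Reference = TPS-role grid, evaluated = IDC-role grid (swappable). Global
normalization to the reference maximum only; voxels at or below 10 % of it
are excluded from numerator and denominator. The spatial search minimizes
over a subvoxel lattice of step DTA/10 within a sphere of 2 × DTA
(`search_cap`), with trilinear interpolation of the evaluated grid; lattice
offsets are built as `(k·DTA)/10` so integer multiples of the DTA are exact
in floating point, and the pass comparison uses `γ ≤ 1 + 1e−9` — together
these make a pure translation by exactly the DTA score γ = 1.0 and pass, as
it should. Voxels whose minimum exceeds the cap are reported as capped and
counted as failing (the conservative choice; the count is reported
separately). The production kernel (numba, early termination on the
distance-sorted lattice; a pure-NumPy kernel is the fallback) agrees with
an exhaustive brute-force lattice search to machine precision, far inside
the 0.01 acceptance band. Clinical criteria: 2 %/2 mm for head, H&N and
pediatric CT protocols, 3 %/3 mm for adult abdomen; warning/fail levels
95 %/90 % on the GPR, boundary inclusive. Local-dose normalization and 2D
film-style gamma are out of scope.

One property worth spelling out: a +2 mm range shift in a *single* beam is
detected as a contiguous gamma-failing region at that beam's distal edge
only when another dose component anchors the field there (e.g. patched or
opposed beams) — a shift of an *entire* single-beam field is a pure
translation and legitimately passes at 2 mm DTA. The detection test
therefore uses two opposed beams meeting mid-phantom, mirroring the
clinical situations (patch junctions, opposed fields) where range errors
matter most.

## Commissioning orchestration

Stage order is fixed 1D → 2D → 3D → output rescaling → PSQA. Default
tolerances (±0.3 mm range, ±0.1 mm BPW80, ±5 % FWHM, ±0.5 mm centroid,
±2 % VSAD/doses) are labeled derived-from-practice and user-overridable —
they describe achieved agreement envelopes, not regulatory limits. The
output rescaling factor is the additive percent correction applied to the
candidate dose, `factor = −mean(3D deviations)` (the sign convention is
defined here because "scaling particles-per-MU up" and "a negative factor"
are otherwise ambiguous); the residual mean after correction is recomputed
and reported. The 24-point PSQA chamber layout (4 × 3 lateral grid at two
depths) is a documented default, fully configurable. Reports serialize to
sorted-key JSON plus CSV tables with seeds and a config hash; identical
config + seed yields byte-identical reports. The CLI takes its few options
as flags rather than a config file; the functions are the primary
interface.

## What the synthetic generator does and does not show

Passing tests demonstrate that the *analysis pipeline* — metric extraction,
tolerance bookkeeping, gamma search, material/stopping-power chain —
is correct against independent oracles and detects injected errors of
clinically relevant magnitude (2 mm range, 2 % output, 10 % spot size).
They do not demonstrate transport fidelity of any dose engine: the
generator has no nuclear halo, no heterogeneity-induced spot distortion,
no CT artifacts, and Gaussian-only spot shapes. Conclusions about a real
IDC still require the facility's measured baselines.

## Problem sizes

Default test problem sizes (9×9×9 gamma oracle grids, 40–80 mm SOBP boxes
on 2–4 mm grids, 0.05–0.2 mm profile sampling) were chosen so the full
suite and the acceptance script each run in well under a minute while
keeping every oracle comparison meaningful; all are parameters, not limits.
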