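# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `femfall`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort

Each (sex × ethnicity) cell is parameterised by the published marginal
means and SDs of nine variables (age, weight, height, BMI, supine TSTT,
FRAX-HFP, total-hip aBMD, T-score, femoral strength) together with its
cell size (male: 494 Chinese / 213 Indian / 273 Malay; female: 594 / 305 /
325; 2204 subjects in total after the documented exclusions
2235 − 18 − 13).

Draws are hierarchical: age is sampled first (normal, truncated at 60
years when truncation is on); the other drawn variables (weight, height,
supine TSTT, FRAX-HFP, aBMD, strength) receive a linear-in-age conditional
mean, `mean + slope·(age − mean_age)`, plus a correlated Gaussian residual
whose variance is shrunk by the trend variance so each marginal SD matches
its target. This construction keeps the joint covariance valid for any
slope configuration. Defaults:

| quantity | default | rationale |
|---|---|---|
| age slopes (per year) | aBMD −0.004 g/cm², strength −0.06 kN, FRAX +0.08 %, TSTT −0.02 cm | signs follow the observed trajectories (density, strength, soft tissue decline; fracture probability rises); magnitudes chosen so the implied age-correlation stays well below 1 in every cell |
| residual correlations | aBMD–strength +0.7, aBMD–FRAX −0.5, TSTT–weight +0.6, others 0 | plausible physiology; **not** derived from published data — only marginals were published. TSTT couples to weight (not BMI) because BMI is a derived field |
| truncation bounds | all quantities ≥ 0, FRAX ≤ 100 %, age ≥ 60 | physical/design limits, enforced by rejection |

Three fields are derived, never drawn: `bmi = weight/height²` (a hard
invariant), T-score = (aBMD − ref)/ref_sd with per-sex young-adult
references fitted by method of moments to the pooled marginals
(male 1.058 ± 0.1273 g/cm², female 0.9122 ± 0.1111), so T-score and aBMD
can never disagree in sign of deviation; and standing TSTT via the
supine-to-standing conversion below.

What passing tests show, and what they do not: the generator reproduces
the published *marginals* (untruncated) and the configured trends; it does
not reproduce the real cohort's joint distribution, so cross-biomarker
percentages (e.g. the share flagged by FRAX but not by strength) are
internally consistent but not comparable to the published cohort values.
Two documented consequences of the calibration itself: (1) truncation at
zero inflates the realised FRAX-HFP means above the printed parameters
(the female Chinese parameter 5.64 % with SD 5.03 has ~13 % of its mass
below zero), and rejection of those draws selects against correlated
low-aBMD/low-strength subjects; (2) the published female Chinese and Malay
strength marginals tie within rounding (3.54 ± 1.13 vs 3.55 ± 1.24 kN), so
no ordering of their strength-fragility rates is implied — the tests
assert the Chinese-highest-risk pattern only where the marginals actually
separate.

## Femur phantom

A three-primitive solid (head sphere, neck cylinder at the neck–shaft
angle, shaft cylinder) voxelised on an isotropic grid, with a cortical
shell (default 3 mm at 0.9 g/cm³) around a trabecular interior
(0.25 g/cm³). Landmarks (head centre, neck and shaft axes,
greater-trochanter point, distal shaft end) are emitted analytically.
The distal hinge of the strength model attaches to the distal shaft-end
centroid: the phantom is proximal-femur-only, so the anatomical hinge
point (condyle centre of a mean femur) is deliberately remapped there.
`project_abmd` line-integrates density along a projection axis and
averages over the bone footprint; with `target_abmd` set, the whole field
is rescaled to match, linking the phantom to a requested total-hip aBMD.
The phantom emulates none of: real DXA image appearance, scanner noise,
statistical shape variation, marrow cavity, or anatomical cross-sections —
absolute phantom strengths are therefore machinery-validation numbers,
not clinical ones.

## Supine-to-standing TSTT

`TSTT = slope·TSTT_sup + intercept` with the six published coefficient
pairs as data (slope 0.63/0.59 Chinese, 0.54/0.51 Indian, 0.53/0.62 Malay
for males/females; intercepts 3.12/2.29, 10.54/12.26, 8.94/6.23 cm). No
extrapolation guard is applied; inputs outside 0–10 cm log a warning. The
large Indian/Malay intercepts mean the conversion's output range sits well
above the supine input range; whether those fits are intended across the
full supine range is unstated in the source, so it is flagged, not
guessed. Note the cohort table's TSTT column is treated as the *supine*
measurement: its values are numerically incompatible with the standing
conversion's intercepts, so it cannot be the standing quantity.

The planar supine-TSTT measurement is a deliberately simple stand-in for
an unpublished image-processing pipeline: at the greater-trochanter row
(given, or detected as the widest bone row), it walks from the outer bone
edge to the skin edge using two intensity thresholds (body ≥ 0.05,
bone ≥ 0.5 by default). It is validated only on constructed phantoms.

## Material mapping

The density chain ρ<sub>K2HPO4</sub> → ρ_ash → ρ_app → E uses
literature-standard constants (ash calibration 0.877/0.0789 g/cm³, ash
fraction 0.6, power law 6850·ρ_app^1.49 MPa) that are **defaults, not
verbatim study values** — the source figure's constants are not printed in
the available text, so every constant lives in `CalibrationParams`.
Negative intermediate densities clamp to zero (a contract, not an error).
Yield: tensile yield stress = E·yield_strain (default 0.0085) times a
static `rate_factor` (default 1.0) that is all that survives of the
original 1 m/s strain-rate sensitivity in this quasi-static setting;
compressive yield is 1.2× tensile (configurable asymmetry).

Partial-volume correction replaces values in the surface layer (within
`depth` voxels of the boundary) with the nearest interior value along the
inward normal (via a Euclidean distance transform); interior voxels are
untouched, so corrected values never leave the interior range. Element
densities are trilinearly interpolated at centroids (default; 4-point
quadrature optional) and averaged before the chain is applied. Elements
fully outside the volume get a zero material (not the intercept floor)
plus a logged count.

## Strength model

Quasi-static, displacement-controlled, small-strain FE — the largest
deviation from the explicit-dynamics contact simulation it re-implements.
Consequences: no inertia, no contact gap, rate effects only through
`rate_factor`, and rigid supports idealised as nodal constraint sets.

* **Mesh**: structured Kuhn (6-tet) subdivision of a coarsened voxel
  lattice; 4-node tetrahedra by default at a 3 mm-class target edge
  scaled to the phantom resolution (the original models use 10-node
  tetrahedra at 3 mm; quadratic elements are available via
  `to_quadratic` and are never stiffer than linear ones on the same
  geometry). 0-based indices, mm coordinates, forces in N, strength in kN.
* **Pose**: the intrinsic frame (shaft axis, anterior, medial) is built
  from landmarks and mapped to shaft→+x, medial→+z, head centre at the
  origin; internal rotation is applied about the shaft axis, adduction
  (default −5°) about the anterior axis. Because the frame is intrinsic,
  posing is frame-indifferent by construction.
* **Supports**: head patch (nodes within `patch_radius` = 12 mm of the top
  of the posed femur) driven along −z; trochanter patch fully fixed — the
  source states all degrees of freedom were constrained there — with a
  "frictionless" axial-only option that adds one anti-spin pin (pure
  axial constraints leave a rigid in-plane rotation about the distal
  hinge); hinge node pinned in translation. Patches are z-band selections
  rather than nearest-node balls so that roundoff-level ties cannot move
  the patch. Patch sizes are an implementation choice; the original
  support geometry is not quantified.
* **Plasticity**: bilinear with von Mises yield; the sign of the
  volumetric strain selects the tensile or compressive yield stress.
  Resolved by damped secant-stiffness iteration (deformation plasticity),
  adequate for the monotonic proportional loading applied here; the
  post-yield tangent defaults to 5 % of E. Convergence: max secant change
  < 1e-3, or head-force stationarity (< 1e-4 relative over three
  iterations) when a handful of boundary elements flicker between yield
  branches without affecting the response. Non-converged increments are
  flagged and the run continues from the last converged state. A modulus
  floor of 1e-6× the maximum keeps nodes of zero-density elements from
  making the system singular.
* **Output**: resultant head reaction per increment; femoral strength is
  the curve peak. At every converged increment the head, trochanter and
  hinge reactions balance along the load axis to machine precision
  (asserted at 1e-6 of the peak).

Verification in place of unavailable subject-level truth: patch test
against the closed-form constrained modulus; elastic-limit equivalence
with a one-shot linear solve (0.1 %); elastic–perfectly-plastic column
plateau = area × yield stress (5 %); density power-law scaling of elastic
strength (10 %, pure-power-law calibration); frame indifference (1 %);
mesh-refinement stability (< 10 % on halving the target edge). Problem
sizes in the tests (phantoms of order 1–10 k elements, 1.5–3 mm voxels)
are the package's chosen desk-scale configuration.

## Statistics

One-way ANOVA is computed from the classical SSB/SSW decomposition with
(k−1, N−k) degrees of freedom; zero within-group variance returns
F = +inf, p = 0 (or F = 0 when means also coincide) by documented
convention. It agrees with `scipy.stats.f_oneway` and with F = t² on two
groups. Age adjustment is classical ANCOVA (single common slope; no
slope-by-group interaction by default): adjusted means are group levels
evaluated at the grand-mean age, and the group effect is the
extra-sum-of-squares F conditional on age; a constant age vector falls
back to plain ANOVA with a warning. LOWESS (statsmodels backend) uses
span 2/3 with one robustness iteration by default — the method's span was
not published — evaluated on an even age grid, with seeded
bootstrap-percentile 95 % bands (199 pair resamples by default; the
published bands' construction is unstated). Significance convention
p < 0.05, no multiple-testing correction (none was applied in the source
analysis).

## Risk classification

Boundary conventions are chosen and documented because inclusivity is
never stated in the source: T ≤ −2.5 osteoporotic, −2.5 < T < −1
osteopenic, T ≥ −1 normal; FRAX-HFP ≥ 2 % at risk; strength strictly
below the sex threshold (3 kN female, 3.5 kN male) fragile. The strength
thresholds carry a provenance caveat: they derive from a Korean cohort
and are unvalidated against incident fractures. `cross_tabulate` reports
both the exclusive joint categories and the marginal totals because
published summaries of this kind mix the two views; counts partition each
stratum exactly and marginals satisfy frax = both + frax_only,
strength = both + strength_only by construction.

## Pipeline and reproducibility

One master seed; stage seeds derive from it by a fixed SeedSequence spawn
order (cohort 0, phantom 1, trajectories 2), so stages are independently
reproducible. Every output carries a config hash computed over the
scientific configuration (output directory and verbosity excluded);
manifests from two runs of the same configuration and seed are identical
up to timestamps. CSV is comma/point/UTF-8 with a mandatory header and
passthrough of unknown columns; meshes and fields are legacy ASCII VTK
(diffable); volumes are NIfTI with a JSON landmark sidecar.

## Known limitations

No contact mechanics, soft-tissue padding, inertia, fracture-surface
prediction, or damage history in the FE model; TSTT is a separate
biomarker, not a boundary condition. The generator's correlations and
trends are modelling choices, not estimates. FRAX-HFP is simulated or
consumed, never computed from its 12 clinical risk factors. No survival
or incident-fracture modelling (the study design has none). Absolute
phantom strengths are not clinically interpretable.
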