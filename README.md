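# femfall

Hip fractures in older adults are poorly predicted by the clinical standard,
the DXA-derived T-score: a large share of fractures occur in people whose
areal bone mineral density (aBMD) is above the osteoporosis threshold.
`femfall` implements a complete, testable pipeline for studying how four
complementary biomarkers stratify hip-fracture risk in a multi-ethnic older
cohort (Chinese, Indian and Malay Singaporeans aged 60+): total-hip aBMD and
its T-score, the FRAX 10-year hip-fracture probability (FRAX-HFP),
trochanteric soft tissue thickness (TSTT), and femoral strength from a
finite-element simulation of a sideways fall.

It is aimed at musculoskeletal biomechanics and bone-epidemiology
researchers who want to prototype or stress-test this kind of analysis
without access to clinical data: a synthetic-data layer generates cohort
tables calibrated to published descriptive statistics and parametric
proximal-femur density phantoms, so every downstream stage runs end to end
out of the box.

## What it computes

**Standing TSTT** from the supine DXA measurement, per sex and ethnicity:

    TSTT = slope · TSTT_sup + intercept        [cm]

with the six published (sex × ethnicity) coefficient pairs shipped as an
editable table, plus a simplified two-threshold edge-walk measurement of
supine TSTT on planar DXA-like phantom images.

**Femoral strength** by a quasi-static finite-element model. Mineral
density (ρ<sub>K2HPO4</sub>, g/cm³) is converted to material properties via

    ρ_ash = 0.877·ρ_K2HPO4 + 0.0789,   ρ_app = ρ_ash / 0.6,
    E     = 6850 · ρ_app^1.49  MPa

(all constants configurable), mapped onto a tetrahedral mesh after a
partial-volume surface correction. The femur is posed for a sideways fall
(−5° adduction, 0° internal rotation), supported at the greater trochanter,
hinged distally, and driven downward at the femoral head; elements follow a
bilinear elastic–plastic law with tension–compression asymmetry. Femoral
strength is the peak resultant head reaction force, in kN.

**Cohort statistics**: per-group descriptives and size-weighted pooling,
one-way ANOVA across ethnicities, ANCOVA age adjustment (common slope,
adjusted means at the grand-mean age), and LOWESS age trajectories with
bootstrap confidence bands.

**Risk classification** against the standard thresholds — T-score −2.5
(osteoporosis) and −1 (osteopenia), FRAX-HFP 2 %, and sex-specific
fragility thresholds of 3 kN (female) / 3.5 kN (male) — with
cross-tabulations reporting both the exclusive joint categories
(both / FRAX-only / strength-only / neither) and the marginal totals.

## Worked example

```python
import femfall as ff

# phantom femur rescaled to a total-hip aBMD of 0.75 g/cm^2
spec = ff.FemurPhantomSpec(target_abmd=0.75)
vol = ff.generate_femur_phantom(spec, seed=42)
mesh = ff.mesh_from_volume(vol, target_edge=6.0)
mat = ff.map_to_elements(vol, mesh, ff.CalibrationParams())

cfg = ff.FallConfig()                       # -5 deg adduction sideways fall
posed = ff.pose_femur(mesh, cfg)
ff.assign_contact_sets(posed, cfg)
res = ff.solve_strength(posed, mat, cfg)

print(f"projected aBMD    : {ff.project_abmd(vol, 'y'):.3f} g/cm^2")
print(f"mesh              : {mesh.n_nodes} nodes, {mesh.n_elements} tetrahedra")
print(f"femoral strength  : {res.femoral_strength:.2f} kN")
print(f"yielded elements  : {100*res.yield_fraction[-1]:.0f} % at {res.displacement[-1]:.1f} mm")
```

prints

```
projected aBMD    : 0.750 g/cm^2
mesh              : 992 nodes, 3774 tetrahedra
femoral strength  : 19.08 kN
yielded elements  : 35 % at 3.0 mm
```

The projected aBMD confirms the phantom was rescaled to the requested
areal density; the strength is the peak of the force–displacement curve,
reached here with about a third of the elements past yield. Absolute
phantom strengths reflect the idealised solid-cylinder geometry and are
several times higher than typical clinical estimates for real femurs —
the phantom validates the machinery, not human anatomy (see
`docs/methods.md`).

The cohort side works the same way:

```python
params = ff.CohortParams()                  # calibrated study defaults
records = ff.generate_cohort(params, seed=42)
ff.add_standing_tstt(records)
table = ff.cross_tabulate(records)
male = table[("male", "pooled")]
print(male["frax_at_risk_percent"], male["strength_fragile_percent"])
```

A command-line interface mirrors the library
(`femfall simulate-cohort | make-phantom | tstt | strength | trajectories |
classify | run`); `femfall run --seed 1 --out out/` executes the whole
pipeline and writes a manifest with the seed and a config hash.

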