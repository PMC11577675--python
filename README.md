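# osteokin

Virtual biplanar medial open-wedge high tibial osteotomy (owHTO) planning
and squat-kinematics simulation on synthetic lower-limb anatomy.

The package reproduces an in-silico surgical experiment end to end:

1. **synthetic anatomy** — generate parametric lower-limb models (landmark
   sets + watertight triangle meshes) whose measured anatomical indices
   (hip–knee–ankle angle, axial TT–TG distance, Insall–Salvati ratio)
   follow configurable cohort distributions;
2. **osteotomy engine** — plan and execute the biplanar owHTO virtually:
   main cut parallel to the medial tibial slope from a medial entry at half
   the plateau width, lateral sagittal hinge axis 15 mm below the plateau,
   coronal biplanar plane 10 mm behind the tibial tuberosity, extended
   *ascending* (tuberosity travels with the distal fragment) or
   *descending* (tuberosity stays proximal), opened to wedge heights of
   6–12 mm by a rigid hinge rotation;
3. **patellar repositioning** — for ascending cuts, translate the patella
   proximodistally so the 3D patellar tendon length is preserved exactly;
4. **squat simulator** — a deterministic quasi-static stand-in for a
   commercial multibody engine: at each integer flexion angle from 5° to
   100° it minimises a documented potential energy (body-weight-scaled
   quadriceps, stiff tendon link, tension-only cruciate/collateral
   ligament springs, constant-force hamstrings, trochlear channel) over
   tibial rotation and patellar shift/slide/rotation/tilt;
5. **statistics** — per-curve RMSE against the preoperative model,
   median/range summaries, paired change t-tests at 100° flexion, and
   random-intercept linear mixed models of kinematics on wedge height and
   cut variant.

All coordinates are millimetres in a right-handed frame (+X lateral for a
right limb, +Y anterior, +Z proximal); left limbs are stored mirrored into
this convention with the flag retained.

## CLI

```sh
osteokin run --limbs 13 --seed 0 --out results/run0     # full pipeline
osteokin run --dry-run                                  # print the plan
osteokin generate --limbs 5 --out results/cohort        # anatomy only
osteokin osteotomize --out results/cuts                 # cuts + index table
osteokin simulate --limbs 2 --heights 6 --heights 12 --out results/sim
osteokin validate results/run0                          # invariant checks
```

`run` produces a deterministic artifact tree: `meshes/` (STL fragments),
`landmarks/` (JSON, schema-versioned), `curves/` (tidy CSV of all four
kinematic parameters vs flexion), `tables/` (index table, grid manifest,
RMSE summary, t-tests, mixed models, report.json) and `logs/run.json` with
the config hash and seed. Re-running with the same config yields identical
tables. Configuration is a YAML file mirroring `ExperimentConfig`
(cohort distributions, wedge heights, variants, every simulator constant);
`--seed/--limbs/--heights/--variants` override it.

## Module map

| module | contents |
| --- | --- |
| `osteokin.anatomy` | `CohortSpec`, `Landmarks`, `LimbModel`, generator, parametric bone meshes |
| `osteokin.metrics` | anatomical frames, HKA / TT–TG / Insall–Salvati, index table |
| `osteokin.osteotomy` | `OsteotomyPlan`, fragment split, wedge transform, experiment grid |
| `osteokin.patella` | tendon-length-preserving patellar repositioning |
| `osteokin.squat` | `KneeModel`, `SimParams`, equilibrium solver, flexion sweep, experiment runner |
| `osteokin.stats` | RMSE, summaries, paired t-tests, mixed models, QQ export |
| `osteokin.mesh` | minimal watertight TriMesh: plane clipping, STL/PLY I/O |
| `osteokin.config` / `osteokin.cli` / `osteokin.pipeline` | configuration, CLI, orchestration |

## Notes and limitations

- The simulator is an explicit, self-contained stand-in: its equations and
  constants are documented configuration, not a reproduction of any
  commercial engine. Absolute kinematic magnitudes are therefore model
  constants; cross-variant and cross-height *differences* are the outputs
  of interest. Menisci and articular contact pressures are not modelled.
- The body-weight estimate is a linear regression on femoral head diameter
  with configurable coefficients.
- Mixed models are random-intercept-only (REML); singular fits on tiny
  grids are reported with diagnostics rather than raised.
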