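# valvemetrics

Quantitative analysis of simulated heart-valve closure: regurgitant orifice
area (ROA) measured directly on 3-D surface meshes, coaptation/contact
metrics from finite-element cell fields, an incompressible Lee–Sacks
leaflet material model, and the uncertainty-quantification machinery
(one-at-a-time sweeps, polynomial-chaos surrogates, total-order Sobol
indices, rank-ordering analysis) needed to study how material assumptions
propagate into those valve-function metrics.

## Why

Finite-element models of the mitral valve are increasingly used to ask
clinical "what if" questions, but the material properties of a specific
patient's leaflets are unknown. A standard way to cope is to perturb the
constitutive parameters — stiffness-like coefficients `c0`, `c1`, the
exponential shape factor `c2` of the Lee–Sacks strain-energy function, and
leaflet thickness — over wide ranges (here ±50%) and check which *functional*
outputs (does the valve leak? how large is the orifice? how much leaflet
contact?) are robust and which are sensitive.

Two measurement problems make this harder than it sounds:

1. **ROA is a 3-D quantity.** Projecting the orifice onto a plane
   underestimates leaks through tilted or tortuous gaps. We measure ROA by
   shrink-wrapping a cover surface onto the closed-valve geometry and then
   *ray-casting* through every candidate gap: a patch of the cover only
   counts as orifice if at least one ray in a cone about the through-flow
   direction escapes the valve entirely. Deep creases and folds that a naive
   cover would bridge are correctly rejected because no ray gets out.
2. **Sensitivity needs a surrogate.** Total-order Sobol indices are
   estimated from a polynomial-chaos expansion fitted on a
   weighted-approximate-Fekete-point (WAFP) design, so a handful of model
   runs yields global sensitivities; a one-at-a-time sweep (4 parameters ×
   5 levels = 20 runs) provides the directly interpretable complement.

Because patient geometries cannot ship with the code, the package includes a
generator of synthetic valve-like fixtures whose orifice areas are known
*analytically* (plates with circular holes, sealed-crease traps with one true
through-slot, domes, coapted leaflet pairs). Every numerical claim in the
test suite is checked against those closed-form truths or against independent
brute-force oracles.

## Worked example

Generate a plate with a single 5 mm circular hole (true orifice area
π·25 = 78.54 mm²) and measure it:

```console
$ valvemetrics synth plate-hole --out plate.vtp --landmarks-out lm.json --truth-out truth.json
true orifice area = 78.5398 mm^2

$ valvemetrics roa --mesh plate.vtp --landmarks lm.json --out roa.json --save-wrap wrap.vtp
ROA = 78.263 mm^2 in 1 orifice(s)
```

`roa.json` is self-describing — it echoes the full configuration alongside
the results:

```json
{
 "components": [{"area_mm2": 78.26337287515749, "n_faces": 1129}],
 "config": {"cone_angle": 50.0, "n_rays": 400, "remesh_vertices": 4000,
            "thickness": 0.396, "...": "..."},
 "converged": true,
 "iterations": 2,
 "potential_area_mm2": 78.26337287515749,
 "roa_mm2": 78.26337287515749,
 "tool_version": "0.1.0",
 "wrap_area_mm2": 452.22926414225856
}
```

The measured 78.263 mm² is 0.35% below the analytic value (the meshed hole
rim is an inscribed polygon, so a small underestimate is expected).

The crease-trap fixture shows why the ray filter matters. Its cover surface
bridges two deep *sealed* trenches (≈120 mm² of false "potential orifice")
while the only true leak is a 2×10 mm through-slot:

```console
$ valvemetrics synth crease-trap --out trap.vtp --landmarks-out trap_lm.json
true orifice area = 20.0000 mm^2 (bridged trap 120.0 mm^2)

$ valvemetrics roa --mesh trap.vtp --landmarks trap_lm.json --out trap_roa.json \
      --thickness 0 --remesh-vertices 8000
ROA = 19.934 mm^2 in 1 orifice(s)
```

The shrink-wrap alone reports 139.4 mm² of potential orifice; ray casting
cuts that to 19.93 mm², within 0.4% of the true slot area.

Material and UQ tools:

```console
$ valvemetrics material variant --out variant.json --target-pct 10
variant c0=64.2388 c1=953.4327 (achieved 10.000%)

$ valvemetrics uq oat --out oat.json
OAT design: 20 rows over 4 parameters
```

The same functionality is available as a Python API:

```python
from valvemetrics import (FixtureSpec, make_fixture, RoaConfig, compute_roa)

fix = make_fixture(FixtureSpec(kind="plate_hole"))
res = compute_roa(fix.mesh, fix.landmarks, RoaConfig(thickness=fix.thickness))
print(res.roa, len(res.components))   # 78.26337287515749 1
```

## What is in the box

| module            | contents |
|-------------------|----------|
| `mesh_io`         | VTP/OBJ/PLY/STL surface meshes with per-cell fields; JSON/FCSV landmarks |
| `orifice`         | inflation, contour spline, disk warp, shrink-wrap, cone ray filter, ROA |
| `contact_metrics` | contact area from traction fields, area-weighted field means |
| `material`        | incompressible isotropic Lee–Sacks model, uniaxial curves, inverse, extensibility variants |
| `uq`              | parameter spaces, OAT designs, WAFP designs, PCE fitting, Sobol indices, ordering consistency |
| `synthetic`       | fixtures with analytic truths (plates, traps, domes, coapted leaflets) |
| `cli`             | `valvemetrics` command with `roa`, `metrics`, `material`, `uq`, `synth` subcommands |

See `docs/methods.md` for models, algorithms, numerical choices and known
limitations.

## Reproduction

All headline quantities can be recomputed from scratch:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This regenerates every fixture, runs the full ROA pipeline on each, fits the
Ishigami-benchmark polynomial-chaos surrogate, and writes one JSON entry per
quantity as `{"value": ..., "n": ...}` (where `n` is the sample or design
size behind the value). With `--seed 1` the key results are:

| quantity | value | reference |
|----------|-------|-----------|
| `roa_plate_hole_mm2` | 78.263 | π·25 = 78.540 |
| `roa_two_holes_mm2` | 40.638 (2 orifices) | 13π = 40.841 |
| `roa_intact_plate_mm2` | 0.0 | 0 |
| `roa_crease_trap_mm2` | 19.934 | 20 (trap bridges 139.4) |
| `roa_rotation_max_change_pct` | 1.6e-13 | 0 (rotation invariance) |
| `ishigami_total_sobol_max_abs_dev_from_analytic` | 3.3e-05 | 0 |
| `oat_design_rows` | 20 | 4 params × 5 levels |
| `variant_loop_max_abs_error_pct` | 2.5e-13 | 0 |

Deterministic quantities are bit-identical across seeds; only the seeded
checks (random rotations, random Saltelli reference sample, WAFP candidate
pools) vary, and they stay within their tolerances for any seed. The test
suite (`python -m pytest -q tests/`) asserts every one of these claims, plus
a 10⁵-ray brute-force visibility oracle cross-check of the crease-trap
ray filter.
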