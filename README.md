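# dialysim

Finite-volume simulation of hollow-fiber hemodialyzers as two
interpenetrating porous media — anisotropic Darcy flow for the blood
(fiber lumina) and dialysate (shell) compartments on one shared mesh,
membrane ultrafiltration and urea exchange through volumetric source
terms, and the device metrics used to compare module designs: urea
clearance, per-side pressure drops, the volume-averaged shell Sherwood
number and the convective (ultrafiltration) share of solute transport.

The package ships a catalogue of 13 module configurations — five housing
shapes (long/short cylinder, thick/flat rectangle, coaxial cylinder)
crossed with dialysate port layouts (8×8 nozzle rings, single same-side
or opposite nozzles, full-length slits, coaxial end ports) — plus the
in-vitro saline validation protocol for the commercial long-cylinder
unit. See `docs/methods.md` for the model, discretisation and
assumptions.

## Worked example

Simulate the commercial configuration (long cylinder, 8 dialysate
inlets/outlets, counter-current) at blood 300 mL/min, dialysate
500 mL/min, ultrafiltration 10 mL/min, urea inlet 20 mol/m³:

```python
from dialysim import comparison_case, run_coupled

case = comparison_case("1A")           # level-1.0 study mesh, 10x24x72 cells
result = run_coupled(case)
print(result.summary())
```

Output (exact numbers; the solver chain is deterministic):

```
{'case': '1A', 'dp_B_Pa': 9431.9, 'dp_D_Pa': 4895.4, 'Sh_D_avg': 14.08,
 'CL_ml_min': 230.0, 'UF_pct': 3.64, 'Q_UF_ml_min': 9.991, 'n_steps': 6}
```

The run converges in 6 alternation steps; the blood-side pressure drop
(9432 Pa) is within 4% of the 9833 Pa used to calibrate the housing
length, the average shell Sherwood number is 14.08, and 230 mL/min of
the 300 mL/min blood flow is cleared of urea. Under the saline
validation protocol (both compartments carry dialysate properties) the
same machinery gives

```python
from dialysim import validation_case
run_coupled(validation_case(200)).CL   # 188.6 mL/min
run_coupled(validation_case(300)).CL   # 247.5 mL/min
```

against reference in-vitro model values of 192 and 255 mL/min (−1.8%
and −2.9%).

Full converged fields (`p`, `C`, `u` per side, local `Sh_D`, `Re_t`) are
in `result.fields`; `dialysim.report.write_report([result], "out/")`
writes a summary CSV/JSON, legacy-VTK field files and a clearance bar
chart.

### Command line

```
dialysim run --config case.yaml --out results/
dialysim sweep --cases a.yaml --cases b.yaml --report table.csv
dialysim mesh --config case.yaml --out mesh.vtk
```

with a YAML config like

```yaml
case: 2B          # one of 1A-1D, 2A-2D, 3A, 3B, 4A-4C, or "validation"
level: 1.0        # mesh-resolution scale
Q_UF_ml_min: 10
port_diameter_mm: 8
```

## The 13-configuration comparison

Computed at the study resolutions (level 1.0, same membrane area,
volume and operating point everywhere):

| case | housing / ports | CL (mL/min) | ⟨Sh_D⟩ | Δp_D (Pa) | UF% |
|---|---|---|---|---|---|
| 1A | long cyl, 8×8 nozzles | 230.0 | 14.1 | 4895 | 3.6 |
| 1B | long cyl, 1×1 same side | 224.2 | 17.5 | 19777 | 4.0 |
| 1C | long cyl, 1×1 opposite | 228.1 | 18.1 | 19791 | 3.8 |
| 1D | long cyl, slits | 212.9 | 19.6 | 1586 | 3.3 |
| 2A | short cyl, 8×8 nozzles | 157.2 | 14.8 | 2827 | 4.1 |
| 2B | short cyl, 1×1 same side | 61.1 | 13.3 | 22496 | 14.4 |
| 2C | short cyl, 1×1 opposite | 213.0 | 22.5 | 26640 | 2.3 |
| 2D | short cyl, slits | 210.6 | 22.6 | 6939 | 2.4 |
| 3A | thick rectangle, cross-flow | 214.7 | 20.1 | 1416 | 2.4 |
| 3B | flat rectangle, cross-flow | 219.6 | 27.1 | 22153 | 4.2 |
| 4A | coaxial, 6×6 end ports | 229.7 | 16.3 | 4384 | 3.4 |
| 4B | coaxial, 4×1 end ports | 229.6 | 16.9 | 5590 | 3.4 |
| 4C | coaxial, 1×1 end ports | 229.5 | 17.3 | 6452 | 3.4 |

The qualitative picture: the commercial configuration 1A clears the
most; the short cylinder with a single same-side nozzle pair (2B)
short-circuits the dialysate and clears by far the least while relying
most on ultrafiltration; single-nozzle and slit layouts raise the local
Sherwood number but lose more to maldistribution than they gain in
transfer.

## Reproduction

```
pip install --no-build-isolation -e ".[test]"
pytest                                    # unit + property + acceptance tests
python scripts/acceptance.py --seed 0 --out acceptance.json
```

The acceptance script recomputes every reported quantity from scratch
(about 8 simulations, a few minutes on one CPU) and writes them as JSON.
Everything is deterministic: direct sparse factorisations, no random
initial guesses; the `--seed` flag only pins the environment RNG.

Two caveats, analysed in `docs/methods.md`:

* With the printed transport coefficients, the counter-flow
  effectiveness bound caps the blood-property clearance of case 1A near
  240 mL/min, about 10% below the published comparison value of
  257 mL/min — while the saline validation cases, which exercise the
  same machinery, agree to 3%. The computed blood-property clearances
  therefore sit systematically ~10–15% below the published comparison
  table, and two of the corresponding acceptance tests fail honestly at
  their stated tolerances.
* Port dimensions for the single-nozzle, slit and coaxial layouts are
  not published; defaults (8 mm nozzles, 5 mm slits) are config
  parameters, and the dialysate pressure-drop *ordering* across cases
  depends on them.

## Layout

```
src/dialysim/
  mesh.py        structured FV meshes (Cartesian / cylindrical)
  geometry.py    housing shapes, calibrated dimensions, port layouts
  flow.py        Darcy pressure operator, factorised solves
  membrane.py    Sherwood correlation, exchange coefficients, fluxes
  transport.py   upwind advection-diffusion with membrane sources
  driver.py      alternating coupling + ultrafiltration tuning
  report.py      metrics, tables, VTK, charts
  reference.py   effectiveness-NTU oracles and test fixtures
  cases.py       the 13 configurations and the validation protocol
  config.py/cli.py  YAML configs and the `dialysim` command
tests/           unit, property-based and acceptance suites
scripts/acceptance.py
docs/methods.md
```
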