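# facprof

Frontal affinity chromatography (FAC) quantitation and glycan-binding
specificity profiling for jacalin-related lectins (JRLs), built around the
pearl-shell mantle lectins PPL2A, PPL3 and PPL4 as archetypes.

## The problem

Lectins are non-catalytic carbohydrate-binding proteins; characterizing one
means measuring its affinity for each glycan in a large panel. FAC does this
by infusing a fluorescently tagged (pyridylaminated, PA) glycan at initial
concentration [A]₀ through a miniature column (ø 2 × 10 mm, bed volume
31.4 µL) carrying the immobilized lectin. Binding retards the glycan's
elution front by V − V₀ relative to a non-binding standard, and for a
single-site equilibrium

```
Kd = Bt / (V − V0) − [A]0,        Ka = 1 / Kd
```

where Bt is the column's effective ligand content (nmol). With Bt in nmol,
volumes in µL and concentrations in mol/L, the identity nmol/µL ≡ mmol/L
supplies the 10³ factor in the arithmetic. Bt and the reference Kd are
calibrated from a concentration-dependence series via the Woolf–Hofstee
linearization: plotting (V − V₀) against (V − V₀)[A]₀ gives a line with
slope −1/Kd and intercept Bt/Kd, fitted by ordinary least squares.

The package implements the complete measurement chain:

| stage | module |
|---|---|
| glycan panel model + TSV I/O | `facprof.glycan_panel` |
| FAC equations, Woolf–Hofstee calibration | `facprof.fac_core` |
| breakthrough-front detection (equal-area / half-height) | `facprof.front_detection` |
| hemagglutination-inhibition MICs and titers, censoring | `facprof.hai` |
| Ka profiles, relative affinity, mJRL group classification | `facprof.profiling` |
| seeded synthetic instrument + panel + archetypes | `facprof.synthetic` |
| end-to-end orchestration / CLI | `facprof.pipeline`, `facprof.cli` |

Because neither the instrument traces nor the full 130-glycan appendix are
publicly deposited, `facprof.synthetic` generates a stated stand-in world
(panel composition 61 N-linked + 39 glycolipid-type + 30 others; three
lectin archetypes; sigmoid fronts with 2 % fluorescence noise) so every
stage is testable end to end. See `docs/methods.md` for what that does and
does not establish.

## Worked example

```python
import facprof as fp

# calibrate a column from a noiseless concentration series (PPL3s values)
pts = fp.simulate_calibration_series(0.63, 3.01e-5, noise_cv=0.0)
cal = fp.woolf_hofstee_fit(pts, "PPL3s")
print(cal.bt_nmol, cal.kd_ref_M)        # 0.63 0.0000301

# one glycan: V - V0 = 20.93 uL at [A]0 = 2.5 nM on that column
kd = fp.kd_from_retardation(0.63, 20.93, 2.5e-9)
print(round(1 / kd))                    # 33233  (Ka ~ 3.32e4 1/M)

# full archetype run: curves -> fronts -> Kd -> classification
panel = fp.make_archetype_panel(0)
run = fp.run_archetype_experiment("PPL2A_like", panel, fp.SimulationConfig(seed=1))
print(run.assignment.group, run.assignment.subgroup)   # A 1
```

The strong complex-type binder classifies as mJRL group A, subgroup 1
(binds complex-type glycans, reduced by a bisecting GlcNAc); the
mannose/chitin binder archetype comes out group A, unclassified subgroup
(no complex-type binding at all).

The numbered drivers under `analysis/` replay the whole study — panel and
plate generation, column calibration, profiling of the three archetypes,
the MIC table, classification — writing small tables under `results/`:

```
python analysis/01_generate_data.py
python analysis/02_calibrate_columns.py
python analysis/03_quantify_profiles.py
python analysis/04_hai_table.py
python analysis/05_classify.py
```

A `facprof` console script exposes the same pipeline as `generate`,
`calibrate`, `quantify`, `hai` and `classify` subcommands (exit codes:
2 I/O, 3 model/fit, 4 validation).

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time, the
deterministic checkpoints of the pipeline: the Woolf–Hofstee recovery of
each column's printed calibration parameters from noiselessly simulated
concentration series, and the MICs of three reference 2-fold dilution
plates. Run it as

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
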