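# tcellflux

Compartmentalized ¹³C metabolic flux analysis for [U-¹³C]glucose tracer
experiments in activated T cells, built as a reusable, fully testable
pipeline:

- **`network_model`** — a plain-text reaction dialect with carbon
  atom-transition maps, three compartments (extracellular / cytosol /
  mitochondrion), extraction-mixing reactions for dual-compartment
  metabolites, and dilution terms (unlabeled CO₂ inflow, extracellular
  pyruvate exchange). Exposes the stoichiometric matrix and a
  deterministic free-flux (null-space) parameterization.
- **`emu_engine`** — steady-state mass-isotopomer simulation by EMU
  (elementary metabolite unit) decomposition, verified against an
  independent brute-force full-isotopomer solver.
- **`ms_processing`** — natural-abundance correction for MOX-TBDMS
  GC-MS fragments (convolution matrices, non-negative least-squares
  inversion, SD propagation), MID table I/O, replicate averaging.
- **`exchange_rates`** — uptake/secretion rates from spent-media
  time courses at 0/6/24 h, via through-origin regression of consumption
  against integrated cell density (exponential interpolation).
- **`flux_fitting`** — multi-start variance-weighted least squares on
  free net fluxes + compactified exchange fluxes + mixing fractions,
  two-sided χ² goodness-of-fit, SSR-profile 95% confidence intervals,
  and condition comparison (CI-overlap verdicts) with DOT flux-map export.
- **`synthetic_data`** — complete synthetic experiments (MID tables with
  natural abundance re-applied, media/growth CSVs, ground-truth sidecar)
  from two flux regimes: `WT-like` (glycolysis/lactate high) and
  `KO-like` (OxPhos/TCA high, elevated glutamine/pyruvate uptake).

All flux units are nmol·(10⁶ cells)⁻¹·h⁻¹. Simulation happens in
tracer-atom space; natural isotope abundance is handled entirely by the
correction layer. The bundled network and fragment library are
documented reconstructions (the study's exact model file and monitored
SIM ions are unpublished).

## CLI

```bash
# synthesize an experiment with known ground truth
tcellflux synth --preset WT-like --seed 7 --out wt/

# extracellular rates from spent media + growth
tcellflux rates --media wt/media.csv --growth wt/growth.csv --out wt/rates.json

# fit fluxes (bundled model/fragments/tracer by default)
tcellflux fit --mids wt/mids.csv --rates wt/rates.json \
    --condition WT --out wt/result.json --dot wt/map.dot

# profile 95% confidence intervals (updates result.json)
tcellflux ci --result wt/result.json --mids wt/mids.csv \
    --rates wt/rates.json --flux ldh --flux pdh

# compare two conditions
tcellflux compare wt/result.json ko/result.json --out cmp.tsv
```

`tcellflux fit --config fit.toml` accepts a `[fit]` table overriding
`n_starts` (default 50), `seed`, bounds, tolerances, the χ² significance
level and the CI confidence level.

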