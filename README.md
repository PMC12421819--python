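# c1flux

Modeling toolkit for synthetic C1-trophic metabolism (formatotrophy and
methylotrophy via the reductive glycine pathway) in engineered bacteria.
It bundles the computational stages needed to design and validate such
strains:

* **`c1flux.network`** — a curated core central-metabolism network
  (C1 uptake, THF-mediated formate activation, reverse glycine cleavage,
  serine/pyruvate formation, TCA cycle, glyoxylate shunt, anaplerosis,
  lumped energy metabolism and biomass drains) with carbon atom maps for
  the labeling subnetwork, parameterized by strain genotype
  (`KT2440-core`, `rG1`, `rG1-T`, `rG-F`, `rG-M`, or custom
  knockouts/modules). Carbon balance and atom-map bijectivity are
  validated at build time.
* **`c1flux.fba`** — flux balance analysis (scipy/HiGHS) with a
  parsimonious tie-break for deterministic flux maps, theoretical-yield
  computation and normalization of fluxes to substrate uptake = 100.
* **`c1flux.isotopes`** — positional ¹³C-isotopomer propagation at
  isotopic steady state (fixed point over 2^n pattern distributions,
  symmetric-metabolite averaging, CO2-reassimilation mixing), predicted
  amino-acid mass-isotopomer distributions (MIDs), and discrimination of
  TCA-entry hypotheses (cyclic TCA vs glyoxylate/malate synthase vs
  anaplerosis) against observed MIDs.
* **`c1flux.midcorr`** — natural-abundance correction matrices for
  TBDMS-derivatized amino-acid fragments (Ala260, Gly246, Ser390,
  Asp418, Glu432) and NNLS-based MID correction.
* **`c1flux.kinetics`** — growth-rate/doubling-time fitting on ln(OD)
  with automatic exponential-window detection, specific uptake rates
  (q_S = ΔS/Δt/X) and biomass yields (Y_X/S = ΔX/ΔS).
* **`c1flux.synth`** — synthetic growth curves (lag/exponential/
  stationary with exact pre-noise mass balance) and raw MID datasets for
  end-to-end, download-free testing.
* **`c1flux.gem`** — optional genome-scale SBML-FBC extension
  (requires `cobra`): closes the native serine/glycine/glyoxylate entry
  reactions and appends the heterologous C1 reactions.

## CLI

```bash
c1flux build-model --strain rG-F --out model.json
c1flux fba --strain rG-F --substrate for --uptake 18.5 --out fluxes.tsv
c1flux simulate-labeling --strain rG-F --scenario formatotrophic_13CO2 \
       --hypothesis anaplerosis --out mids.csv
c1flux correct-mid --raw raw_mids.csv --out corrected.csv
c1flux discriminate --observed corrected.csv --strain rG-F \
       --scenario formatotrophic_12CO2
c1flux fit-growth --curve od.csv --od-to-cdw 0.4
c1flux estimate-uptake --curve od.csv --substrate formate.csv
c1flux generate-synthetic --regime formatotroph --seed 1 --out data/
c1flux run --config pipeline.yaml --out results/
```

Tracer scenarios can be named presets (`unlabeled`, `mixotrophic_13C`,
`formatotrophic_12CO2`, `formatotrophic_13CO2`) or YAML files:

```yaml
name: my_scenario
substrate_labels:
  for: [0.99]
  co2: [0.0]
co2_reassimilation: 0.0
```

## Notes on defaults

Cofactor parameters (P/O ratios, growth/non-growth ATP maintenance),
biomass precursor-drain coefficients, the OD600→gCDW factor (0.4) and
the TBDMS fragment elemental formulas are documented package defaults,
editable via `build_core_model(...)` keyword arguments and the
`FragmentSpec`/`SimulationRecipe` dataclasses.
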