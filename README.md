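# hydrogem

Constraint-based analysis of anaerobic gut-fungal metabolism: a
core-scale stoichiometric model of *Neocallimastix lanati* with an
explicit hydrogenosome, and the machinery to interrogate it.

Anaerobic gut fungi (Neocallimastigomycota) decompose lignocellulose in
the herbivore digestive tract and run an entirely fermentative
metabolism. Their mitochondrion-derived organelle, the hydrogenosome,
converts malate and pyruvate to acetate, formate and H₂ while making ATP
by substrate-level phosphorylation. Two open questions drive the model's
design: whether H₂ comes from pyruvate:ferredoxin oxidoreductase (PFO)
or pyruvate formate lyase (PFL), and whether a speculative bifurcating
hydrogenase or proton-pumping module could raise the organism's energy
yield.

The package is aimed at researchers in constraint-based metabolic
modeling and anaerobe physiology. It provides:

* a curated 3-compartment core network (EMP glycolysis with PPi-linked
  phosphofructokinase and both NAD⁺/NADP⁺ GAPDH variants, non-oxidative
  pentose phosphate pathway, xylose isomerase route, mixed-acid
  fermentation, lumped CAZymes, hydrogenosome with PFL/PFO/hydrogenases
  and the ATP-yielding acetate route, and bounded-to-zero speculative
  machinery), elementally balanced throughout, with a JSON on-disk format;
* a biomass objective compiled from the measured macromolecular
  composition (fractions summing to 81.8% of dry weight, renormalized),
  with growth-associated maintenance GAM = 75.98 mmol ATP/gDW embedded and
  non-growth-associated maintenance NGAM = 2.27 mmol ATP/gDW/h as a flux
  floor;
* FBA / parsimonious FBA / flux variability analysis and seedable
  artificial-centering hit-and-run flux sampling over the near-optimal
  polytope (S·v = 0, lb ≤ v ≤ ub, c·v ≥ 0.9 c·v*);
* maintenance-energy estimation: max-ATP-yield regression against growth
  rate over cellobiose-gradient cultures (slope → GAM, intercept → NGAM);
* the 46-test substrate-utilization / vitamin-essentiality validation
  battery, scored by accuracy and Matthews correlation coefficient;
* hydrogenosome scenario analyses (ferredoxin vs bifurcating hydrogenase
  vs proton module), compartment-wise NAD⁺/ATP production over samples,
  formate:(acetate+ethanol) ratio distributions, and constraint
  sensitivity of prediction error;
* a reduced ¹³C metabolic flux analysis stack: elementary-metabolite-unit
  (EMU) decomposition and steady-state mass-isotopomer simulation under a
  [1,2-¹³C]glucose tracer, a brute-force isotopomer oracle, and
  variance-weighted least-squares flux fitting with profile-likelihood
  identifiability flags;
* synthetic-data generators for every pipeline stage (growth experiments,
  measured-flux tables, labeled MIDs), deterministic given a seed.

See `docs/methods.md` for the model's assumptions, parameters and
numerical choices.

## Worked example

```python
import hydrogem as hg

# base case: ferredoxin hydrogenase, glucose uptake 1.5 mmol/gDW/h
model = hg.build_default_model()
print(hg.fba(model).objective_value)          # 0.042783  (growth rate, 1/h)

# swap in the bifurcating hydrogenase
bif = hg.build_default_model(hg.ScenarioConfig(hydrogenase_mode="bifurcating"))
print(hg.fba(bif).objective_value)            # 0.049791  (+16.4%)

# substrate/vitamin validation battery
accuracy, mcc, cm = hg.score_predictions(hg.run_battery(model))
print(round(100 * accuracy, 1), round(mcc, 2))  # 89.1 0.79

# maintenance energy from synthetic gradient cultures (5% noise)
spec = hg.GeneratorSpec(seed=1, noise_cv=0.05)
fit = hg.fit_maintenance(model, hg.generate_growth_experiments(model, spec),
                         volume=spec.volume)
print(fit.summary())
```

The last call prints:

```
Maintenance-energy fit (max ATP yield ~ growth rate)
----------------------------------------------------
n experiments : 5
GAM  (slope)  :     73.276 mmol ATP/gDW
NGAM (intercept):    2.254 mmol ATP/gDW/h
R^2           :     0.9983
```

Reading the numbers: the base model grows at 0.0428 h⁻¹ on 1.5 mmol
glucose/gDW/h — within a few percent of the measured 0.045 h⁻¹ — and the
bifurcating hydrogenase raises the optimum by ~16% because it lets the
hydrogenosome regenerate cytosolic NAD⁺, freeing acetyl-CoA from the
ethanol route. The validation battery reproduces 41 of the 46 printed
growth/essentiality outcomes (89%, MCC 0.79), with the model's xylose
false positive and biotin false essentiality among the five misses. The
maintenance fit on one noisy synthetic replicate lands within ~4% of the
generating GAM (75.98) and ~1% of NGAM (2.27).

The same operations are available from the shell:

```bash
hydrogem build-model --scenario base --out model.json
hydrogem fba --out fluxes.tsv
hydrogem validate --out battery.tsv
hydrogem scenario --modes base,bifurcating,proton --n 2000 --seed 1 --outdir out/
hydrogem sample --n 2000 --seed 1 --out samples.tsv
hydrogem synth growth --seed 1 --out growth.tsv
hydrogem mfa simulate --out mids.tsv
```

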