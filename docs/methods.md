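# Methods

`hydrogem` is a core-scale constraint-based model of the central and
hydrogenosomal metabolism of the anaerobic gut fungus *Neocallimastix
lanati*, together with the analysis machinery needed to interrogate it:
flux balance analysis (FBA), parsimonious FBA, flux variability analysis,
hit-and-run flux sampling, maintenance-energy regression, a qualitative
substrate/vitamin validation harness, hydrogenosome scenario analyses, and
a reduced elementary-metabolite-unit (EMU) simulator and fitter for
steady-state ¹³C labeling data. This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## The core network

The model spans three compartments — extracellular (`e`), cytosol (`c`)
and hydrogenosome (`h`) — with 162 metabolites and 184 reactions:

* **Glycolysis** (Embden–Meyerhof–Parnas) with both the NAD⁺ and the
  non-phosphorylating NADP⁺ variant of glyceraldehyde-3-phosphate
  dehydrogenase. Phosphofructokinase is PPi-linked, an energy-conserving
  trait of anaerobic eukaryotes; the PPi pool is closed by a reversible
  pyrophosphatase, i.e. the phosphoanhydride free energy of PPi is not
  tracked, and glycolysis yields a net 3 ATP per glucose.
* **Pentose phosphate pathway, non-oxidative only** — the oxidative
  entry (glucose-6-phosphate dehydrogenase, 6-phosphogluconate steps) is
  absent in this organism, so pentoses are made (and xylose is consumed)
  through transketolase/transaldolase, and NADPH comes from the NADP⁺-GAPDH.
* **Mixed-acid fermentation**: lactate dehydrogenase, pyruvate formate
  lyase (PFL) with the acetaldehyde/alcohol dehydrogenase ethanol route,
  and the reductive succinate branch (PEP carboxykinase → malate
  dehydrogenase → fumarase → soluble NADH-linked fumarate reductase).
* **Hydrogenosome**: reversible uniporters for pyruvate, malate, acetate,
  formate, CO₂, H₂ and phosphate plus an adenine-nucleotide translocase
  (the membrane is impermeable to H⁺ except through the explicit
  machinery); malic enzyme; PFL; pyruvate:ferredoxin oxidoreductase (PFO,
  ferredoxin modeled as a two-electron carrier); ferredoxin hydrogenase;
  a hydrogen dehydrogenase restricted to its energetically favorable
  direction (H₂ + NAD⁺ → NADH; the H₂-evolving direction is strongly
  endergonic, ΔG ≈ 34 ± 5.9 kJ/mol, recorded as an annotation); and the
  ATP-yielding acetate route (acetate:succinyl-CoA transferase +
  succinyl-CoA synthetase). Speculative machinery — the Thermotoga-type
  bifurcating hydrogenase (NADH + Fdred + H⁺ → NAD⁺ + Fdox + 2 H₂) and a
  lumped complex-1/2 + ATP-synthase proton module — is present but bounded
  to zero flux in the base case; scenario configurations open it.
* **Lumped extracellular CAZymes** hydrolyze cellobiose, maltose,
  maltodextrin, sucrose, raffinose, cellulose, xylan and lignocellulose to
  their monomers; the cell imports monosaccharides only.
* **Lumped biosyntheses** produce the 20 amino acids, NTPs/dNTPs,
  N-acetylglucosamine (chitin monomer), the three saturated fatty acids
  (C14:0/C16:0/C18:0) with a glycerol backbone, and the six vitamins with
  complete pathways (pyridoxine, riboflavin, folate-from-pABA,
  pantothenate, nicotinate, thiamine). Heme and biotin have no synthesis
  route and must be taken up; folate cannot be imported and is made from
  4-aminobenzoate; methionine synthesis is cobalamin-independent. Each
  lumped reaction names its carbon skeletons (pyruvate, PEP, oxaloacetate,
  G6P, E4P, R5P …) and its NAD(P)H/ATP costs and is closed exactly over
  {NH₃, CO₂, Pi, H₂O, H⁺}, so the whole network is elementally balanced
  (all species are carried in neutral, fully protonated form; formal
  charges are zero by construction and charge balance reduces to hydrogen
  balance).

Gene associations and confidence scores for the hydrogenosomal enzymes
follow the organism's annotated protein identifiers; speculative reactions
carry confidence 1.

Two deliberate simplifications keep structural identities exact. First,
the acetyl-CoA pool has no sinks besides the acetate and ethanol routes —
lumped fatty-acid and chitin synthesis draw their C2 units from pyruvate
directly. Consequently, in any feasible solution with zero PFO flux every
secreted acetate or ethanol is accompanied by exactly one formate, and the
formate:(acetate+ethanol) ratio is exactly 1; PFO flux lowers it below 1.
Second, there is no fructose-1,6-bisphosphatase and PEP carboxykinase is
irreversible toward oxaloacetate, so no gluconeogenesis exists: C2–C4
acids, amino acids and other non-sugar substrates cannot support growth,
which is what makes the negative half of the validation battery emerge
mechanistically rather than by fiat.

## Biomass and maintenance

The biomass reaction is compiled from the measured macromolecular
composition (carbohydrate 32.4%, protein 43.7%, lipid 4.9%, DNA 0.2%,
RNA 0.6% of dry mass; the measured fractions sum to 81.8%). By default the
gap to 1 g is closed by proportional renormalization; an "ash sink" mode
keeps the measured fractions. Monomer coefficients divide each fraction by
the free-monomer molar mass, so one unit of biomass flux drains 1.000 g of
monomers; polymerization releases water (peptide and glycosidic bonds) or
PPi (nucleotide incorporation — which also feeds the PPi-PFK). The
carbohydrate fraction is entirely chitin; the amino-acid distribution
defaults to a documented generic fungal proteome frequency vector (the
organism's predicted-proteome distribution is not printed); nucleotide
vectors default to uniform; the fatty-acid split defaults to equal thirds
(the measured relative ratios are only available graphically) — all three
are overridable. Trace vitamin demands (10⁻⁵ mmol/gDW each) couple the
eight required cofactors to growth.

Maintenance follows the convention GAM = 75.98 mmol ATP per gDW embedded
in the biomass reaction and NGAM = 2.27 mmol ATP/gDW/h as the lower bound
of a separate ATP-hydrolysis reaction. (The source tables attach the "/h"
to GAM rather than NGAM, transposed relative to this standard convention;
the standard convention is implemented.) Because GAM was estimated by
regression against whole-culture data it subsumes polymerization energy,
so the biomass reaction carries no separate polymerization ATP term.

## Calibration of the lumped biosyntheses

A ~180-reaction core network lumps away most of the anabolic detail of a
genome-scale reconstruction. Two systematic consequences: the redox
turnover of biosynthesis is understated (every lumped step hides
NAD(P)H-cycling reactions) and its marginal ATP cost is overstated. The
builder therefore applies two effective multipliers to the reductant and
ATP coefficients of the lumped monomer syntheses
(`ANABOLIC_REDUCTANT_SCALE = 4.0`, `ANABOLIC_ATP_SCALE = 0.5`). They were
fixed once, at design time, so that the reduced model reproduces the
parent reconstruction's two benchmark behaviors at the measured glucose
uptake of 1.5 mmol/gDW/h: a base-case growth rate near 0.044 h⁻¹ and a
~16% growth gain when the bifurcating hydrogenase replaces the ferredoxin
hydrogenase. Both multipliers act on the same documented table of
per-monomer precursor/reductant/ATP entries; neither touches the
exchange, fermentation or hydrogenosome stoichiometry. The aggregate
anabolic reductant demand after scaling (~45 mmol NAD(P)H per gDW) is the
effective quantity that gives the base case its fermentative redox relief;
it is roughly twice the explicit NADPH demand of published microbial
reconstructions, the excess standing in for the hidden redox cycling of
the lumped pathways. The growth gain from electron bifurcation is
controlled by exactly this quantity, because the bifurcating hydrogenase's
benefit is the NADH it disposes for free that fermentation would otherwise
dispose at ~0.5 ATP per NADH.

## LP machinery

All solves use `scipy.optimize.linprog` (HiGHS) with solver tolerance
1e-9; solutions are validated against S·v = 0 and the bounds at 1e-6.
Bounds default to ±1000 mmol/gDW/h, keeping the polytope compact.
Parsimonious FBA minimizes Σ|v| via splitting into irreversible pairs (no
MILP) after pinning the objective at a fraction of its optimum (with a
1e-9 relative backoff so the stage-1 vertex stays feasible). Alternate
optima are resolved by pFBA throughout.

Sampling is artificial-centering hit-and-run in null-space coordinates:
fluxes pinned by FVA at the target objective fraction (width < 1e-8) are
folded into the equality system so the walk only moves in genuinely free
directions; the start point is the Chebyshev center of the reduced
polytope; directions pass through a reservoir-sampled set of previously
visited points; warm-up is 1000 steps and thinning 100 (neither is stated
for the published protocol; both are this package's documented defaults).
Samples satisfy the constraints to machine precision by construction, and
the single-free-flux marginal on a box polytope passes a
Kolmogorov–Smirnov uniformity test at n = 2000.

The growth/no-growth call threshold for qualitative predictions is
μ > 10⁻⁴ h⁻¹ (the wet-lab criterion was pressure accumulation, for which
no flux equivalent is printed). Sole-carbon-source tests scale each
substrate's uptake bound to glucose-carbon equivalents
(1.5 × 6 / n_carbon mmol/gDW/h) so polymers are not trivially advantaged.

## Maintenance-energy estimation

For each gradient culture, specific rates are Δmoles/(Δt × Δdry-mass) —
the dry-mass increment, because lysed biomass no longer metabolizes. The
max-ATP solve fixes growth to zero (the ATP cost of growth must not be
double-counted), relaxes the NGAM floor, closes every unmeasured carbon
route in both directions, caps each measured secretion from above at its
measured rate, and leaves the substrate uptake rate free: at ~10%
substrate depletion between samplings the depletion difference is
dominated by assay noise, while the secreted products pin the same
carbon/energy budget far more precisely. GAM and NGAM are the slope and
intercept of the ordinary-least-squares line of maximum ATP yield against
growth rate; the fit result carries R² and residuals.

## Synthetic data

The generators define the study conditions and are first-class, tested
code:

* **Growth experiments** — five cellobiose levels (1–5 g/L), two
  samplings 24 h apart, 10 mL cultures, 0.5 mg inoculum dry mass. Growth
  rates follow a saturating Monod-like curve (μmax = 0.07 h⁻¹, K = 3 g/L)
  placing the 5 g/L culture at the observed exponential growth rate; only
  monotonicity matters to the fit. Each culture's fermentation profile is
  constructed analytically on the network's route stoichiometry — the
  route mix mirrors the measured mixed-acid proportions, the PFL acetate
  route closes the redox balance, and the profile is scaled to the
  maintenance ATP budget implied by the ground-truth GAM/NGAM — so the
  fitting procedure recovers the ground truth exactly on noiseless data
  (audited against the LP in the tests). Multiplicative lognormal noise
  applies to the measured concentrations (liquid products, substrate,
  headspace H₂), averaged over triplicate tubes; dry masses and the
  pressure-derived growth rate are carried as given, since they derive
  from a many-point pressure fit and a single end-point weighing.
* **Flux tables** — replicate rates drawn from a normal truncated at
  zero; the reported bounds are the observed replicate range, mirroring
  the printed table's semantics.
* **Labeled MIDs** — EMU-simulated steady-state fractions under a
  [1,2-¹³C]glucose tracer (99% positional purity, natural abundance off)
  with additive Gaussian noise whose standard deviation is proportional to
  the fraction (5% by default) plus a 5×10⁻⁴ absolute floor — the
  realistic mass-spectrometric error model — renormalized per replicate.

What the generators do **not** emulate: lag/decline-phase kinetics,
pressure traces, chromatographic artifacts, natural isotope abundance,
and biological (as opposed to measurement) variance. Passing tests
therefore demonstrate the correctness and statistical behavior of the
estimation machinery under the stated error models, not field performance
on raw instrument data.

## Reduced ¹³C labeling model

The atom-transition network mirrors the mapped central metabolism:
glycolysis, both directions of the non-oxidative PPP, the PFL/PFO split,
and the PEP-carboxykinase → malate → malic-enzyme cycle with its CO₂
exchange. The malate/fumarate pool scrambles its backbone (fumarate is
symmetric; the scrambling exchange is fixed at 100 uptake-units,
near-equilibrium fumarase) — this is what renders CO₂ fixation visible
under the [1,2-¹³C] tracer. Succinate leaves from the malate pool;
effluxes are unlabeled sinks. The measured-fragment panel (a documented
default; the exact measured fragment set is not enumerated in the source)
reads pyruvate (alanine), oxaloacetate (aspartate), ribose (RNA), F6P
(glycogen glucose), the C2 acetyl unit (ethanol/acetate) and formate.

EMU decomposition walks backward from the target fragments; simulation
solves one linear system per EMU size. An independent brute-force
positional-isotopomer simulator (damped Gauss–Seidel with per-update
renormalization — the raw iteration's probability mass is unstable under
condensation cycles) verifies the EMU path to 10⁻¹⁰ on toy networks and
10⁻⁸ on the full reduced network.

Fitting is variance-weighted nonlinear least squares over a free-flux
parametrization (anaplerotic flux, PFO share, PPP cycling) with box
bounds and multi-start. Identifiability is diagnosed by profile
likelihood: a parameter is flagged flat unless fixing it 10% off its
optimum and re-optimizing the rest raises the SSR by at least the 95%
χ²(1) quantile; best fits pinned to a box bound are flagged flat
conservatively. Under this tracer the PFO share is structurally invisible
(the pyruvate-C1 and CO₂ pools equilibrate) and the anaplerotic flux is
only weakly identified; both are consistently flagged rather than
silently returned, while the PPP cycling flux and the dependent
glycolytic fluxes are recovered within a few percent at realistic noise.
Constraining the hydrogenosome to pyruvate-only import removes the
malic-enzyme return and pins the anaplerotic flux — the reduced analogue
of resolving the malate/pyruvate import degeneracy by constraint. Because
the parent study's measured intracellular fluxes are published only
graphically, the labeling module's quantitative claims are
parameter-recovery properties on synthetic data, not numeric comparisons.

## Known limitations

* The two calibration multipliers are effective parameters of the reduced
  network, not measurements; reduced-model growth rates inherit their
  validity only near the calibrated operating point (glucose-limited
  anaerobic growth).
* In the reduced network the H₂ constraint is more informative than in
  the parent model (H₂ is stoichiometrically tied to PFO and hence to the
  formate identity), so in the constraint-sensitivity analysis acetate is
  the most informative *carbon-product* constraint while H₂ can outrank
  it overall.
* Fumarase scrambling is included in the labeling model but not in the
  stoichiometric model's atom bookkeeping (the stoichiometric model does
  not track atoms at all).
* Vitamin exchanges are uptake-only; the model cannot secrete cofactors.
* No thermodynamic (ΔG-constrained) or loopless FBA; recorded ΔG values
  are annotations. No enzyme-capacity or regulatory constraints — the
  PFL-vs-PFO partitioning observed in vivo is attributed to regulation
  outside the model's scope.
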