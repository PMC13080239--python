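# Methods

## The reduced kinetic network

The model (`src/myoflux/models/cardiac_reduced_v1.yaml`) describes central
cardiac energy metabolism as 14 lumped reactions over 18 species. Each
catabolic pathway segment is one reaction: glucose transport (facilitated,
insulin-activated), glycolysis, lactate exchange (MCT + LDH, reversible and
redox-coupled), fatty-acid transport/activation, β-oxidation of a lumped
C16 fatty acid, ketolysis (separate β-hydroxybutyrate and acetoacetate
steps sharing one enzyme set), BCAA oxidation (valine/leucine/isoleucine
steps sharing the BCAT/BCKDH proteins), pyruvate dehydrogenase, the TCA
cycle, a lumped respiratory chain, and a hyperbolic ATP demand
`v_ATP = load · ATP/(ATP + K_m)`. Units are mM for concentrations and
mM·min⁻¹ per g wet tissue for fluxes; whole-heart values are per-gram values
times cardiac mass.

Key simplifications, all visible in the definition file:

* **Single reducing-equivalent pool.** FADH₂ is not a separate carrier;
  β-oxidation delivers 7 NADH per palmitate and the respiratory chain
  operates at P/O = 2.5. The stoichiometric ATP yields that follow —
  glucose 34, palmitate 103.5, lactate 16, β-hydroxybutyrate 23.5,
  acetoacetate 21, valine/isoleucine 27, leucine 38 ATP per molecule — are
  computed from the network at build time by solving each substrate's unique
  steady-flux mode, never hard-coded. They sit close to textbook values, and
  the ATP/O₂ ceiling over pure substrates (glucose, 34/6 ≈ 5.67) bounds every
  simulated mixture ratio.
* **Oxygen is clamped** (no delivery limitation) and CO₂ is an explicit
  boundary product so the validator can check per-reaction carbon balance.
  The lumped BCAA stoichiometries are chosen to balance literal carbons
  (valine 5C → 2 acetyl-CoA + CO₂; leucine 6C → 3 acetyl-CoA; isoleucine
  6C → 2 acetyl-CoA + 2 CO₂); nitrogen disposal and O/H bookkeeping are
  outside the network. Redox bookkeeping reduces to the conserved NAD⁺+NADH
  pool; ATP+ADP is the second conserved pool.
* **Uniform NAD gating.** Every substrate-uptake lump carries the same NAD⁺
  affinity (K_m 0.05 mM). At low demand the single redox pool is necessarily
  highly reduced (OXPHOS is ADP-limited, so NAD⁺ falls until uptake matches
  demand); a shared gate makes all pathways throttle proportionally, which
  keeps the substrate shares of ATP production approximately load-invariant,
  the behavior the capacity readouts assume. PDH and TCA get a tighter NAD⁺
  affinity (0.005 mM) so pyruvate and acetyl-CoA do not pool at rest, and the
  acetoacetate step carries an explicit NAD gate (its chemistry has no
  dehydrogenase step, but its downstream oxidation does). The lumped TCA rate
  law deliberately omits ADP (kept in the stoichiometry): with the ADP term,
  acetyl-CoA producers (NAD-gated) and the consumer (NAD·ADP-gated) diverge
  at low load and no bounded steady state exists.
* **Insulin** multiplies the glucose-transport Vmax by
  `1 + a·I/(I + K_ins)` with a = 1.0, K_ins = 200 pM: the multiplier is 1.33
  at fasted insulin (100 pM) and 1.75 postprandially (600 pM), a ~1.3-fold
  stimulation. Catecholamines are accepted (0.75 nM in both built-in
  profiles) but act on no reaction — with a single fixed value their
  functional form is unidentifiable, so they are a documented no-op.

## Calibration

The network is a stand-in for a full molecularly-resolved cardiac model
whose parameter inventory is not reproduced here. Its Vmax values were
calibrated once, against three qualitative behaviors of a healthy fasted
heart, and then frozen in the shipped YAML:

1. fatty acids contribute ~80% of ATP production across the load ramp under
   the fasted profile (achieved: 80.0%);
2. the fatty-acid share falls to ~50% at maximal load under the postprandial
   profile (achieved: 48.5%), with glucose and lactate taking up the
   difference;
3. maximal fasted ATP production is 3–4× the resting demand
   (achieved: 3.73×). Resting demand, 0.5 mM ATP/min/g, is the model's
   calibration constant and the unit of the reported "load" axis.

Two structural choices mattered for share flatness: the glycolysis lump's
glucose affinity (K_m 0.5 mM) matches β-oxidation's saturation swing between
rest (intracellular substrates backed up toward plasma levels) and maximal
load (substrates drawn down), and the lactate-exchange equilibrium constant
is an effective lumped value (1.0) rather than the LDH mass-action constant,
because the single redox pool mixes mitochondrial and cytosolic NADH. The
model reproduces lactate *efflux* at low load and net lactate uptake at high
load as an emergent behavior.

## Steady states

`solve_steady_state` integrates the stiff ODE system (LSODA, rtol 1e-8) to a
60-min horizon (600 min on retry) and polishes with a Newton solve in
reduced coordinates — one member of each conserved pool is eliminated, so
pool totals are exact by construction. If Newton leaves the physical region
(which happens at boundary corners such as zero load, where NAD⁺ → 0 and
ADP → 0 exactly), a bounded trust-region least-squares solve with per-species
bounds [0, pool total] takes over. Convergence means max |dC/dt| ≤ 1e-6
mM/min over internal species; non-convergence is flagged, never silent.
Concentrations are clipped at zero inside rate laws; dips below −1e-9 during
integration are logged. `check_balance` recomputes S·v and pool drift from a
reported state and is used only as a test oracle.

## Capacity readouts

* **Substrate capacities**: geometric titration grid, 12 points from the
  base plasma level to 50×, (0→10 mM linear when the base is zero, e.g.
  postprandial ketones), ketones at fixed 2:1 bhb:acac, BCAAs at the base
  profile's proportions; ancillary ATP demand at 10× resting so uptake is
  never demand-limited; plateau detected at <0.1% relative gain. The
  capacity is the maximal net uptake flux of the titrated class. Because
  all substrates remain present, the respiratory chain and the shared NAD
  pool co-limit large capacities; halving one pathway's enzymes therefore
  scales its capacity slightly less than proportionally (the glycolysis
  test asserts a 0.40–0.68 ratio band rather than exactly 0.5).
* **ATP load ramp**: load starts at 10% of resting demand, multiplies by
  1.25 (≤60 steps), and stops at <0.1% relative production gain or
  non-convergence; a confirming solve at 20× the stopping load pins the
  plateau, which makes the reported capacity insensitive to the grid (vmax
  homogeneity holds to ~1e-6 relative). ATP/O₂ is taken at the plateau
  state. Substrate contributions are net uptake × stoichiometric yield;
  because the yield modes span the steady-flux space, contributions sum to
  total production exactly (lactate efflux appears as a negative
  contribution).
* **Individualized profiles** overlay measured per-animal plasma panels on
  the fasted defaults field-by-field (logged); triglycerides have no model
  substrate and are ignored.
* `k_m` of the demand law defaults to 0.5 mM, far below resting ATP (~7–8
  mM), so demand ≈ load until ATP collapses; raising it mainly shifts the
  load scale, not the plateau.

## Statistics

Fold changes are linear-scale ratios of group means; per-protein p-values
come from a two-sided Welch t-test on log2 intensities; volcano classes use
strict thresholds (down: FC < 0.5, up: FC > 2, both at p < 0.05) and raw
p-values by default (Benjamini–Hochberg behind a flag). Group comparisons
pass through a one-sample Kolmogorov–Smirnov gate on standardized values;
both groups normal → pooled t-test, otherwise the two-sample Mann–Whitney
rank-sum test (the unpaired reading of a signed-rank test, since no pairing
exists between animals). Marker regressions are per-protein OLS of a
pathway's capacity on protein abundance; pathway scores are intensity shares
of a protein set; the correlation ledger is pairwise-complete Pearson with a
significance mask at α = 0.05 and a signed −1/0/+1 export. Clustering is
average-linkage on Euclidean distances of z-scored features with
input-order tie-breaking; PCA runs on z-scored features with a deterministic
sign convention (largest-magnitude loading positive). Type-I error of the
gated test and of the ledger is calibrated to 0.05 ± 0.02 in 2000-replicate
null simulations.

## Synthetic cohorts

The generator emulates the three-group design: control (n=4), diet-stressed
(n=5), genetically obese (n=5); 2470 proteins, ~300 metabolic. Intensities
are `baseline × planted group fold × 2^N(0, 0.25)`. The diet plan plants a
0.5-fold on OXPHOS/TCA proteins and fills to 7.4% up / 34.6% down among
metabolic proteins (2.6%/9.4% among the rest); the obese plan plants 2-fold
fatty-acid handling, collagen and inflammation increases, 0.5-fold
lactate/ketone/BCAA machinery, filling to 10.7%/22.8% (5.9%/4.1% elsewhere).
Planted folds default to 0.5/2.0 — exactly on the volcano thresholds, so
threshold logic is exercised; recovery tests that score classification use a
stronger plan (0.25/4.0) so the planted class is unambiguous. Plasma panels
shift triglycerides and leucine/isoleucine up and β-hydroxybutyrate down in
the obese group only; heart mass falls in the diet group and rises ~1.4× in
the obese group; ejection fraction is a linear function of the latent OXPHOS
scale with an extra fibrosis penalty in the obese group plus noise — a toy
coupling for recovery tests, not a physiological claim. Everything is
reproducible from the seed.

What passing tests do and do not show: the generator draws log-normal,
comparably-scaled intensities with no batch effects, no missingness by
default, and exactly proportional enzyme–Vmax coupling, so recovery there
demonstrates the pipeline's correctness, not robustness to real-data
pathologies (normalization drift, isoenzyme switching, peptide-level
artifacts). The end-to-end OXPHOS-propagation check plants its fold with
measurement noise switched off, because it asserts a deterministic model
property (capacity halves within 5%; residual deviation ~1% from
substrate-level phosphorylation that does not scale with the respiratory
chain); identifiability under the default noise is asserted separately
(significant diet-group capacity reduction in ≥45/50 seeded cohorts).

## Problem sizes

Tests run on reduced cohorts (3–5 samples per group, 130 proteins) and the
shipped 14-reaction model; steady states take ~5–20 ms each, a full load
ramp ~0.2 s, and the complete suite about two minutes on one CPU. The
statistical calibration suites use 2000 null replicates and 50 seeded
cohorts as stated above.

## Known limitations

No glycogen/triacylglycerol store dynamics, no Ca²⁺/contraction coupling, no
oxygen-delivery limitation, no separate cytosolic/mitochondrial redox
states, no isoenzyme resolution in the enzyme→reaction mapping, and the
catecholamine input is inert. The shipped mapping is a curated
reduced-network mapping, not a reconstruction of any published assignment.
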