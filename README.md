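# myoflux

Proteome-constrained kinetic analysis of cardiac energy metabolism.

The failing heart remodels its fuel metabolism long before pump function
collapses, and quantitative proteomics can see that remodeling: the enzymes
of fatty-acid oxidation, glycolysis, ketolysis, BCAA catabolism and oxidative
phosphorylation are all measurable in a single LC–MS/MS run. `myoflux` turns
such protein abundance profiles into *functional* readouts. It ships a
calibrated reduced kinetic model of central cardiac energy metabolism,
rescales each reaction's maximal rate by a sample's enzyme abundances
relative to a control reference, and computes for every animal:

* **substrate-utilization capacities** — the maximal steady-state uptake flux
  of glucose, free fatty acids (NEFA), lactate, ketone bodies and
  branched-chain amino acids, obtained by titrating one substrate class to
  supraphysiological plasma levels while all others stay fixed;
* **ATP production capacity and ATP/O₂ ratio** — the plateau ATP output under
  a stepwise-increased hyperbolic demand
  `v_ATP = load · ATP / (ATP + K_m)`, evaluated under defined fasted,
  postprandial, or per-animal ("individualized") plasma profiles, with the
  ATP-equivalent contribution of each substrate resolved along the load ramp;
* the **downstream cohort statistics** used in differential proteomics:
  volcano classification (down if FC < 0.5, up if FC > 2, at p < 0.05),
  z-score hierarchical clustering and PCA, group tests with a
  Kolmogorov–Smirnov normality gate (Student t-test, rank-sum fallback),
  per-pathway marker regressions, collagen/inflammation pathway shares, and a
  significance-masked Pearson correlation ledger linking capacities, plasma
  metabolites and echocardiographic parameters.

A synthetic-cohort generator produces three-group mouse cohorts (control,
diet-stressed, genetically obese) with planted fold changes, shifted plasma
panels, group-specific heart masses and echo parameters coupled to the latent
metabolic state, so the whole pipeline is testable end-to-end with known
ground truth.

## The model in brief

The reduced network lumps each pathway segment into one reaction: glucose
transport (insulin-activated, `1 + I/(I + K_ins)`), glycolysis, lactate
exchange (MCT+LDH), fatty-acid transport/activation, β-oxidation, ketolysis,
BCAA oxidation, pyruvate dehydrogenase, the TCA cycle, a lumped respiratory
chain (single NADH pool, P/O = 2.5), and the ATP demand law. Plasma
substrates are clamped boundary species; ATP+ADP and NAD⁺+NADH are conserved
moiety pools. ATP yields per substrate are derived from the network's own
stoichiometry at build time (glucose 34, palmitate 103.5, lactate 16 ATP per
molecule). Per-sample instantiation sets

```
vmax_sample(r) = vmax_ref(r) · agg(E_sample(r)) / agg(E_ref(r))
```

with a geometric-mean aggregation over each reaction's protein set and a
conservative fallback to the reference when proteins are unmeasured.

## Worked example

```python
from myoflux import load_default_model, FASTED, POSTPRANDIAL
from myoflux.capacity import atp_load_scan

model = load_default_model()
fasted = atp_load_scan(model, FASTED)
post = atp_load_scan(model, POSTPRANDIAL)
print(f"fasted:  max ATP {fasted.max_atp:.3f} mM/min/g, "
      f"ATP/O2 {fasted.atp_o2_at_max:.2f}, "
      f"FA share (ramp mean) {fasted.mean_share('ffa'):.2f}")
print(f"postprandial: max ATP {post.max_atp:.3f} mM/min/g, "
      f"FA share at max load {post.share_at_max('ffa'):.2f}")
print(f"reserve: {fasted.max_atp / model.resting_demand:.2f}x resting demand")
```

prints

```
fasted:  max ATP 1.864 mM/min/g, ATP/O2 5.36, FA share (ramp mean) 0.80
postprandial: max ATP 1.355 mM/min/g, FA share at max load 0.48
reserve: 3.73x resting demand
```

i.e. the calibrated reference heart draws ~80% of its ATP from fatty acids
when fasted, shifts to roughly half fatty acids / half carbohydrate-derived
fuel after a meal, and can raise ATP output ~3.7-fold above resting demand
before saturating.

The command line mirrors the library:

```
myoflux simulate-data --preset tiny --seed 4 --outdir sim
myoflux run --matrix sim/abundance.tsv --metadata sim/metadata.tsv \
            --plasma sim/plasma.tsv --outdir results
myoflux atp-scan --profile fasted --out atp_scan.tsv
```

`run` writes per-sample capacity tables, volcano/marker/correlation TSVs, a
JSON summary and a manifest (config hash, seed, versions) that suffices to
reproduce every table bit-identically.

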