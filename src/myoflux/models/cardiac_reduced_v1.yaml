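# Calibrated reduced kinetic network of cardiac central energy metabolism.
#
# One lumped reaction per pathway segment: glucose transport, glycolysis,
# lactate exchange (MCT+LDH), fatty-acid transport+activation, beta-oxidation,
# ketolysis (bhb and acac steps), BCAA oxidation (val/leu/ile steps sharing
# one enzyme set), pyruvate dehydrogenase, TCA cycle, respiratory chain
# (OXPHOS, single reducing-equivalent pool at P/O 2.5), and a hyperbolic ATP
# demand.  Units: concentrations mM, fluxes mM/min per g wet tissue.
# The fatty-acid species is lumped palmitate (C16).  CO2 is an explicit
# boundary product so per-reaction carbon balance is checkable; O2 is a
# clamped boundary species (no transport limitation).
schema_version: 1
name: cardiac_reduced_v1
resting_demand: 0.5        # mM ATP/min/g, calibration constant for "load" units
demand_reaction: atp_demand

metabolites:
  # plasma (clamped boundary; conc0 = overnight-fasted profile)
  - {id: glc_p, name: plasma glucose,       compartment: plasma, conc0: 5.8,  carbons: 6}
  - {id: nefa,  name: plasma NEFA,          compartment: plasma, conc0: 0.5,  carbons: 16}
  - {id: lac,   name: plasma lactate,       compartment: plasma, conc0: 0.8,  carbons: 3}
  - {id: bhb,   name: beta-hydroxybutyrate, compartment: plasma, conc0: 0.08, carbons: 4}
  - {id: acac,  name: acetoacetate,         compartment: plasma, conc0: 0.04, carbons: 4}
  - {id: val,   name: valine,               compartment: plasma, conc0: 0.2,  carbons: 5}
  - {id: leu,   name: leucine,              compartment: plasma, conc0: 0.15, carbons: 6}
  - {id: ile,   name: isoleucine,           compartment: plasma, conc0: 0.06, carbons: 6}
  - {id: o2,    name: oxygen (clamped),     compartment: mitochondria, conc0: 1.0, boundary: true}
  - {id: co2,   name: carbon dioxide (sink), compartment: mitochondria, conc0: 0.0, boundary: true, carbons: 1}
  # internal
  - {id: glc_c, name: intracellular glucose, compartment: cytosol, conc0: 1.0, carbons: 6}
  - {id: fa_c,  name: activated fatty acid,  compartment: cytosol, conc0: 0.05, carbons: 16}
  - {id: pyr,   name: pyruvate,              compartment: cytosol, conc0: 0.1, carbons: 3}
  - {id: acoa,  name: acetyl-CoA,            compartment: mitochondria, conc0: 0.1, carbons: 2}
  - {id: nadh,  name: reducing equivalents (NADH), compartment: mitochondria, conc0: 0.3}
  - {id: nad,   name: NAD+,                  compartment: mitochondria, conc0: 0.7}
  - {id: atp,   name: ATP,                   compartment: cytosol, conc0: 7.0}
  - {id: adp,   name: ADP,                   compartment: cytosol, conc0: 1.0}

pools:
  - {name: adenine, members: [atp, adp], total: 8.0}
  - {name: nicotinamide, members: [nadh, nad], total: 1.0}

reactions:
  - id: glut
    pathway: glycolysis
    stoichiometry: {glc_p: -1, glc_c: 1}
    proteins: [Slc2a4, Slc2a1]
    law:
      form: facilitated-transport
      vmax: 0.017
      km: {glc_p: 8.0}
      modifiers:
        - {effector: insulin, type: activator, k: 200.0, a: 1.0}

  - id: glyc
    pathway: glycolysis
    stoichiometry: {glc_c: -1, nad: -2, adp: -2, pyr: 2, nadh: 2, atp: 2}
    proteins: [Hk2, Pfkm, Gapdh, Pkm]
    law:
      form: irreversible-MM
      vmax: 0.019
      km: {glc_c: 0.5, nad: 0.05}

  - id: lacx
    pathway: lactate-exchange
    stoichiometry: {lac: -1, nad: -1, pyr: 1, nadh: 1}
    proteins: [Slc16a1, Ldha, Ldhb]
    law:
      form: reversible-MM
      vmax: 0.02
      keq: 1.0
      km: {lac: 1.25, nad: 0.1, pyr: 0.2, nadh: 0.1}

  - id: fat
    pathway: fao
    stoichiometry: {nefa: -1, atp: -2, fa_c: 1, adp: 2}
    proteins: [Cd36, Acsl1]
    law:
      form: facilitated-transport
      vmax: 0.027
      km: {nefa: 0.25}

  - id: box
    pathway: fao
    stoichiometry: {fa_c: -1, nad: -7, acoa: 8, nadh: 7}
    proteins: [Cpt1b, Cpt2, Acadvl, Hadha, Hadhb]
    law:
      form: irreversible-MM
      vmax: 0.030
      km: {fa_c: 0.05, nad: 0.05}

  - id: ket_bhb
    pathway: ketolysis
    stoichiometry: {bhb: -1, nad: -1, atp: -1, acoa: 2, nadh: 1, adp: 1}
    proteins: [Bdh1, Oxct1, Acat1]
    law:
      form: irreversible-MM
      vmax: 0.008
      km: {bhb: 0.15, nad: 0.05}

  - id: ket_acac
    pathway: ketolysis
    stoichiometry: {acac: -1, atp: -1, acoa: 2, adp: 1}
    proteins: [Oxct1, Acat1]
    law:
      form: irreversible-MM
      vmax: 0.005
      km: {acac: 0.1}
      modifiers:
        - {effector: nad, type: gate, k: 0.05}
        - {effector: acoa, type: inhibitor, k: 1.0}

  - id: bcaa_val
    pathway: bcaa
    stoichiometry: {val: -1, nad: -2, acoa: 2, co2: 1, nadh: 2}
    proteins: [Bcat2, Bckdha, Bckdhb, Dbt]
    law:
      form: irreversible-MM
      vmax: 0.0025
      km: {val: 0.3, nad: 0.05}

  - id: bcaa_leu
    pathway: bcaa
    stoichiometry: {leu: -1, nad: -2, acoa: 3, nadh: 2}
    proteins: [Bcat2, Bckdha, Bckdhb, Dbt]
    law:
      form: irreversible-MM
      vmax: 0.0025
      km: {leu: 0.25, nad: 0.05}

  - id: bcaa_ile
    pathway: bcaa
    stoichiometry: {ile: -1, nad: -2, acoa: 2, co2: 2, nadh: 2}
    proteins: [Bcat2, Bckdha, Bckdhb, Dbt]
    law:
      form: irreversible-MM
      vmax: 0.0025
      km: {ile: 0.15, nad: 0.05}

  - id: pdh
    pathway: tca
    stoichiometry: {pyr: -1, nad: -1, acoa: 1, co2: 1, nadh: 1}
    proteins: [Pdha1, Pdhb, Dlat]
    law:
      form: irreversible-MM
      vmax: 0.06
      km: {pyr: 0.05, nad: 0.005}
      modifiers:
        - {effector: acoa, type: inhibitor, k: 1.0}

  - id: tca
    pathway: tca
    stoichiometry: {acoa: -1, nad: -4, adp: -1, co2: 2, nadh: 4, atp: 1}
    proteins: [Cs, Idh3a, Ogdh, Sdha, Mdh2, Fh1, Sucla2]
    law:
      form: irreversible-MM
      vmax: 0.30
      km: {acoa: 0.05, nad: 0.005}

  - id: oxphos
    pathway: oxphos
    stoichiometry: {nadh: -1, adp: -2.5, o2: -0.5, nad: 1, atp: 2.5}
    proteins: [Ndufs1, Ndufv1, Sdhb, Uqcrc1, Uqcrc2, Cox4i1, Atp5f1a, Atp5f1b, Slc25a4]
    law:
      form: irreversible-MM
      vmax: 0.75
      km: {nadh: 0.05, adp: 0.05, o2: 0.01}

  - id: atp_demand
    pathway: atp-demand
    stoichiometry: {atp: -1, adp: 1}
    proteins: []
    law:
      form: load-hyperbolic
      vmax: 0.5
      km: {atp: 0.5}

substrate_classes:
  glucose:  {species: [glc_p], reactions: [glut]}
  ffa:      {species: [nefa],  reactions: [fat]}
  lactate:  {species: [lac],   reactions: [lacx]}
  ketones:  {species: [bhb, acac], reactions: [ket_bhb, ket_acac]}
  bcaa:     {species: [val, leu, ile], reactions: [bcaa_val, bcaa_leu, bcaa_ile]}
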