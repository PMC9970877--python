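{
 "name": "reduced thermodynamic yeast network (synthetic fixture)",
 "description": "Illustrative ~20-reaction lumped network for exercising phase-dependent, dissipation-capped FBA; stoichiometries are synthetic, not a published reconstruction.",
 "M_biomass": 0.966,
 "g_lim": 12.3,
 "c_model": {
  "protein": 0.45,
  "lipid": 0.08,
  "polysaccharide": 0.25,
  "RNA": 0.14,
  "DNA": 0.01,
  "storage": 0.07
 },
 "component_species": {
  "protein": "prot",
  "lipid": "lip",
  "polysaccharide": "ps",
  "RNA": "rna",
  "DNA": "dna",
  "storage": "sto"
 },
 "metabolites": {
  "glc_e": {
   "mass": 180.156,
   "dfG": -915.9,
   "exchanged": true
  },
  "glc_c": {
   "mass": 180.156,
   "dfG": null,
   "exchanged": false
  },
  "o2_e": {
   "mass": 31.998,
   "dfG": 16.4,
   "exchanged": true
  },
  "o2_c": {
   "mass": 31.998,
   "dfG": null,
   "exchanged": false
  },
  "co2_e": {
   "mass": 44.009,
   "dfG": -386.0,
   "exchanged": true
  },
  "co2_c": {
   "mass": 44.009,
   "dfG": null,
   "exchanged": false
  },
  "etoh_e": {
   "mass": 46.069,
   "dfG": -181.6,
   "exchanged": true
  },
  "etoh_c": {
   "mass": 46.069,
   "dfG": null,
   "exchanged": false
  },
  "h2o_e": {
   "mass": 18.015,
   "dfG": -157.6,
   "exchanged": true
  },
  "h2o_c": {
   "mass": 18.015,
   "dfG": null,
   "exchanged": false
  },
  "pyr_c": {
   "mass": 88.062,
   "dfG": null,
   "exchanged": false
  },
  "atp": {
   "mass": 507.18,
   "dfG": null,
   "exchanged": false
  },
  "adp": {
   "mass": 427.201,
   "dfG": null,
   "exchanged": false
  },
  "pi": {
   "mass": 79.979,
   "dfG": null,
   "exchanged": false
  },
  "nad": {
   "mass": 663.425,
   "dfG": null,
   "exchanged": false
  },
  "nadh": {
   "mass": 665.4409999999999,
   "dfG": null,
   "exchanged": false
  },
  "prot": {
   "mass": 434.7,
   "dfG": null,
   "exchanged": false
  },
  "lip": {
   "mass": 77.28,
   "dfG": null,
   "exchanged": false
  },
  "ps": {
   "mass": 241.5,
   "dfG": null,
   "exchanged": false
  },
  "rna": {
   "mass": 135.24,
   "dfG": null,
   "exchanged": false
  },
  "dna": {
   "mass": 9.66,
   "dfG": null,
   "exchanged": false
  },
  "sto": {
   "mass": 67.62,
   "dfG": null,
   "exchanged": false
  },
  "biomass": {
   "mass": 966.0,
   "dfG": -100.0,
   "exchanged": true
  }
 },
 "reactions": [
  {
   "id": "EX_glc",
   "stoich": {
    "glc_e": -1
   },
   "lb": -10.0,
   "ub": 0.0,
   "kind": "exchange"
  },
  {
   "id": "EX_o2",
   "stoich": {
    "o2_e": -1
   },
   "lb": -1000.0,
   "ub": 0.0,
   "kind": "exchange"
  },
  {
   "id": "EX_co2",
   "stoich": {
    "co2_e": -1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "exchange"
  },
  {
   "id": "EX_etoh",
   "stoich": {
    "etoh_e": -1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "exchange"
  },
  {
   "id": "EX_h2o",
   "stoich": {
    "h2o_e": -1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "exchange"
  },
  {
   "id": "EX_biomass",
   "stoich": {
    "biomass": -1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "exchange"
  },
  {
   "id": "GLCt",
   "stoich": {
    "glc_e": -1,
    "glc_c": 1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "O2t",
   "stoich": {
    "o2_e": -1,
    "o2_c": 1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "CO2t",
   "stoich": {
    "co2_c": -1,
    "co2_e": 1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "ETOHt",
   "stoich": {
    "etoh_c": -1,
    "etoh_e": 1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "H2Ot",
   "stoich": {
    "h2o_c": -1,
    "h2o_e": 1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "GLYC",
   "stoich": {
    "glc_c": -1,
    "adp": -2,
    "pi": -2,
    "nad": -2,
    "pyr_c": 2,
    "atp": 2,
    "nadh": 2
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "FERM",
   "stoich": {
    "pyr_c": -1,
    "nadh": -1,
    "etoh_c": 1,
    "co2_c": 1,
    "nad": 1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "RESP",
   "stoich": {
    "pyr_c": -1,
    "o2_c": -2.5,
    "adp": -12.5,
    "pi": -12.5,
    "co2_c": 3,
    "h2o_c": 2,
    "atp": 12.5
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "NADHox",
   "stoich": {
    "nadh": -1,
    "o2_c": -0.5,
    "adp": -1.5,
    "pi": -1.5,
    "nad": 1,
    "h2o_c": 1,
    "atp": 1.5
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "ATPm",
   "stoich": {
    "atp": -1,
    "adp": 1,
    "pi": 1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "internal"
  },
  {
   "id": "PROT_syn",
   "stoich": {
    "glc_c": -3.0,
    "atp": -30.0,
    "adp": 30.0,
    "pi": 30.0,
    "prot": 1.0,
    "co2_c": 1.5,
    "h2o_c": 2.3186511240632837,
    "nadh": -1.0,
    "nad": 1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "synthesis"
  },
  {
   "id": "LIP_syn",
   "stoich": {
    "glc_c": -1.0,
    "atp": -10.0,
    "adp": 10.0,
    "pi": 10.0,
    "lip": 1.0,
    "co2_c": 2.0,
    "h2o_c": 1.048570635581456,
    "nadh": -2.0,
    "nad": 2.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "synthesis"
  },
  {
   "id": "PS_syn",
   "stoich": {
    "glc_c": -1.5,
    "atp": -5.0,
    "adp": 5.0,
    "pi": 5.0,
    "ps": 1.0,
    "co2_c": 0.2,
    "h2o_c": 1.1064224257563162
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "synthesis"
  },
  {
   "id": "RNA_syn",
   "stoich": {
    "glc_c": -1.0,
    "atp": -8.0,
    "adp": 8.0,
    "pi": 8.0,
    "rna": 1.0,
    "co2_c": 0.5,
    "h2o_c": 1.2718012767138493
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "synthesis"
  },
  {
   "id": "DNA_syn",
   "stoich": {
    "glc_c": -0.1,
    "atp": -1.0,
    "adp": 1.0,
    "pi": 1.0,
    "dna": 1.0,
    "co2_c": 0.1,
    "h2o_c": 0.2251179572578408,
    "nadh": -0.05,
    "nad": 0.05
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "synthesis"
  },
  {
   "id": "STO_syn",
   "stoich": {
    "glc_c": -0.4,
    "atp": -2.0,
    "adp": 2.0,
    "pi": 2.0,
    "sto": 1.0,
    "co2_c": 0.02,
    "h2o_c": 0.19773633083541528
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "synthesis"
  },
  {
   "id": "BIOMASS",
   "stoich": {
    "prot": -1,
    "lip": -1,
    "ps": -1,
    "rna": -1,
    "dna": -1,
    "sto": -1,
    "atp": -25,
    "adp": 25,
    "pi": 25,
    "biomass": 1
   },
   "lb": 0.0,
   "ub": 1000.0,
   "kind": "biomass"
  }
 ]
}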