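{
 "metabolites": [
  {"id": "glucose", "name": "imported glucose", "role": "source"},
  {"id": "G6P", "name": "glucose-6-phosphate", "role": "internal"},
  {"id": "F6P", "name": "fructose-6-phosphate", "role": "internal"},
  {"id": "UDP_GlcNAc", "name": "UDP-N-acetylglucosamine", "role": "internal"},
  {"id": "G3P", "name": "glyceraldehyde-3-phosphate", "role": "internal"},
  {"id": "PG3", "name": "3-phosphoglycerate", "role": "internal"},
  {"id": "serine", "name": "serine", "role": "internal"},
  {"id": "ceramide", "name": "ceramide", "role": "internal"},
  {"id": "pyruvate", "name": "pyruvate", "role": "internal"},
  {"id": "acetyl_CoA", "name": "acetyl-CoA", "role": "internal"},
  {"id": "citrate", "name": "citrate", "role": "internal"},
  {"id": "nucleotide_synthesis__sink", "name": "nucleotide pool", "role": "sink"},
  {"id": "glycosylation__sink", "name": "glycan pool", "role": "sink"},
  {"id": "sialic_acid__sink", "name": "sialic acid pool", "role": "sink"},
  {"id": "lipid_synthesis__sink", "name": "lipid pool", "role": "sink"},
  {"id": "ganglioside_synthesis__sink", "name": "ganglioside pool", "role": "sink"},
  {"id": "serine_synthesis__sink", "name": "free serine pool", "role": "sink"},
  {"id": "lactate_production__sink", "name": "lactate pool", "role": "sink"},
  {"id": "tca_entry__sink", "name": "TCA intermediate pool", "role": "sink"}
 ],
 "reactions": [
  {"id": "R_uptake_HK", "stoichiometry": {"glucose": -1.0, "G6P": 1.0},
   "ec": ["2.7.1.1"], "genes": ["SLC2A1", "SLC2A3", "SLC5A1", "SLC5A2", "SLC2A10", "HK1", "HK2"],
   "proton_coefficient": 1.0, "pathway": "internal"},
  {"id": "R_GPI", "stoichiometry": {"G6P": -1.0, "F6P": 1.0},
   "ec": ["5.3.1.9"], "genes": ["GPI"], "proton_coefficient": 0.0, "pathway": "internal"},
  {"id": "R_GFPT", "stoichiometry": {"F6P": -1.0, "UDP_GlcNAc": 1.0},
   "ec": ["2.6.1.16"], "genes": ["GFPT1", "GNPNAT1", "PGM3", "UAP1"],
   "proton_coefficient": 1.0, "pathway": "internal"},
  {"id": "R_PFK_ALDO", "stoichiometry": {"F6P": -1.0, "G3P": 1.0},
   "ec": ["2.7.1.11", "4.1.2.13"], "genes": ["PFKM", "PFKL", "ALDOA", "TPI1"],
   "proton_coefficient": 1.0, "pathway": "internal"},
  {"id": "R_GAPDH_PGK", "stoichiometry": {"G3P": -1.0, "PG3": 1.0},
   "ec": ["1.2.1.12", "2.7.2.3"], "genes": ["GAPDH", "PGK1"],
   "proton_coefficient": 1.0, "pathway": "internal"},
  {"id": "R_PHGDH", "stoichiometry": {"PG3": -1.0, "serine": 1.0},
   "ec": ["1.1.1.95"], "genes": ["PHGDH", "PSAT1", "PSPH"],
   "proton_coefficient": 1.0, "pathway": "internal"},
  {"id": "R_ENO_PKM", "stoichiometry": {"PG3": -1.0, "pyruvate": 1.0},
   "ec": ["4.2.1.11", "2.7.1.40"], "genes": ["ENO1", "PKM"],
   "proton_coefficient": 1.0, "pathway": "internal"},
  {"id": "R_SPT", "stoichiometry": {"serine": -1.0, "ceramide": 1.0},
   "ec": ["2.3.1.50"], "genes": ["SPTLC1", "SPTLC2", "CERS2"],
   "proton_coefficient": 0.0, "pathway": "internal"},
  {"id": "R_PDH", "stoichiometry": {"pyruvate": -1.0, "acetyl_CoA": 1.0},
   "ec": ["1.2.4.1"], "genes": ["PDHA1", "DLAT"],
   "proton_coefficient": -1.0, "pathway": "internal"},
  {"id": "R_CS", "stoichiometry": {"acetyl_CoA": -1.0, "citrate": 1.0},
   "ec": ["2.3.3.1"], "genes": ["CS"], "proton_coefficient": 1.0, "pathway": "internal"},
  {"id": "R_sink_nucleotide", "stoichiometry": {"G6P": -1.0, "nucleotide_synthesis__sink": 1.0},
   "ec": ["1.1.1.49"], "genes": ["G6PD", "PGD", "PRPS1"],
   "proton_coefficient": 8.0, "pathway": "nucleotide_synthesis"},
  {"id": "R_sink_glycosylation", "stoichiometry": {"UDP_GlcNAc": -1.0, "glycosylation__sink": 1.0},
   "ec": ["2.4.1.255"], "genes": ["OGT", "MGAT1"],
   "proton_coefficient": 0.0, "pathway": "glycosylation"},
  {"id": "R_sink_sialic", "stoichiometry": {"UDP_GlcNAc": -1.0, "sialic_acid__sink": 1.0},
   "ec": ["2.7.7.43"], "genes": ["GNE", "CMAS", "ST3GAL1"],
   "proton_coefficient": 1.0, "pathway": "sialic_acid"},
  {"id": "R_sink_lipid", "stoichiometry": {"citrate": -1.0, "lipid_synthesis__sink": 1.0},
   "ec": ["2.3.1.85"], "genes": ["ACLY", "ACACA", "FASN", "SCD"],
   "proton_coefficient": -2.0, "pathway": "lipid_synthesis"},
  {"id": "R_sink_ganglioside", "stoichiometry": {"ceramide": -1.0, "ganglioside_synthesis__sink": 1.0},
   "ec": ["2.4.99.9"], "genes": ["ST3GAL5", "B4GALNT1"],
   "proton_coefficient": 1.0, "pathway": "ganglioside_synthesis"},
  {"id": "R_sink_serine", "stoichiometry": {"serine": -1.0, "serine_synthesis__sink": 1.0},
   "ec": ["2.1.2.1"], "genes": ["SLC1A4", "SHMT1"],
   "proton_coefficient": 0.0, "pathway": "serine_synthesis"},
  {"id": "R_sink_lactate", "stoichiometry": {"pyruvate": -1.0, "lactate_production__sink": 1.0},
   "ec": ["1.1.1.27"], "genes": ["LDHA", "SLC16A1"],
   "proton_coefficient": 1.0, "pathway": "lactate_production"},
  {"id": "R_sink_tca", "stoichiometry": {"citrate": -1.0, "tca_entry__sink": 1.0},
   "ec": ["4.2.1.3"], "genes": ["ACO2", "IDH2"],
   "proton_coefficient": 1.0, "pathway": "tca_entry"}
 ],
 "sink_pathways": ["nucleotide_synthesis", "lactate_production", "lipid_synthesis",
                   "glycosylation", "sialic_acid", "ganglioside_synthesis",
                   "serine_synthesis", "tca_entry"]
}
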