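{
  "description": "Observed recurrent NDD CNV counts from a published population-based screen of 12,252 genotyped mother-father-child trios. Used as the counts fixture for the statistics module and as default event rates for the cohort simulator.",
  "n_trios": 12252,
  "mother_carriers": 43,
  "father_carriers": 44,
  "maternal_transmitted": 24,
  "paternal_transmitted": 15,
  "rows": [
    {"region": "1q21.1", "svclass": "del", "n": 6, "de_novo": 2, "inherited_maternal": 3, "inherited_paternal": 1, "de_novo_maternal": 0, "de_novo_paternal": 2, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "1q21.1", "svclass": "dup", "n": 4, "de_novo": 0, "inherited_maternal": 4, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "3q29", "svclass": "del", "n": 1, "de_novo": 1, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 1, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "3q29", "svclass": "dup", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "7q11.23", "svclass": "del", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "7q11.23", "svclass": "dup", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "15q11.2-13.1", "svclass": "del", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "15q11.2-13.1", "svclass": "dup", "n": 3, "de_novo": 2, "inherited_maternal": 1, "inherited_paternal": 0, "de_novo_maternal": 2, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 1},
    {"region": "15q13.3", "svclass": "del", "n": 5, "de_novo": 1, "inherited_maternal": 3, "inherited_paternal": 1, "de_novo_maternal": 0, "de_novo_paternal": 1, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "15q13.3", "svclass": "dup", "n": 6, "de_novo": 1, "inherited_maternal": 2, "inherited_paternal": 3, "de_novo_maternal": 0, "de_novo_paternal": 1, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "16p11.2_distal", "svclass": "del", "n": 3, "de_novo": 1, "inherited_maternal": 1, "inherited_paternal": 1, "de_novo_maternal": 1, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "16p11.2_distal", "svclass": "dup", "n": 8, "de_novo": 2, "inherited_maternal": 1, "inherited_paternal": 5, "de_novo_maternal": 1, "de_novo_paternal": 0, "de_novo_unresolved": 1, "mosaic": 0},
    {"region": "16p11.2_proximal", "svclass": "del", "n": 6, "de_novo": 4, "inherited_maternal": 2, "inherited_paternal": 0, "de_novo_maternal": 3, "de_novo_paternal": 1, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "16p11.2_proximal", "svclass": "dup", "n": 5, "de_novo": 0, "inherited_maternal": 4, "inherited_paternal": 1, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "17p13.3", "svclass": "del", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "17p13.3", "svclass": "dup", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "17p11.2", "svclass": "del", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "17p11.2", "svclass": "dup", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "17q12", "svclass": "del", "n": 3, "de_novo": 3, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 1, "de_novo_paternal": 2, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "17q12", "svclass": "dup", "n": 2, "de_novo": 0, "inherited_maternal": 1, "inherited_paternal": 1, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "17q21.31", "svclass": "del", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "17q21.31", "svclass": "dup", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "22q11.2", "svclass": "del", "n": 1, "de_novo": 1, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 1, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "22q11.2", "svclass": "dup", "n": 6, "de_novo": 2, "inherited_maternal": 2, "inherited_paternal": 2, "de_novo_maternal": 1, "de_novo_paternal": 1, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "22q11.2_distal", "svclass": "del", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0},
    {"region": "22q11.2_distal", "svclass": "dup", "n": 0, "de_novo": 0, "inherited_maternal": 0, "inherited_paternal": 0, "de_novo_maternal": 0, "de_novo_paternal": 0, "de_novo_unresolved": 0, "mosaic": 0}
  ]
}
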