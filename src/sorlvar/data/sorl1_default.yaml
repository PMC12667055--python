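# Default SORL1 (SORLA) domain architecture and variant-priority rules.
#
# Segment residue ranges are as published for the canonical 2,214-residue
# protein (transcript T260197).  Per-repeat boundaries are NOT published at
# residue resolution: the starts below are derived from anchored
# residue/repeat-position facts (see `anchors`) and otherwise interpolated.
# Boundaries without an anchor are approximate and user-editable; treat this
# config as a starting point, not a complete structural annotation.
#
# Known tension kept visible: the 3Fn1 start implied by the anchored
# tyrosine-corner residues (p.L1617V at position 77 => start 1541) precedes
# the stated 3Fn-cassette start (1551); repeats may overhang their parent
# segment by <= 10 residues, which triggers a warning, not an error.

name: sorl1_default
protein_length: 2214

segments:
  - {name: signal_peptide, start: 1, end: 28}
  - {name: pro, start: 29, end: 81}
  - {name: VPS10p, start: 82, end: 617}
  - {name: "10CC", start: 618, end: 753}
  - {name: YWTD, start: 754, end: 1013}
  - {name: EGF, start: 1014, end: 1074}
  - {name: CR_cluster, start: 1075, end: 1550}
  - {name: 3Fn_cassette, start: 1551, end: 2121}
  - {name: TM_tail, start: 2122, end: 2214}

repeats:
  # VPS10p beta-propeller ligand-release loops (approximate extents).
  - {class: L1_loop, index: 1, start: 380, end: 410}
  - {class: L2_loop, index: 1, start: 460, end: 490}
  # YWTD beta-propeller blades; blade 5 anchored by p.R953H at position 38.
  - {class: YWTD_blade, index: 1, start: 754, end: 794}
  - {class: YWTD_blade, index: 2, start: 795, end: 835}
  - {class: YWTD_blade, index: 3, start: 836, end: 875}
  - {class: YWTD_blade, index: 4, start: 876, end: 915}
  - {class: YWTD_blade, index: 5, start: 916, end: 958}
  - {class: YWTD_blade, index: 6, start: 959, end: 1013}
  # Eleven CR (complement-type repeat) domains, one per exon 23-33.
  # CR1/CR5/CR7 anchored so the published calcium-cage variants sit at
  # within-repeat position 37.
  - {class: CR, index: 1, start: 1072, end: 1114}
  - {class: CR, index: 2, start: 1115, end: 1151}
  - {class: CR, index: 3, start: 1152, end: 1188}
  - {class: CR, index: 4, start: 1189, end: 1224}
  - {class: CR, index: 5, start: 1225, end: 1266}
  - {class: CR, index: 6, start: 1267, end: 1308}
  - {class: CR, index: 7, start: 1309, end: 1350}
  - {class: CR, index: 8, start: 1351, end: 1400}
  - {class: CR, index: 9, start: 1401, end: 1450}
  - {class: CR, index: 10, start: 1451, end: 1500}
  - {class: CR, index: 11, start: 1501, end: 1540}
  # Six 3Fn (fibronectin type III) domains; 3Fn1-3 and 3Fn6 anchored by
  # published within-repeat positions of the tyrosine corner, the
  # glycine-96 variant and the common D2065V (3Fn6 position 47).
  - {class: 3Fn, index: 1, start: 1541, end: 1636}
  - {class: 3Fn, index: 2, start: 1637, end: 1733}
  - {class: 3Fn, index: 3, start: 1734, end: 1833}
  - {class: 3Fn, index: 4, start: 1834, end: 1925}
  - {class: 3Fn, index: 5, start: 1926, end: 2018}
  - {class: 3Fn, index: 6, start: 2019, end: 2121}

anchors:
  - {residue: 1108, repeat_class: CR, repeat_position: 37}   # D1108N calcium cage, CR1
  - {residue: 1261, repeat_class: CR, repeat_position: 37}   # D1261G calcium cage, CR5
  - {residue: 1345, repeat_class: CR, repeat_position: 37}   # D1345N calcium cage, CR7
  - {residue: 1617, repeat_class: 3Fn, repeat_position: 77}  # L1617V tyrosine corner
  - {residue: 1619, repeat_class: 3Fn, repeat_position: 79}  # P1619Q tyrosine corner
  - {residue: 1732, repeat_class: 3Fn, repeat_position: 96}  # G1732A conserved glycine
  - {residue: 1816, repeat_class: 3Fn, repeat_position: 83}  # Y1816C tyrosine corner
  - {residue: 2065, repeat_class: 3Fn, repeat_position: 47}  # D2065V, 3Fn6
  - {residue: 953, repeat_class: YWTD_blade, repeat_position: 38}  # R953H, blade 5
  - {residue: 391, repeat_class: L1_loop, repeat_position: 12}     # Y391C in loop L1
  - {residue: 480, repeat_class: L2_loop, repeat_position: 21}     # R480C in loop L2

rules:
  revel_threshold: 0.5
  maf_threshold: 0.0005
  splice_review_threshold: 0.2
  dosage_threshold: 0.5
  ptv_exon_rescue: [48]
  high_rules:
    - {label: CR_calcium_cage, scope: "repeat:CR", trigger: fixed_position,
       positions: [37, 41, 47, 48]}
    - {label: CR_asx_turn, scope: "repeat:CR", trigger: fixed_position,
       positions: [44]}
    - {label: CR_cysteine, scope: "segment:CR_cluster",
       trigger: cysteine_gain_or_loss}
    - {label: EGF_cysteine, scope: "segment:EGF",
       trigger: cysteine_gain_or_loss}
    - {label: 10CC_cysteine, scope: "segment:10CC",
       trigger: cysteine_gain_or_loss}
    - {label: L1_cysteine, scope: "repeat:L1_loop",
       trigger: cysteine_gain_or_loss}
    - {label: L2_cysteine, scope: "repeat:L2_loop",
       trigger: cysteine_gain_or_loss}
    - {label: YWTD_motif, scope: "repeat:YWTD_blade", trigger: fixed_position,
       positions: [17, 18, 19, 20]}
    - {label: YWTD_conserved, scope: "repeat:YWTD_blade",
       trigger: fixed_position, positions: [29, 35]}
    - {label: YWTD_partly_conserved, scope: "repeat:YWTD_blade",
       trigger: fixed_position, positions: [9, 38]}
    - {label: 3Fn_glycine, scope: "repeat:3Fn", trigger: fixed_position,
       positions: [36, 96]}
    - {label: 3Fn_conserved, scope: "repeat:3Fn", trigger: fixed_position,
       positions: [25, 41, 77, 83]}
    - {label: 3Fn_tyrosine_corner_proline, scope: "repeat:3Fn",
       trigger: fixed_position, positions: [79]}
    - {label: VPS10p_revel, scope: "segment:VPS10p", trigger: revel_at_least}
    - {label: 10CC_revel, scope: "segment:10CC", trigger: revel_at_least}
  moderate_rules:
    - {label: 3Fn_proline, scope: "repeat:3Fn", trigger: fixed_position,
       positions: [6, 7]}
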