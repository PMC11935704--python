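# Default synthetic-cohort specification.
#
# Block sizes, subgroup mixes, log-normal age/weight at first procedure
# (median and IQR, days / kg), prematurity and comorbidity rates are the
# published whole-cohort registry summaries for the nine sentinel CHDs;
# the survival and reintervention entries are the published 1/5/10-year
# point estimates, from which piecewise-constant death hazards and
# reintervention intensities are derived in closed form at load time.
# Pathway stage attainment probabilities and inter-stage gaps are
# realistic defaults (documented in docs/methods.md) and fully overridable.
#
# gap_days entries are [median days, log-scale sigma], measured from the
# previous pathway procedure.

study_years: 22.0
born_outside_window_rate: 0.0
nonresident_rate: 0.0
non_nhs_rate: 0.0
seed: 0

blocks:
  - diagnosis: HLHS
    n_patients: 1296
    prematurity_rate: 0.042
    comorbidity_rate: 0.140
    sv_fraction: 1.0
    reint_surgical_fraction: 0.6
    survival: [0.638, 0.591, 0.576]
    reintervention: [0.374, 0.487, 0.545]
    subgroups:
      hlhs: {n: 1296, age_days: [4, 3, 6], weight_kg: [3.1, 2.8, 3.5]}
    pathway_sv:
      - {role: prepathway, concept: balloon_atrial_septostomy, prob: 0.15}
      - {role: stage1, concepts: {norwood: 0.85, hybrid_stage1: 0.15}, prob: 0.97, gap_days: [4, 0.5]}
      - {role: stage2, concept: glenn, prob: 0.80, gap_days: [130, 0.35]}
      - {role: stage3, concept: fontan, prob: 0.93, gap_days: [1000, 0.35]}

  - diagnosis: FUH
    n_patients: 997
    prematurity_rate: 0.078
    comorbidity_rate: 0.145
    sv_fraction: 1.0
    reint_surgical_fraction: 0.6
    survival: [0.904, 0.878, 0.867]
    reintervention: [0.279, 0.460, 0.573]
    subgroups:
      double_inlet_ventricle: {n: 443, age_days: [15, 6, 70], weight_kg: [3.5, 3.0, 4.4]}
      tricuspid_atresia: {n: 554, age_days: [22, 6, 68], weight_kg: [3.3, 2.9, 4.2]}
    pathway_sv:
      - {role: prepathway, concept: balloon_atrial_septostomy, prob: 0.08}
      - {role: stage1, concepts: {pa_band: 0.45, systemic_pulmonary_shunt: 0.45, norwood: 0.10}, prob: 0.90, gap_days: [5, 0.5]}
      - {role: stage2, concept: glenn, prob: 0.90, gap_days: [150, 0.40]}
      - {role: stage3, concept: fontan, prob: 0.85, gap_days: [1100, 0.35]}

  - diagnosis: TGA
    n_patients: 3838
    prematurity_rate: 0.041
    comorbidity_rate: 0.052
    sv_fraction: 0.024
    reint_surgical_fraction: 0.5
    survival: [0.944, 0.935, 0.931]
    reintervention: [0.132, 0.184, 0.209]
    subgroups:
      complex_with_PS: {n: 447, age_days: [13, 3, 55], weight_kg: [3.5, 3.0, 4.1]}
      complex_without_PS: {n: 1283, age_days: [8, 2, 17], weight_kg: [3.3, 3.0, 3.7]}
      intact_septum: {n: 2108, age_days: [2, 1, 8], weight_kg: [3.3, 3.0, 3.7]}
    pathway_bv:
      - {role: prepathway, concept: balloon_atrial_septostomy, prob: 0.65}
      - role: repair
        concepts: {arterial_switch: 1.0}
        concepts_by_subgroup: {complex_with_PS: rastelli}
        prob: 0.98
        gap_days: [7, 0.6]
    pathway_sv:
      - {role: stage1, concept: pa_band, prob: 0.95}
      - {role: stage2, concept: glenn, prob: 0.85, gap_days: [150, 0.40]}
      - {role: stage3, concept: fontan, prob: 0.80, gap_days: [1100, 0.35]}

  - diagnosis: PA
    n_patients: 1643
    prematurity_rate: 0.107
    comorbidity_rate: 0.281
    sv_fraction: 0.102
    reint_surgical_fraction: 0.5
    survival: [0.865, 0.821, 0.810]
    reintervention: [0.360, 0.593, 0.668]
    subgroups:
      with_VSD: {n: 1131, age_days: [34, 8, 148], weight_kg: [3.4, 2.8, 5.7]}
      intact_septum: {n: 512, age_days: [5, 3, 10], weight_kg: [3.2, 2.8, 3.6]}
    pathway_bv:
      - {role: stage1, concept: systemic_pulmonary_shunt, prob: 0.55}
      - {role: repair, concepts: {pa_repair: 0.7, pulmonary_valvotomy: 0.3}, prob: 0.92, gap_days: [360, 0.6]}
    pathway_sv:
      - {role: stage1, concept: systemic_pulmonary_shunt, prob: 0.95}
      - {role: stage2, concept: glenn, prob: 0.85, gap_days: [160, 0.40]}
      - {role: stage3, concept: fontan, prob: 0.80, gap_days: [1100, 0.35]}

  - diagnosis: AVSD
    n_patients: 4358
    prematurity_rate: 0.075
    comorbidity_rate: 0.538
    sv_fraction: 0.031
    reint_surgical_fraction: 0.5
    survival: [0.923, 0.892, 0.885]
    reintervention: [0.095, 0.176, 0.216]
    subgroups:
      tetralogy_AVSD: {n: 215, age_days: [158, 60, 342], weight_kg: [5.5, 3.7, 8.0]}
      unbalanced: {n: 291, age_days: [40, 9, 140], weight_kg: [3.5, 2.9, 5.0]}
      partial: {n: 1108, age_days: [770, 306, 1402], weight_kg: [11.4, 7.3, 15.3]}
      complete: {n: 2744, age_days: [133, 90, 192], weight_kg: [4.8, 4.0, 6.0]}
    pathway_bv:
      - {role: stage1, concept: pa_band, prob: 0.06}
      - {role: repair, concept: avsd_repair, prob: 0.97, gap_days: [150, 0.5]}
    pathway_sv:
      - {role: stage1, concept: pa_band, prob: 0.90}
      - {role: stage2, concept: glenn, prob: 0.85, gap_days: [160, 0.40]}
      - {role: stage3, concept: fontan, prob: 0.75, gap_days: [1150, 0.35]}

  - diagnosis: TOF
    n_patients: 4643
    prematurity_rate: 0.088
    comorbidity_rate: 0.223
    sv_fraction: 0.0
    reint_surgical_fraction: 0.45
    survival: [0.973, 0.957, 0.951]
    reintervention: [0.088, 0.211, 0.266]
    subgroups:
      absent_pulm_valve: {n: 185, age_days: [146, 45, 370], weight_kg: [5.6, 3.7, 8.4]}
      DORV: {n: 546, age_days: [156, 56, 279], weight_kg: [5.8, 3.6, 7.7]}
      standard: {n: 3912, age_days: [198, 119, 306], weight_kg: [6.8, 5.3, 8.3]}
    pathway_bv:
      - {role: stage1, concept: systemic_pulmonary_shunt, prob: 0.17}
      - {role: repair, concept: tof_repair, prob: 0.984, gap_days: [180, 0.5]}

  - diagnosis: AS
    n_patients: 1631
    prematurity_rate: 0.057
    comorbidity_rate: 0.086
    sv_fraction: 0.0
    reint_surgical_fraction: 0.35
    survival: [0.955, 0.947, 0.944]
    reintervention: [0.134, 0.219, 0.312]
    subgroups:
      multilevel_LHO: {n: 434, age_days: [45, 7, 649], weight_kg: [4.1, 3.2, 10.6]}
      isolated: {n: 1197, age_days: [141, 29, 1706], weight_kg: [6.7, 3.9, 17.7]}
    pathway_bv:
      - {role: repair, concepts: {balloon_aortic_valvuloplasty: 0.6, aortic_valvotomy: 0.4}, prob: 0.98}

  - diagnosis: COARCT
    n_patients: 4338
    prematurity_rate: 0.073
    comorbidity_rate: 0.120
    sv_fraction: 0.0
    reint_surgical_fraction: 0.3
    survival: [0.976, 0.969, 0.967]
    reintervention: [0.118, 0.168, 0.198]
    subgroups:
      with_VSD: {n: 1333, age_days: [13, 7, 40], weight_kg: [3.3, 2.8, 3.8]}
      isolated: {n: 3005, age_days: [34, 9, 255], weight_kg: [3.9, 3.1, 8.0]}
    pathway_bv:
      - {role: repair, concept: coarct_repair, prob: 0.99}

  - diagnosis: VSD
    n_patients: 6575
    prematurity_rate: 0.100
    comorbidity_rate: 0.238
    sv_fraction: 0.0
    reint_surgical_fraction: 0.5
    survival: [0.984, 0.973, 0.969]
    reintervention: [0.028, 0.053, 0.061]
    subgroups:
      multiple: {n: 426, age_days: [105, 66, 178], weight_kg: [4.3, 3.4, 5.5]}
      isolated: {n: 6149, age_days: [158, 97, 335], weight_kg: [5.4, 4.2, 7.9]}
    pathway_bv:
      - {role: stage1, concept: pa_band, prob: 0.02}
      - {role: repair, concept: vsd_closure, prob: 0.985, gap_days: [120, 0.5]}
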