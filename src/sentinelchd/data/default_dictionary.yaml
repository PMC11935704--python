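# Default concept dictionary.
#
# SYNTHETIC stand-in for the licensed production code lists: the raw codes
# below are invented six-digit identifiers in the style of hierarchical
# clinical coding schemes, not real IPCCC codes.  A production mapping plugs
# in through this same format.
#
# codes:               raw code -> concept (several codes may share a concept)
# diagnosis_markers:   concept -> sentinel diagnosis it marks
# subgroup_rules:      per diagnosis, ordered modifier rules + residual default
# roles:               per diagnosis, procedure concept -> pathway role

version: "1.0.0"

codes:
  # --- diagnosis concepts ---
  "100101": hlhs
  "100102": hlhs                       # synonym (aortic+mitral atresia form)
  "100201": double_inlet_ventricle
  "100301": tricuspid_atresia
  "100401": tga
  "100402": tga
  "100411": tga_complex
  "100421": pulmonary_stenosis
  "100501": pulmonary_atresia
  "100601": avsd
  "100611": unbalanced_avsd
  "100621": partial_avsd
  "100701": tof
  "100711": dorv
  "100721": absent_pulmonary_valve
  "100801": aortic_stenosis
  "100811": multilevel_lho
  "100901": coarctation
  "101001": vsd
  "101002": vsd
  "101011": multiple_vsd
  "101101": patent_ductus              # non-sentinel
  "101201": atrial_septal_defect      # non-sentinel
  "109101": prematurity
  "109201": congenital_comorbidity
  "109202": trisomy_21
  "109203": digeorge_syndrome
  # --- procedure concepts ---
  "200101": balloon_atrial_septostomy
  "200201": norwood
  "200202": hybrid_stage1
  "200301": systemic_pulmonary_shunt
  "200401": pa_band
  "200501": glenn
  "200601": fontan
  "200701": arterial_switch
  "200801": rastelli
  "200901": tof_repair
  "201001": pa_repair
  "201101": pulmonary_valvotomy
  "201201": avsd_repair
  "201301": aortic_valvotomy
  "201401": balloon_aortic_valvuloplasty
  "201501": coarct_repair
  "201601": vsd_closure
  "201701": heart_transplant
  "202101": pacemaker_insertion
  "202201": balloon_dilation
  "202301": stent_implantation
  "202401": device_closure
  "202501": ep_ablation
  "202901": diagnostic_catheter
  "202902": ep_study
  "203001": pda_ligation

diagnosis_markers:
  hlhs: HLHS
  double_inlet_ventricle: FUH
  tricuspid_atresia: FUH
  tga: TGA
  pulmonary_atresia: PA
  avsd: AVSD
  tof: TOF
  aortic_stenosis: AS
  coarctation: COARCT
  vsd: VSD

subgroup_rules:
  HLHS:
    default: hlhs
  FUH:
    rules:
      - {when_all: [double_inlet_ventricle], subgroup: double_inlet_ventricle}
      - {when_all: [tricuspid_atresia], subgroup: tricuspid_atresia}
    default: tricuspid_atresia
  TGA:
    rules:
      - {when_all: [tga_complex, pulmonary_stenosis], subgroup: complex_with_PS}
      - {when_all: [tga_complex], subgroup: complex_without_PS}
    default: intact_septum
  PA:
    rules:
      - {when_all: [vsd], subgroup: with_VSD}
    default: intact_septum
  AVSD:
    rules:
      - {when_all: [tof], subgroup: tetralogy_AVSD}
      - {when_all: [unbalanced_avsd], subgroup: unbalanced}
      - {when_all: [partial_avsd], subgroup: partial}
    default: complete
  TOF:
    rules:
      - {when_all: [absent_pulmonary_valve], subgroup: absent_pulm_valve}
      - {when_all: [dorv], subgroup: DORV}
    default: standard
  AS:
    rules:
      - {when_all: [multilevel_lho], subgroup: multilevel_LHO}
    default: isolated
  COARCT:
    rules:
      - {when_all: [vsd], subgroup: with_VSD}
    default: isolated
  VSD:
    rules:
      - {when_all: [multiple_vsd], subgroup: multiple}
    default: isolated

roles:
  HLHS:
    balloon_atrial_septostomy: prepathway
    norwood: stage1
    hybrid_stage1: stage1
    systemic_pulmonary_shunt: stage1
    glenn: stage2
    fontan: stage3
    heart_transplant: transplant
  FUH:
    balloon_atrial_septostomy: prepathway
    norwood: stage1
    pa_band: stage1
    systemic_pulmonary_shunt: stage1
    glenn: stage2
    fontan: stage3
    heart_transplant: transplant
  TGA:
    balloon_atrial_septostomy: prepathway
    pa_band: stage1
    systemic_pulmonary_shunt: stage1
    glenn: stage2
    fontan: stage3
    arterial_switch: repair
    rastelli: repair
    heart_transplant: transplant
  PA:
    balloon_atrial_septostomy: prepathway
    systemic_pulmonary_shunt: stage1
    pa_band: stage1
    glenn: stage2
    fontan: stage3
    pa_repair: repair
    pulmonary_valvotomy: repair
    heart_transplant: transplant
  AVSD:
    pa_band: stage1
    systemic_pulmonary_shunt: stage1
    glenn: stage2
    fontan: stage3
    avsd_repair: repair
    heart_transplant: transplant
  TOF:
    systemic_pulmonary_shunt: stage1
    glenn: stage2
    fontan: stage3
    tof_repair: repair
    heart_transplant: transplant
  AS:
    glenn: stage2
    fontan: stage3
    aortic_valvotomy: repair
    balloon_aortic_valvuloplasty: repair
    heart_transplant: transplant
  COARCT:
    pa_band: stage1
    glenn: stage2
    fontan: stage3
    coarct_repair: repair
    heart_transplant: transplant
  VSD:
    pa_band: stage1
    glenn: stage2
    fontan: stage3
    vsd_closure: repair
    device_closure: repair
    heart_transplant: transplant

prematurity_concepts: [prematurity]
comorbidity_concepts: [congenital_comorbidity, trisomy_21, digeorge_syndrome]
diagnostic_concepts: [diagnostic_catheter, ep_study]
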