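# Default data-quality ruleset (versioned; replaceable via the same format).
# Rules fire on a patient's pathway assignment; flagged patients are excluded
# from reintervention metrics but retained for survival metrics by default.
version: "1.0.0"
rules:
  - id: q1
    description: stage 2 palliation present without a stage 1 procedure
  - id: q2
    description: Fontan-type completion present without a stage 2 procedure
  - id: q3
    description: staged palliation coded for an exclusively biventricular diagnosis
    params:
      biventricular_only: [TOF, VSD, COARCT, AS]
  - id: q4
    description: both reparative surgery and stage 2/3 palliation present
  - id: q5
    description: first procedure age implausible for the diagnosis
    params:
      max_first_procedure_age_days:
        HLHS: 365
  - id: q6
    description: a reintervention duplicates a filled pathway slot on the same day
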