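# Default per-bone skeletal mass fractions used as BSI weights.
# Approximate values derived from ICRP reference-skeleton mass data,
# collapsed onto the 12 bone labels this package segments (left/right
# limbs pooled; distal limbs, which carry metastases rarely, are not
# segmented and their mass is excluded from the table). Every BSI report
# records which table produced it; supply your own YAML to override.
provenance: "approximate ICRP reference-skeleton mass fractions (package default)"
weights:
  skull: 0.118
  cervical_vertebrae: 0.022
  thoracic_vertebrae: 0.055
  lumbar_vertebrae: 0.048
  sacrum: 0.028
  pelvis: 0.110
  rib: 0.086
  scapula: 0.036
  humerus: 0.048
  femur: 0.125
  sternum: 0.012
  clavicle: 0.010
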