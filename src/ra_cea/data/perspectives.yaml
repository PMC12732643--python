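# Cost-category fractions per payer perspective. The patient out-of-pocket and
# medical-insurance fractions are complementary and sum to the full
# healthcare-system cost. Fractions are configuration.
healthcare_system:
  default_fraction: 1.0
patient_oop:
  default_fraction: 0.5
  item_fractions:
    drug: 0.30
    ae_drug: 0.50
    outpatient: 0.50
    diagnostics: 0.40
    administration: 0.50
    inpatient: 0.30
    palliative: 0.45
insurance:
  default_fraction: 0.5
  item_fractions:
    drug: 0.70
    ae_drug: 0.50
    outpatient: 0.50
    diagnostics: 0.60
    administration: 0.50
    inpatient: 0.70
    palliative: 0.55
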