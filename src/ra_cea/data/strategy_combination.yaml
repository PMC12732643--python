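# Combination-therapy scenario pathway (editorial first-line efficacy).
name: "rhTNFR:Fc + MTX first"
lines:
  - name: "rhTNFR:Fc + MTX"
    response: "p rhTNFR:Fc + MTX ACR20 response rate"
    withdrawal: "p rhTNFR:Fc + MTX withdrawal rate"
    utility_responder: "u rhTNFR:Fc + MTX"
    utility_nonresponder: "u base"
    costs:
      - {item: "c rhTNFR:Fc", units_per_cycle: 52}
      - {item: "c MTX", units_per_cycle: 156}
      - {item: "c Injection fee, subcutaneous", units_per_cycle: 52}
      - {item: "c Registration"}
      - {item: "c Complete blood count"}
      - {item: "c Biochemical tests"}
      - {item: "c Lipid profile tests"}
      - {item: "c Ultrasound scans"}
      - {item: "c CT"}
      - {item: "c Bone density tests"}
      - {item: "c Hospitalization"}
      - {item: "c Nursing"}
      - {item: "c Loratadine"}
      - {item: "c Buprofen Sustained-Release Capsules"}
      - {item: "c Amoxicillin"}
      - {item: "c Omeprazole enteric-coated capsules"}
      - {item: "c Polyene Phosphatidylcholine"}
  - name: "Adalimumab + MTX"
    response: "p Adalimumab + MTX ACR20 response rate"
    withdrawal: "p Adalimumab + MTX withdrawal rate"
    utility_responder: "u Adalimumab (rhTNFR:Fc group)"
    utility_nonresponder: "u base"
    costs:
      - {item: "c Adalimumab", units_per_cycle: 13}
      - {item: "c MTX", units_per_cycle: 156}
      - {item: "c Injection fee, subcutaneous", units_per_cycle: 13}
      - {item: "c Registration"}
      - {item: "c Complete blood count"}
      - {item: "c Biochemical tests"}
      - {item: "c Lipid profile tests"}
      - {item: "c Ultrasound scans"}
      - {item: "c CT"}
      - {item: "c Bone density tests"}
      - {item: "c Hospitalization"}
      - {item: "c Nursing"}
      - {item: "c Loratadine"}
      - {item: "c Buprofen Sustained-Release Capsules"}
      - {item: "c Amoxicillin"}
      - {item: "c Omeprazole enteric-coated capsules"}
      - {item: "c Polyene Phosphatidylcholine"}
  - name: "Tocilizumab + MTX"
    response: "p Tocilizumab + MTX ACR20 response rate"
    withdrawal: "p Tocilizumab + MTX withdrawal rate"
    utility_responder: "u Tocilizumab (rhTNFR:Fc group)"
    utility_nonresponder: "u base"
    costs:
      - {item: "c Tocilizumab", units_per_cycle: 16.9}
      - {item: "c MTX", units_per_cycle: 156}
      - {item: "c Injection fee, intravenous", units_per_cycle: 6.5}
      - {item: "c Registration"}
      - {item: "c Complete blood count"}
      - {item: "c Biochemical tests"}
      - {item: "c Lipid profile tests"}
      - {item: "c Ultrasound scans"}
      - {item: "c CT"}
      - {item: "c Bone density tests"}
      - {item: "c Hospitalization"}
      - {item: "c Nursing"}
      - {item: "c Loratadine"}
      - {item: "c Buprofen Sustained-Release Capsules"}
      - {item: "c Amoxicillin"}
      - {item: "c Omeprazole enteric-coated capsules"}
      - {item: "c Polyene Phosphatidylcholine"}
  - name: "Tofacitinib"
    response: "p Tofacitinib ACR20 response rate"
    withdrawal: "p Tofacitinib withdrawal rate"
    utility_responder: "u Tofacitinib (rhTNFR:Fc group)"
    utility_nonresponder: "u base"
    costs:
      - {item: "c Tofacitinib", units_per_cycle: 365}
      - {item: "c Registration"}
      - {item: "c Complete blood count"}
      - {item: "c Biochemical tests"}
      - {item: "c Lipid profile tests"}
      - {item: "c Ultrasound scans"}
      - {item: "c CT"}
      - {item: "c Bone density tests"}
      - {item: "c Hospitalization"}
      - {item: "c Nursing"}
      - {item: "c Loratadine"}
      - {item: "c Buprofen Sustained-Release Capsules"}
      - {item: "c Amoxicillin"}
      - {item: "c Omeprazole enteric-coated capsules"}
      - {item: "c Polyene Phosphatidylcholine"}
palliative:
  name: "Palliative care"
  utility: "u Palliative care"
  costs:
    - {item: "c Palliative care"}
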