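# Model parameter file: one record per tabulated input.
# Rates carry the observation window of their source trial (months); they are
# converted to 6-month cycle probabilities under a constant-hazard assumption.
# Bounds are the one-way sensitivity ranges and set PSA dispersion.
# Dosing/usage quantities (units_per_cycle) and the HAQ mapping are calibrated
# free inputs: see docs/methods.md.
schema_version: 1

settings:
  start_age: 49.0
  male_fraction: 0.15
  discount_rate_annual: 0.05
  cycle_length_years: 0.5
  max_age: 100.0
  haq_floor: 1.5
  haq_max: 3.0
  mortality_haq_hr: 1.281804
  haq_map_intercept: 1.148970
  haq_map_slope: -0.318592

scalars:
  - {name: "Age (years)", base: 49.0, lower: 49.0, upper: 49.0}
  - {name: "Male (%)", base: 0.15, lower: 0.12, upper: 0.18}
  - {name: "p Discount", base: 0.05, lower: 0.00, upper: 0.08}

probabilities:
  - {name: "p rhTNFR:Fc ACR20 response rate", base: 0.7542, lower: 0.6730, upper: 0.8273, window_months: 6}
  - {name: "p rhTNFR:Fc withdrawal rate", base: 0.1356, lower: 0.0802, upper: 0.2026, window_months: 6}
  - {name: "p MTX ACR20 response rate", base: 0.7000, lower: 0.4802, upper: 0.6383, window_months: 6,
     note: "base outside printed bounds; kept as printed, bounds set dispersion only"}
  - {name: "p MTX withdrawal rate", base: 0.0917, lower: 0.0471, upper: 0.1491, window_months: 6}
  - {name: "p Adalimumab + MTX ACR20 response rate", base: 0.6700, lower: 0.6035, upper: 0.7333, window_months: 6}
  - {name: "p Adalimumab + MTX withdrawal rate", base: 0.0800, lower: 0.0467, upper: 0.1213, window_months: 24,
     note: "window editorial: withdrawal observed over a long-term extension"}
  - {name: "p Tocilizumab + MTX ACR20 response rate", base: 0.5000, lower: 0.4310, upper: 0.5690, window_months: 6}
  - {name: "p Tocilizumab + MTX withdrawal rate", base: 0.0800, lower: 0.0467, upper: 0.1213, window_months: 24,
     note: "window editorial"}
  - {name: "p Tofacitinib ACR20 response rate", base: 0.5200, lower: 0.4508, upper: 0.5888, window_months: 6}
  - {name: "p Tofacitinib withdrawal rate", base: 0.1100, lower: 0.0706, upper: 0.1568, window_months: 24,
     note: "window editorial"}
  # combination-therapy scenario efficacy (proxy source; editorial values)
  - {name: "p rhTNFR:Fc + MTX ACR20 response rate", base: 0.8500, lower: 0.7800, upper: 0.9100, window_months: 6,
     note: "editorial: combination efficacy proxied from originator-plus-MTX trials"}
  - {name: "p rhTNFR:Fc + MTX withdrawal rate", base: 0.1000, lower: 0.0600, upper: 0.1500, window_months: 6,
     note: "editorial"}

costs:
  # drugs (units_per_cycle set per line in the strategy files)
  - {name: "c rhTNFR:Fc", unit_price: 126.60, lower: 101.28, upper: 151.92, category: drug}
  - {name: "c MTX", unit_price: 1.94, lower: 1.55, upper: 2.32, category: drug}
  - {name: "c Adalimumab", unit_price: 998.00, lower: 798.40, upper: 1197.60, category: drug}
  - {name: "c Tocilizumab", unit_price: 1506.38, lower: 1205.10, upper: 1807.66, category: drug}
  - {name: "c Tofacitinib", unit_price: 1.30, lower: 1.04, upper: 1.56, category: drug}
  # adverse-event management medication (usage per cycle from expert schedule)
  - {name: "c Loratadine", unit_price: 2.3137, lower: 1.85, upper: 2.78, units_per_cycle: 30, category: ae_drug}
  - {name: "c Buprofen Sustained-Release Capsules", unit_price: 0.2246, lower: 0.18, upper: 0.27, units_per_cycle: 60, category: ae_drug}
  - {name: "c Amoxicillin", unit_price: 0.1449, lower: 0.12, upper: 0.17, units_per_cycle: 40, category: ae_drug}
  - {name: "c Omeprazole enteric-coated capsules", unit_price: 0.4201, lower: 0.34, upper: 0.50, units_per_cycle: 30, category: ae_drug}
  - {name: "c Polyene Phosphatidylcholine", unit_price: 1.29, lower: 1.03, upper: 1.55, units_per_cycle: 60, category: ae_drug}
  # outpatient services and monitoring
  - {name: "c Registration", unit_price: 14.0, lower: 11.20, upper: 16.80, units_per_cycle: 3, category: outpatient}
  - {name: "c Complete blood count", unit_price: 54.0, lower: 43.20, upper: 64.80, units_per_cycle: 2, category: diagnostics}
  - {name: "c Lipid profile tests", unit_price: 36.0, lower: 28.80, upper: 43.20, units_per_cycle: 1, category: diagnostics}
  - {name: "c Biochemical tests", unit_price: 64.0, lower: 51.20, upper: 76.80, units_per_cycle: 2, category: diagnostics}
  - {name: "c Ultrasound scans", unit_price: 105.0, lower: 84.00, upper: 126.00, units_per_cycle: 0.5, category: diagnostics}
  - {name: "c CT", unit_price: 265.0, lower: 212.00, upper: 318.00, units_per_cycle: 0.25, category: diagnostics}
  - {name: "c Bone density tests", unit_price: 40.0, lower: 32.00, upper: 48.00, units_per_cycle: 0.25, category: diagnostics}
  # administration
  - {name: "c Injection fee, subcutaneous", unit_price: 3.5, lower: 2.80, upper: 4.20, category: administration}
  - {name: "c Injection fee, intravenous", unit_price: 5.0, lower: 4.00, upper: 6.00, category: administration}
  # inpatient (days per cycle; calibrated)
  - {name: "c Hospitalization", unit_price: 34.0, lower: 27.20, upper: 40.80, units_per_cycle: 39.40, category: inpatient,
     note: "bed-days per cycle; calibrated usage schedule"}
  - {name: "c Nursing", unit_price: 12.5, lower: 10.00, upper: 15.00, units_per_cycle: 945.60, category: inpatient,
     note: "hourly nursing units (24 per bed-day); calibrated usage schedule"}
  # palliative care: CNY per year, accrued half per 6-month cycle
  - {name: "c Palliative care", unit_price: 41971.0, lower: 37017.00, upper: 47046.00, units_per_cycle: 0.5, category: palliative}

utilities:
  - {name: "u base", base: 0.193193, lower: 0.15, upper: 0.23}
  - {name: "u rhTNFR:Fc", base: 0.514056, lower: 0.41, upper: 0.62}
  - {name: "u MTX", base: 0.37967, lower: 0.30, upper: 0.46}
  - {name: "u Adalimumab (rhTNFR:Fc group)", base: 0.737562, lower: 0.59, upper: 0.89}
  - {name: "u Adalimumab (MTX group)", base: 0.64043, lower: 0.51, upper: 0.77}
  - {name: "u Tocilizumab (rhTNFR:Fc group)", base: 0.737562, lower: 0.59, upper: 0.89}
  - {name: "u Tocilizumab (MTX group)", base: 0.64043, lower: 0.51, upper: 0.77}
  - {name: "u Tofacitinib (rhTNFR:Fc group)", base: 0.737562, lower: 0.59, upper: 0.89}
  - {name: "u Tofacitinib (MTX group)", base: 0.64043, lower: 0.51, upper: 0.77}
  - {name: "u Palliative care", base: 0.193193, lower: 0.15, upper: 0.23}
  - {name: "u rhTNFR:Fc + MTX", base: 0.55, lower: 0.44, upper: 0.66,
     note: "editorial: combination-scenario utility"}

# Patient out-of-pocket share per cost category; the insurance perspective is
# the complement. Fractions are configuration (reimbursement rules unprinted).
reimbursement:
  patient_oop:
    drug: 0.30
    ae_drug: 0.50
    outpatient: 0.50
    diagnostics: 0.40
    administration: 0.50
    inpatient: 0.30
    palliative: 0.45
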