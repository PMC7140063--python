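# Chemotherapy regimens used in the human-to-zebrafish dose-equivalence
# safety study: drug names and human clinical doses (mg per m^2 of body
# surface area).  The index drug is the component whose concentration
# labels the safety experiments of that regimen.
regimens:
  - name: GEM
    index_drug: Gemcitabine
    drugs:
      - {name: Gemcitabine, clinical_dose_mg_per_m2: 1000}
  - name: GEMOX
    index_drug: Gemcitabine
    drugs:
      - {name: Gemcitabine, clinical_dose_mg_per_m2: 1000}
      - {name: Oxaliplatin, clinical_dose_mg_per_m2: 100}
  - name: GEM/nab-P
    index_drug: Gemcitabine
    drugs:
      - {name: Gemcitabine, clinical_dose_mg_per_m2: 1000}
      - {name: nab-Paclitaxel, clinical_dose_mg_per_m2: 125}
  - name: GEMCIS
    index_drug: Gemcitabine
    drugs:
      - {name: Gemcitabine, clinical_dose_mg_per_m2: 1000}
      - {name: Cisplatin, clinical_dose_mg_per_m2: 25}
  - name: 5-FU
    index_drug: 5-Fluorouracil
    drugs:
      - {name: 5-Fluorouracil, clinical_dose_mg_per_m2: 3200}
  - name: FOLFOX
    index_drug: 5-Fluorouracil
    drugs:
      - {name: 5-Fluorouracil, clinical_dose_mg_per_m2: 2800}
      - {name: Lederfolin, clinical_dose_mg_per_m2: 200}
      - {name: Oxaliplatin, clinical_dose_mg_per_m2: 85}
  - name: FOLFIRI
    index_drug: 5-Fluorouracil
    drugs:
      - {name: 5-Fluorouracil, clinical_dose_mg_per_m2: 2800}
      - {name: Lederfolin, clinical_dose_mg_per_m2: 200}
      - {name: Irinotecan, clinical_dose_mg_per_m2: 180}
  - name: FOLFOXIRI
    index_drug: 5-Fluorouracil
    drugs:
      - {name: 5-Fluorouracil, clinical_dose_mg_per_m2: 3200}
      - {name: Lederfolin, clinical_dose_mg_per_m2: 200}
      - {name: Irinotecan, clinical_dose_mg_per_m2: 165}
      - {name: Oxaliplatin, clinical_dose_mg_per_m2: 85}
  - name: FLOT
    index_drug: 5-Fluorouracil
    drugs:
      - {name: 5-Fluorouracil, clinical_dose_mg_per_m2: 2600}
      - {name: Lederfolin, clinical_dose_mg_per_m2: 200}
      - {name: Oxaliplatin, clinical_dose_mg_per_m2: 85}
      - {name: Docetaxel, clinical_dose_mg_per_m2: 50}
  - name: ECF
    index_drug: 5-Fluorouracil
    drugs:
      - {name: 5-Fluorouracil, clinical_dose_mg_per_m2: 2800}
      - {name: Cisplatin, clinical_dose_mg_per_m2: 60}
      - {name: Epirubicin, clinical_dose_mg_per_m2: 50}
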