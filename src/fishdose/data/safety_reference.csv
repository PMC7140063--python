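regimen,drug,clinical_dose_mg_per_m2,epc_mg_ml,ic50_mg_ml,ld25_mg_ml,epc_ic50,epc_ld25
GEM,Gemcitabine,1000,0.34,0.1,0.076,3.35,4.41
GEMOX,Gemcitabine,1000,0.34,0.23,0.16,1.50,2.13
GEMOX,Oxaliplatin,100,0.034,0.023,0.016,,
GEM/nab-P,Gemcitabine,1000,0.34,0.11,0.089,3.03,3.77
GEM/nab-P,nab-Paclitaxel,125,0.04,0.014,0.011,,
GEMCIS,Gemcitabine,1000,0.34,0.19,0.1,1.75,3.35
GEMCIS,Cisplatin,25,0.01,0.0048,0.0025,,
5-FU,5-Fluorouracil,3200,1.08,6.66,7.56,0.16,0.14
FOLFOX,5-Fluorouracil,2800,0.94,6.55,6.29,0.14,0.15
FOLFOX,Lederfolin,200,0.07,0.47,0.45,,
FOLFOX,Oxaliplatin,85,0.03,0.2,0.19,,
FOLFIRI,5-Fluorouracil,2800,0.94,0.15,0.19,6.21,5.03
FOLFIRI,Lederfolin,200,0.07,0.011,0.013,,
FOLFIRI,Irinotecan,180,0.06,0.01,0.012,,
FOLFOXIRI,5-Fluorouracil,3200,1.08,0.09,0.22,11.99,4.83
FOLFOXIRI,Lederfolin,200,0.07,0.0056,0.014,,
FOLFOXIRI,Oxaliplatin,85,0.03,0.0024,0.0059,,
FOLFOXIRI,Irinotecan,165,0.06,0.0046,0.012,,
FLOT,5-Fluorouracil,2600,0.88,0.28,0.27,3.08,3.23
FLOT,Lederfolin,200,0.07,0.022,0.02,,
FLOT,Oxaliplatin,85,0.03,0.0093,0.0089,,
FLOT,Docetaxel,50,0.02,0.0055,0.0052,,
ECF,5-Fluorouracil,2800,0.94,3.29,2.54,0.29,0.37
ECF,Cisplatin,60,0.02,0.07,0.054,,
ECF,Epirubicin,50,0.02,0.059,0.045,,
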