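{
  "denosumab": {
    "synonyms": ["DENOSUMAB", "Xgeva", "Ranmark", "Prolia"],
    "approved_indications": [
      "osteoporosis",
      "postmenopausal osteoporosis",
      "osteoporosis postmenopausal",
      "glucocorticoid-induced osteoporosis",
      "bone loss",
      "bone metastases",
      "giant cell tumour of bone",
      "hypercalcaemia of malignancy"
    ],
    "labeled_aes": [
      "osteonecrosis of jaw",
      "hypocalcaemia",
      "back pain",
      "bone pain",
      "musculoskeletal pain",
      "arthralgia",
      "pain in extremity",
      "dermatitis",
      "infection",
      "dyspnoea",
      "atypical femur fracture"
    ]
  },
  "zoledronic acid": {
    "synonyms": ["ZOLEDRONIC ACID", "ZOLEDRONATE", "ACLASTA", "RECLAST", "ZOMETA"],
    "approved_indications": [
      "osteoporosis",
      "postmenopausal osteoporosis",
      "osteoporosis postmenopausal",
      "glucocorticoid-induced osteoporosis",
      "paget's disease",
      "bone metastases",
      "multiple myeloma",
      "hypercalcaemia of malignancy"
    ],
    "labeled_aes": [
      "osteonecrosis of jaw",
      "hypocalcaemia",
      "pyrexia",
      "arthralgia",
      "myalgia",
      "bone pain",
      "renal impairment",
      "influenza like illness",
      "nausea",
      "anaemia"
    ]
  }
}
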