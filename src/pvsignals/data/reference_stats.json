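{
  "description": "Published top-10 disproportionality rows for two antiresorptive drugs, used by the self-consistency verifier: for each row, the PRR implied by (DE, D, ROR) and the CI lower bound of the table reconstructed from (DE, D, ROR, chi2) must match the printed values.",
  "drug_totals": {"denosumab": 117857, "zoledronic acid": 36878},
  "rows": [
    {"drug": "denosumab", "event": "death", "DE": 16013, "ror": 3.478, "ci_low": 3.42, "prr": 3.142, "chi2": 23699.174},
    {"drug": "denosumab", "event": "osteonecrosis of jaw", "DE": 6043, "ror": 53.025, "ci_low": 51.377, "prr": 50.358, "chi2": 193469.11},
    {"drug": "denosumab", "event": "back pain", "DE": 2793, "ror": 2.432, "ci_low": 2.342, "prr": 2.398, "chi2": 2244.037},
    {"drug": "denosumab", "event": "tooth disorder", "DE": 1929, "ror": 16.18, "ci_low": 15.414, "prr": 15.931, "chi2": 23239.1},
    {"drug": "denosumab", "event": "bone pain", "DE": 1878, "ror": 6.523, "ci_low": 6.223, "prr": 6.435, "chi2": 8106.468},
    {"drug": "denosumab", "event": "hypocalcaemia", "DE": 1805, "ror": 23.173, "ci_low": 22.009, "prr": 22.834, "chi2": 30578.129},
    {"drug": "denosumab", "event": "spinal fracture", "DE": 1369, "ror": 15.963, "ci_low": 15.073, "prr": 15.79, "chi2": 16337.329},
    {"drug": "denosumab", "event": "pain in jaw", "DE": 1314, "ror": 9.335, "ci_low": 8.819, "prr": 9.242, "chi2": 8831.068},
    {"drug": "denosumab", "event": "fracture", "DE": 894, "ror": 6.768, "ci_low": 6.323, "prr": 6.725, "chi2": 4076.903},
    {"drug": "denosumab", "event": "tooth extraction", "DE": 815, "ror": 11.487, "ci_low": 10.681, "prr": 11.415, "chi2": 6932.845},
    {"drug": "zoledronic acid", "event": "osteonecrosis", "DE": 6980, "ror": 104.866, "ci_low": 101.892, "prr": 85.207, "chi2": 458676.62},
    {"drug": "zoledronic acid", "event": "death", "DE": 5283, "ror": 3.645, "ci_low": 3.539, "prr": 3.266, "chi2": 8597.053},
    {"drug": "zoledronic acid", "event": "pain", "DE": 4177, "ror": 3.963, "ci_low": 3.836, "prr": 3.627, "chi2": 8110.249},
    {"drug": "zoledronic acid", "event": "osteonecrosis of jaw", "DE": 3696, "ror": 91.744, "ci_low": 88.342, "prr": 82.649, "chi2": 236587.42},
    {"drug": "zoledronic acid", "event": "tooth extraction", "DE": 2321, "ror": 142.143, "ci_low": 135.258, "prr": 133.26, "chi2": 214317.12},
    {"drug": "zoledronic acid", "event": "bone disorder", "DE": 2129, "ror": 68.221, "ci_low": 65.038, "prr": 64.34, "chi2": 110354.49},
    {"drug": "zoledronic acid", "event": "pyrexia", "DE": 1957, "ror": 3.932, "ci_low": 3.756, "prr": 3.777, "chi2": 4002.168},
    {"drug": "zoledronic acid", "event": "arthralgia", "DE": 1895, "ror": 3.364, "ci_low": 3.211, "prr": 3.242, "chi2": 2953.963},
    {"drug": "zoledronic acid", "event": "pain in jaw", "DE": 1792, "ror": 44.097, "ci_low": 41.93, "prr": 42.002, "chi2": 63354.395},
    {"drug": "zoledronic acid", "event": "fall", "DE": 1543, "ror": 3.039, "ci_low": 2.887, "prr": 2.953, "chi2": 2001.728}
  ]
}
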