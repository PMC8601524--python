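{
  "name": "CTCAE v5.0 haematology laboratory grading",
  "haemoglobin_gdl_per_mmoll": 1.6113,
  "parameters": {
    "haemoglobin": {
      "canonical_unit": "g/dL",
      "lln": {"male": 13.696, "female": 12.085},
      "grade_upper_bounds": [10.0, 8.0],
      "max_grade": 3,
      "note": "Anemia grade 4 is a clinical (life-threatening) criterion; value-based grading caps at 3. LLN defaults are 8.5 (male) / 7.5 (female) mmol/L converted at 1.6113 g/dL per mmol/L."
    },
    "leucocytes": {
      "canonical_unit": "1e9/L",
      "lln": 4.0,
      "grade_upper_bounds": [3.0, 2.0, 1.0],
      "max_grade": 4
    },
    "neutrophils": {
      "canonical_unit": "1e9/L",
      "lln": 1.5,
      "grade_upper_bounds": [1.5, 1.0, 0.5],
      "max_grade": 4
    },
    "platelets": {
      "canonical_unit": "1e9/L",
      "lln": 150.0,
      "grade_upper_bounds": [75.0, 50.0, 25.0],
      "max_grade": 4
    }
  }
}
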