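{
 "descriptor_names": [
  "D1",
  "D2",
  "D3",
  "D4"
 ],
 "averages": {
  "tn": {
   "ACE": [
    2.0,
    1.3333333333333333,
    1.0,
    8.0
   ],
   "NEP": [
    3.0,
    2.0,
    1.0,
    8.0
   ]
  },
  "st": {
   "IC50": [
    2.5,
    1.5,
    0.75,
    8.5
   ],
   "Ki": [
    2.0,
    2.0,
    2.0,
    6.0
   ]
  },
  "at": {
   "B": [
    2.5,
    1.5,
    0.5,
    9.5
   ],
   "F": [
    2.3333333333333335,
    1.6666666666666667,
    1.3333333333333333,
    7.0
   ]
  }
 },
 "deviation_columns": [
  "D1_tn",
  "D2_tn",
  "D3_tn",
  "D4_tn",
  "D1_st",
  "D2_st",
  "D3_st",
  "D4_st",
  "D1_at",
  "D2_at",
  "D3_at",
  "D4_at"
 ],
 "deviations": {
  "M1": [
   -1.0,
   0.666666666667,
   -1.0,
   2.0,
   -1.5,
   0.5,
   -0.75,
   1.5,
   -1.5,
   0.5,
   -0.5,
   0.5
  ],
  "M2": [
   1.0,
   -1.333333333333,
   0.0,
   0.0,
   0.5,
   -1.5,
   0.25,
   -0.5,
   0.666666666667,
   -1.666666666667,
   -0.333333333333,
   1.0
  ],
  "M3": [
   3.0,
   -0.333333333333,
   3.0,
   -8.0,
   3.0,
   -1.0,
   2.0,
   -6.0,
   2.5,
   -0.5,
   3.5,
   -9.5
  ],
  "M4": [
   0.0,
   0.666666666667,
   1.0,
   -2.0,
   0.0,
   0.0,
   0.0,
   0.0,
   -0.333333333333,
   0.333333333333,
   0.666666666667,
   -1.0
  ],
  "M5": [
   1.0,
   -1.0,
   0.0,
   1.0,
   1.5,
   -0.5,
   0.25,
   0.5,
   1.5,
   -0.5,
   0.5,
   -0.5
  ],
  "M6": [
   3.0,
   1.0,
   4.0,
   -7.0,
   4.0,
   1.0,
   3.0,
   -5.0,
   3.666666666667,
   1.333333333333,
   3.666666666667,
   -6.0
  ],
  "M7": [
   -1.0,
   1.0,
   0.0,
   -1.0,
   -0.5,
   1.5,
   0.25,
   -1.5,
   -0.333333333333,
   1.333333333333,
   -0.333333333333,
   0.0
  ],
  "M8": [
   5.0,
   -2.0,
   5.0,
   -6.0,
   6.0,
   -2.0,
   4.0,
   -4.0,
   5.5,
   -1.5,
   5.5,
   -7.5
  ]
 },
 "wilks_lambda_subset": [
  "D1_tn",
  "D2_tn"
 ],
 "wilks_lambda": 0.053009387079,
 "metrics_example": {
  "rule": "predict active iff D4 >= 7",
  "counts": {
   "tp": 4,
   "fp": 0,
   "tn": 3,
   "fn": 1
  },
  "accuracy_pct": 87.5,
  "sensitivity_pct": 80.0,
  "specificity_pct": 100.0,
  "precision_pct": 100.0,
  "f_measure": 0.8888888889,
  "mcc": 0.7745966692
 }
}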