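{
 "schema_version": 1,
 "pcsm": {
  "cause": "pcsm",
  "fp_terms": [
   {
    "variable": "age",
    "powers": [
     3.0
    ],
    "betas": [
     0.002995508979798371
    ],
    "pre_shift": 0.0,
    "pre_scale": 10.0,
    "centers": [
     341.16
    ]
   },
   {
    "variable": "psa",
    "powers": [
     0.0
    ],
    "betas": [
     0.18564934688662926
    ],
    "pre_shift": 1.0,
    "pre_scale": 100.0,
    "centers": [
     -1.6364
    ]
   }
  ],
  "categorical_terms": [
   {
    "variable": "grade_group",
    "reference": "1",
    "betas": {
     "1": 0.0,
     "2": 0.27763173659827955,
     "3": 0.5481214085096876,
     "4": 0.7419373447293773,
     "5": 1.3686394258811698
    }
   },
   {
    "variable": "t_stage",
    "reference": "1",
    "betas": {
     "1": 0.0,
     "2": 0.16551443847757333,
     "3": 0.3987761199573678,
     "4": 0.6312717768418578
    }
   },
   {
    "variable": "treatment",
    "reference": "conservative",
    "betas": {
     "conservative": 0.0,
     "radical": -0.6931471805599453,
     "hormone": 0.9082585601768908
    }
   }
  ],
  "baseline": {
   "powers": [
    0.0
   ],
   "coefs": [
    1.5807
   ],
   "intercept": -6.2667,
   "domain": [
    0.0,
    15.0
   ],
   "r_squared": null,
   "monotone": true
  }
 },
 "npcm": {
  "cause": "npcm",
  "fp_terms": [
   {
    "variable": "age",
    "powers": [
     1.0
    ],
    "betas": [
     0.12221763272424911
    ],
    "pre_shift": 0.0,
    "pre_scale": 1.0,
    "centers": [
     69.87
    ]
   }
  ],
  "categorical_terms": [
   {
    "variable": "comorbidity",
    "reference": "0",
    "betas": {
     "0": 0.0,
     "1": 0.636576829071551
    }
   }
  ],
  "baseline": {
   "powers": [
    0.0
   ],
   "coefs": [
    1.4614
   ],
   "intercept": -4.821,
   "domain": [
    0.0,
    15.0
   ],
   "r_squared": null,
   "monotone": true
  }
 },
 "ppc_hr": {
  "lt50": 0.54,
  "ge50": 1.78,
  "unknown": 1.0
 },
 "metadata": {
  "version": "published-coefficients",
  "comorbidity_prevalence": 0.1021,
  "power_set": [
   -2,
   -1,
   -0.5,
   0,
   0.5,
   1,
   2,
   3
  ]
 }
}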