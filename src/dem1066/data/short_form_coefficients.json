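{
  "schema": "dem1066-coefficients-v1",
  "provenance": "10/66 short-form calibration model, development database n=1218; published logistic regression coefficients with quartile/standard score categories; intercept not published",
  "beta": {
    "eurod": {"0": 0.0, "1-2": 0.576, "3-5": -0.312, ">5": -1.214},
    "recall": {"7-10": 0.0, "5-6": 1.5, "4": 1.721, "1-3": 2.454, "0": 3.241},
    "cogscore": {">31.84": 0.0, "30.67-31.83": -0.048, "28.62-30.66": 1.174, "23.70-28.61": 2.208, "0-23.69": 3.792},
    "relscore": {"0": 0.0, "0.5-1.5": 1.497, "2-5": 2.251, "5.5-12": 4.343, ">12": 6.088}
  },
  "intercept": null,
  "cutoff": 0.2,
  "cutoff_scale": "linear_predictor"
}
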