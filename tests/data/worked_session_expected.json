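{
  "corXY": 0.7618981467532913,
  "numberTaps": 20.0,
  "skewDriftRight": -0.003348696803319311,
  "skewDriftLeft": 0.7559767611331429,
  "cvTapInter": 25.720723697867093,
  "cvDriftRight": 29.35260410491589,
  "cvDriftLeft": 58.31882783634338,
  "meanTapInter": 0.46421052631578946,
  "medianTapInter": 0.45999999999999996
}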