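{
  "gamma0": 2.0,
  "gamma_cov": 0.6,
  "gamma_harbor": 0.8,
  "eta2": 0.3,
  "rho2": 2.0,
  "psi": [
    -0.3234800440863309,
    -0.6538181064472938,
    -0.017413354934869056,
    -0.3429720961889702,
    0.05225831350021792,
    -0.4024615656605548,
    -0.37391926227212563,
    -0.44982277356571976,
    -0.26932677785198766
  ],
  "lambda": [
    7.979176120709215,
    3.171104040756458,
    7.580660934628146,
    8.008218377031456,
    5.50604752601699,
    5.4870817999215555,
    29.135898655362062,
    5.395303824594552,
    2.763000150416328
  ]
}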