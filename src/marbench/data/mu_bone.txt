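# bone: linear attenuation coefficient
# energy_keV  mu_per_cm
  10.0000  5.473920e+01
  11.4471  3.731591e+01
  13.1037  2.543839e+01
  15.0000  1.734144e+01
  16.5096  1.321945e+01
  18.1712  1.007724e+01
  20.0000  7.681920e+00
  22.8943  5.322793e+00
  26.2074  3.688157e+00
  30.0000  2.555520e+00
  33.0193  2.028318e+00
  36.3424  1.609877e+00
  40.0000  1.277760e+00
  43.0887  1.099656e+00
  46.4159  9.463774e-01
  50.0000  8.144640e-01
  53.1329  7.373832e-01
  56.4622  6.675973e-01
  60.0000  6.044160e-01
  66.0385  5.387175e-01
  72.6848  4.801602e-01
  80.0000  4.279680e-01
  86.1774  4.025525e-01
  92.8318  3.786464e-01
 100.0000  3.561600e-01
 114.4714  3.303323e-01
 131.0371  3.063776e-01
 150.0000  2.841600e-01
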