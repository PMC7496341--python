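# iron: linear attenuation coefficient
# energy_keV  mu_per_cm
  10.0000  1.343304e+03
  11.4471  9.325585e+02
  13.1037  6.474075e+02
  15.0000  4.494479e+02
  16.5096  3.443894e+02
  18.1712  2.638883e+02
  20.0000  2.022043e+02
  22.8943  1.380720e+02
  26.2074  9.428031e+01
  30.0000  6.437782e+01
  33.0193  4.910793e+01
  36.3424  3.745993e+01
  40.0000  2.857475e+01
  43.0887  2.326257e+01
  46.4159  1.893795e+01
  50.0000  1.541729e+01
  53.1329  1.311393e+01
  56.4622  1.115469e+01
  60.0000  9.488170e+00
  66.0385  7.500227e+00
  72.6848  5.928794e+00
  80.0000  4.686605e+00
  86.1774  4.005913e+00
  92.8318  3.424087e+00
 100.0000  2.926766e+00
 114.4714  2.366125e+00
 131.0371  1.912878e+00
 150.0000  1.546454e+00
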