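# water: linear attenuation coefficient
# energy_keV  mu_per_cm
  10.0000  5.329000e+00
  11.4471  3.621839e+00
  13.1037  2.461572e+00
  15.0000  1.673000e+00
  16.5096  1.313472e+00
  18.1712  1.031207e+00
  20.0000  8.096000e-01
  22.8943  6.267421e-01
  26.2074  4.851848e-01
  30.0000  3.756000e-01
  33.0193  3.357561e-01
  36.3424  3.001389e-01
  40.0000  2.683000e-01
  43.0887  2.537223e-01
  46.4159  2.399366e-01
  50.0000  2.269000e-01
  53.1329  2.196722e-01
  56.4622  2.126747e-01
  60.0000  2.059000e-01
  66.0385  1.982169e-01
  72.6848  1.908204e-01
  80.0000  1.837000e-01
  86.1774  1.792602e-01
  92.8318  1.749278e-01
 100.0000  1.707000e-01
 114.4714  1.636821e-01
 131.0371  1.569527e-01
 150.0000  1.505000e-01
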