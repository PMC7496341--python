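# 120 kVp tungsten spectrum (Kramers model, 2.5 mm Al filtration)
# energy_keV  relative_fluence
   10.0  3.35713751e-09
   11.0  2.29303060e-07
   12.0  4.26831483e-06
   13.0  3.42549117e-05
   14.0  1.56439374e-04
   15.0  4.84154721e-04
   16.0  1.12805957e-03
   17.0  2.16028356e-03
   18.0  3.57899596e-03
   19.0  5.31777142e-03
   20.0  7.27176116e-03
   21.0  9.17752828e-03
   22.0  1.10667246e-02
   23.0  1.28691570e-02
   24.0  1.45348233e-02
   25.0  1.60322857e-02
   26.0  1.73454534e-02
   27.0  1.84699692e-02
   28.0  1.94098557e-02
   29.0  2.01747046e-02
   30.0  2.07774786e-02
   31.0  2.10539230e-02
   32.0  2.12276976e-02
   33.0  2.13111601e-02
   34.0  2.13157688e-02
   35.0  2.12519926e-02
   36.0  2.11292892e-02
   37.0  2.09561283e-02
   38.0  2.07400421e-02
   39.0  2.04876916e-02
   40.0  2.02049405e-02
   41.0  1.98195521e-02
   42.0  1.94256736e-02
   43.0  1.90256566e-02
   44.0  1.86215211e-02
   45.0  1.82149976e-02
   46.0  1.78075655e-02
   47.0  1.74004856e-02
   48.0  1.69948290e-02
   49.0  1.65915021e-02
   50.0  1.61912684e-02
   51.0  1.57644693e-02
   52.0  1.53460137e-02
   53.0  1.49358863e-02
   54.0  1.45340420e-02
   55.0  1.41404108e-02
   56.0  1.37549022e-02
   57.0  1.33774094e-02
   58.0  1.30078117e-02
   59.0  1.26459780e-02
   60.0  1.22917684e-02
   61.0  1.19293807e-02
   62.0  1.15761192e-02
   63.0  1.12316626e-02
   64.0  1.08957033e-02
   65.0  1.05679469e-02
   66.0  1.02481113e-02
   67.0  9.93592622e-03
   68.0  9.63113273e-03
   69.0  9.33348276e-03
   70.0  9.04273849e-03
   71.0  8.75867199e-03
   72.0  8.48106465e-03
   73.0  8.20970683e-03
   74.0  7.94439740e-03
   75.0  7.68494337e-03
   76.0  7.43115949e-03
   77.0  7.18286791e-03
   78.0  6.93989782e-03
   79.0  6.70208515e-03
   80.0  6.46927224e-03
   81.0  6.23762392e-03
   82.0  6.01106772e-03
   83.0  5.78943635e-03
   84.0  5.57256981e-03
   85.0  5.36031498e-03
   86.0  5.15252525e-03
   87.0  4.94906019e-03
   88.0  4.74978520e-03
   89.0  4.55457125e-03
   90.0  4.36329454e-03
   91.0  4.17583631e-03
   92.0  3.99208252e-03
   93.0  3.81192363e-03
   94.0  3.63525443e-03
   95.0  3.46197376e-03
   96.0  3.29198435e-03
   97.0  3.12519265e-03
   98.0  2.96150860e-03
   99.0  2.80084554e-03
  100.0  2.64312000e-03
  101.0  2.48758910e-03
  102.0  2.33493287e-03
  103.0  2.18507132e-03
  104.0  2.03792746e-03
  105.0  1.89342709e-03
  106.0  1.75149871e-03
  107.0  1.61207340e-03
  108.0  1.47508468e-03
  109.0  1.34046844e-03
  110.0  1.20816280e-03
  111.0  1.07810803e-03
  112.0  9.50246455e-04
  113.0  8.24522364e-04
  114.0  7.00881932e-04
  115.0  5.79273137e-04
  116.0  4.59645683e-04
  117.0  3.41950935e-04
  118.0  2.26141844e-04
  119.0  1.12172886e-04
  120.0  0.00000000e+00
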