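{
 "state_label": "neutral",
 "charge": 0,
 "elements": [
  "H",
  "C",
  "N"
 ],
 "masses_amu": [
  1.008,
  12.011,
  14.007
 ],
 "geometry_angstrom": [
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  1.07,
  0.0,
  0.0,
  2.22
 ],
 "frequencies_cm1": [
  778.0,
  778.0,
  2149.0,
  3500.0
 ],
 "modes_massweighted": [
  [
   -0.8527886640363305,
   7.461709599808273e-17,
   1.8545731758184137e-18,
   -8.22530187359916e-18
  ],
  [
   1.2881054995062061e-17,
   0.8527886640363307,
   5.075263468673644e-16,
   -3.4595815955035475e-16
  ],
  [
   1.1698494313192609e-17,
   1.1097267854385459e-16,
   0.05256377006160996,
   0.9797650906084847
  ],
  [
   0.47691088556997363,
   1.4408065445212533e-16,
   1.54757378895569e-18,
   -1.365412221333925e-17
  ],
  [
   6.2963259911226175e-18,
   -0.4769108855699736,
   -2.898386549335804e-16,
   2.3826951616309185e-16
  ],
  [
   4.03821358725577e-17,
   3.7675223856166966e-16,
   -0.7397048481780586,
   -0.09172158674012901
  ],
  [
   -0.21285558887657577,
   3.836625313243712e-17,
   -3.9628003156504094e-18,
   2.3614351978765497e-18
  ],
  [
   -2.3004229282837584e-17,
   0.2128555888765757,
   1.2902266616758673e-16,
   -1.2025260639756184e-16
  ],
  [
   4.3608612264283664e-17,
   -5.003524727416549e-16,
   0.6708753890692261,
   -0.1778974922555692
  ]
 ],
 "linear": true
}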