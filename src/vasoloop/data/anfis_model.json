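{
 "schema_version": 1,
 "premises": [
  [
   [
    22.455616732400443,
    2.709491459906067,
    -31.586007136670858
   ],
   [
    20.589880848633882,
    1.397093056720359,
    -5.772597583017932
   ],
   [
    20.497043886877236,
    0.7060758338164181,
    23.773486865769623
   ]
  ],
  [
   [
    0.04624487989174049,
    1.9999275466125626,
    -0.08178337940675935
   ],
   [
    0.042799729507853004,
    2.0000250343157657,
    -0.02849617418380396
   ],
   [
    0.044875630049822555,
    1.9999799750608176,
    0.02911714054109514
   ]
  ]
 ],
 "consequents": [
  [
   0.18685447551998705,
   -17.573780173322053,
   7.723824401374847
  ],
  [
   0.15037169190550245,
   -19.4203072618689,
   8.463920877835987
  ],
  [
   0.15569542168548597,
   -7.672207390377729,
   10.269649378512801
  ],
  [
   0.3556559464718143,
   9.786354932158863,
   -1.0967859353195444
  ],
  [
   0.3831121698056145,
   10.951451704208443,
   -0.9518520607155597
  ],
  [
   0.4676753395427046,
   8.618663206181091,
   -0.6791228004976858
  ],
  [
   -0.04066662193080509,
   -1.5411097363671478,
   3.4687294183626296
  ],
  [
   -0.028508544424227237,
   -2.123254935868672,
   2.799081106303421
  ],
  [
   -0.011481277731345137,
   -0.9416155415220424,
   1.600202624474638
  ]
 ]
}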