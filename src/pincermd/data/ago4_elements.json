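{
 "protein": "AGO4",
 "domains": [],
 "selections": [
  {
   "name": "H1",
   "residues": [
    242,
    243,
    244,
    245,
    246,
    247,
    248,
    249,
    250,
    251,
    252,
    253,
    254
   ]
  },
  {
   "name": "L1_loop",
   "residues": [
    337,
    338,
    339,
    340,
    341,
    342,
    343,
    344,
    345,
    346,
    347
   ]
  },
  {
   "name": "SL1",
   "residues": [
    592,
    593,
    594,
    595,
    596,
    597,
    598,
    599,
    600,
    601
   ]
  },
  {
   "name": "SL2",
   "residues": [
    625,
    626,
    627,
    628,
    629,
    630,
    631,
    632,
    633,
    634,
    635
   ]
  },
  {
   "name": "LL1",
   "residues": [
    820,
    821,
    822,
    823,
    824,
    825,
    826,
    827,
    828,
    829,
    830,
    831,
    832,
    833,
    834,
    835,
    836,
    837,
    838,
    839,
    840
   ]
  }
 ]
}
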