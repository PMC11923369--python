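{
 "protein": "AGO2",
 "domains": [
  {
   "name": "N",
   "start": 36,
   "end": 166
  },
  {
   "name": "L1",
   "start": 175,
   "end": 227
  },
  {
   "name": "PAZ",
   "start": 235,
   "end": 370
  },
  {
   "name": "L2",
   "start": 374,
   "end": 420
  },
  {
   "name": "MID",
   "start": 429,
   "end": 510
  },
  {
   "name": "PIWI",
   "start": 517,
   "end": 818
  }
 ],
 "selections": [
  {
   "name": "CT",
   "residues": [
    597,
    737,
    669,
    807
   ]
  },
  {
   "name": "ZSWIM8",
   "residues": [
    493
   ]
  },
  {
   "name": "GW182",
   "residues": [
    590,
    620,
    651,
    653,
    654,
    657,
    659,
    660,
    694,
    695,
    698
   ]
  },
  {
   "name": "LCS1",
   "residues": [
    322,
    323,
    324,
    325,
    326,
    327,
    328,
    329,
    330,
    331,
    332,
    333,
    334,
    335,
    336,
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
    347,
    348,
    349,
    350,
    351,
    352,
    353,
    354,
    355,
    356,
    357,
    358,
    359,
    360,
    361,
    362,
    363,
    364,
    365
   ]
  },
  {
   "name": "LCS2",
   "residues": [
    782,
    783,
    784,
    785,
    786,
    787,
    788,
    789,
    790,
    791,
    792,
    793,
    794,
    795,
    796,
    797,
    798,
    799,
    800,
    801,
    802,
    803,
    804,
    805,
    806,
    807,
    808,
    809,
    810,
    811,
    812,
    813,
    814,
    815,
    816,
    817,
    818,
    819,
    820,
    821,
    822,
    823,
    824,
    825,
    826,
    827,
    828,
    829
   ]
  }
 ]
}
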