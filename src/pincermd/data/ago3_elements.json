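{
 "protein": "AGO3",
 "domains": [],
 "selections": [
  {
   "name": "H1",
   "residues": [
    252,
    253,
    254,
    255,
    256,
    257,
    258,
    259,
    260,
    261,
    262,
    263,
    264
   ]
  },
  {
   "name": "L1_loop",
   "residues": [
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
    358
   ]
  },
  {
   "name": "SL1",
   "residues": [
    601,
    602,
    603,
    604,
    605,
    606,
    607,
    608,
    609,
    610
   ]
  },
  {
   "name": "SL2",
   "residues": [
    634,
    635,
    636,
    637,
    638,
    639,
    640,
    641
   ]
  },
  {
   "name": "LL1",
   "residues": [
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
    829,
    830,
    831,
    832,
    833,
    834,
    835,
    836,
    837,
    838
   ]
  }
 ]
}
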