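{
 "partition": [
  2,
  2,
  2,
  2,
  2,
  0,
  0,
  0,
  0,
  0,
  3,
  3,
  3,
  3,
  3,
  1,
  1,
  1,
  1,
  1
 ],
 "stable_edges": [
  [
   0,
   1
  ],
  [
   0,
   2
  ],
  [
   0,
   3
  ],
  [
   0,
   4
  ],
  [
   1,
   2
  ],
  [
   1,
   3
  ],
  [
   1,
   4
  ],
  [
   2,
   3
  ],
  [
   2,
   4
  ],
  [
   3,
   4
  ]
 ],
 "acc": 100.0,
 "auc": 100.0
}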