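{
 "alphabet": [1, 2, 3],
 "contexts": {
  "1": [0.0, 1.0, 0.0],
  "3": [1.0, 0.0, 0.0],
  "1,2": [0.0, 0.26, 0.74],
  "2,2": [1.0, 0.0, 0.0]
 }
}
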