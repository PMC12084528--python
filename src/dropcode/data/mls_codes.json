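{
 "mls1": {
  "order": 6,
  "taps": [
   6,
   1
  ],
  "seed": 1,
  "bits": "100000111111010101100110111011010010011100010111100101000110000"
 },
 "mls2": {
  "order": 6,
  "taps": [
   6,
   5
  ],
  "seed": 1,
  "bits": "100000100001100010100111101000111001001011011101100110101011111"
 }
}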