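# position-specific scoring matrix (integer log-odds)
      A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
  1 D   0   1  -1   3  -2  -1   1   0  -2  -3  -1   0  -2   1   0   1  -2  -3  -2  -3
  2 D  -2  -3   0   5  -2  -1   2   1  -3  -3  -3  -2   1  -3  -2   1   1  -3  -3  -3
  3 W  -4  -4  -4  -5  -2  -3  -4  -3  -2  -3  -2  -4  -2   4  -5  -3  -3  11   5  -3
  4 D  -2  -3  -2   2  -3   1   2  -3   1   1   1  -2  -1  -3  -2  -1   1  -3  -2   2
  5 M   0  -2  -2   0  -2  -1   1  -3   0   1   0   0   2   1   0   0   1  -3  -2   1
  6 I  -2  -4  -4  -4  -1  -3  -4  -5  -4   4   4  -3   0  -1  -4  -3  -2  -3  -2   3
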