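{
  "table1_scores.csv": "9221a3378367112899093b969c7c3b85e755ec629171073b6b99942b78eafffc",
  "heni_factors.csv": "3d1dc34e201a5b1deb05091fcbc289e8f20806d942d57dc7d5ece9479857cee5",
  "printed_compositions.csv": "5e9fb3cf31edd6b8b8dcdba833ea298d7752c18c326153900d165afe7f56a5c3"
}
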