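{
  "pk_default": {
    "provenance": "pKa of the most acidic/basic ring nitrogen of each free base: adenine N1 3.5, cytosine N3 4.2, guanine N1 9.2, thymine N3 9.7.",
    "mapping": {"A": 3.5, "C": 4.2, "G": 9.2, "T": 9.7}
  },
  "eiip": {
    "provenance": "Electron-ion interaction pseudopotential amplitudes for nucleotides.",
    "mapping": {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}
  }
}
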