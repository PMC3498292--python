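{
  "name": "united-heavy-atom",
  "version": "1.0",
  "provenance": "Element-class van der Waals radii for hydrogen-free protein models, following the united-atom values of Chothia (J Mol Biol 1976, 105:1-12) collapsed per element.",
  "units": "A",
  "probe_radius_A": 1.4,
  "radii": {
    "C": 1.87,
    "N": 1.65,
    "O": 1.4,
    "S": 1.85,
    "P": 1.9,
    "H": 1.0
  }
}
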