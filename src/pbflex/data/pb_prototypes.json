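{
  "name": "protein-blocks-16",
  "version": "1.0",
  "provenance": "Reference dihedral prototypes of the 16-letter Protein Blocks structural alphabet (de Brevern, Etchebest & Hazout, Proteins 2000, 41:271-287), as distributed with the PBxplore assignment tool.",
  "angle_order": [
    "psi_m2",
    "phi_m1",
    "psi_m1",
    "phi_0",
    "psi_0",
    "phi_p1",
    "psi_p1",
    "phi_p2"
  ],
  "units": "degrees",
  "checksum_sha256": "c6186c96716f48023ae2470b68b1d7e7f91ce9cca79faedd449ace5b6daaaa4e",
  "prototypes": {
    "a": [
      41.14,
      75.53,
      13.92,
      -99.8,
      131.88,
      -96.27,
      122.08,
      -99.68
    ],
    "b": [
      108.24,
      -90.12,
      119.54,
      -92.21,
      -18.06,
      -128.93,
      147.04,
      -99.9
    ],
    "c": [
      -11.61,
      -105.66,
      94.81,
      -106.09,
      133.56,
      -106.93,
      135.97,
      -100.63
    ],
    "d": [
      141.98,
      -112.79,
      132.2,
      -114.79,
      140.11,
      -111.05,
      139.54,
      -103.16
    ],
    "e": [
      133.25,
      -112.37,
      137.64,
      -108.13,
      133.0,
      -87.3,
      120.54,
      77.4
    ],
    "f": [
      116.4,
      -105.53,
      129.32,
      -96.68,
      140.72,
      -74.19,
      -26.65,
      -94.51
    ],
    "g": [
      0.4,
      -81.83,
      4.91,
      -100.59,
      85.5,
      -71.65,
      130.78,
      84.98
    ],
    "h": [
      119.14,
      -102.58,
      130.83,
      -67.91,
      121.55,
      76.25,
      -2.95,
      -90.88
    ],
    "i": [
      130.68,
      -56.92,
      119.26,
      77.85,
      10.42,
      -99.43,
      141.4,
      -98.01
    ],
    "j": [
      114.32,
      -121.47,
      118.14,
      82.88,
      -150.05,
      -83.81,
      23.35,
      -85.82
    ],
    "k": [
      117.16,
      -95.41,
      140.4,
      -59.35,
      -29.23,
      -72.39,
      -25.08,
      -76.16
    ],
    "l": [
      139.2,
      -55.96,
      -32.7,
      -68.51,
      -26.09,
      -74.44,
      -22.6,
      -71.74
    ],
    "m": [
      -39.62,
      -64.73,
      -39.52,
      -65.54,
      -38.88,
      -66.89,
      -37.76,
      -70.19
    ],
    "n": [
      -35.34,
      -65.03,
      -38.12,
      -66.34,
      -29.51,
      -89.1,
      -2.91,
      77.9
    ],
    "o": [
      -45.29,
      -67.44,
      -27.72,
      -87.27,
      5.13,
      77.49,
      30.71,
      -93.23
    ],
    "p": [
      -27.09,
      -86.14,
      0.3,
      -82.19,
      19.31,
      -124.9,
      156.96,
      -95.95
    ]
  }
}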