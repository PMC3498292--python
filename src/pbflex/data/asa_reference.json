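{
  "name": "ala-x-ala-extended",
  "version": "1.0",
  "provenance": "Extended Ala-X-Ala tripeptide reference accessibilities (Miller, Janin, Lesk & Chothia, J Mol Biol 1987, 196:641-656), with Leu and Pro set to the 183/142 A^2 values used for rASA normalisation of the beta3 HPA-1 variant residue.",
  "units": "A^2",
  "values": {
    "ALA": 113.0,
    "ARG": 241.0,
    "ASN": 158.0,
    "ASP": 151.0,
    "CYS": 140.0,
    "GLN": 189.0,
    "GLU": 183.0,
    "GLY": 85.0,
    "HIS": 194.0,
    "ILE": 182.0,
    "LEU": 183.0,
    "LYS": 211.0,
    "MET": 204.0,
    "PHE": 218.0,
    "PRO": 142.0,
    "SER": 122.0,
    "THR": 146.0,
    "TRP": 259.0,
    "TYR": 229.0,
    "VAL": 160.0
  }
}
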