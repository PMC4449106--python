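{
 "description": "Residue groups behind the ':' (strong) and '.' (weak) symbols of classic Clustal output (Gonnet PAM250 conservation groups).",
 "strong": ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"],
 "weak": ["CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY"]
}
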