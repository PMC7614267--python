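"""Frozen integer m/z labels of pyridylaminated N-glycan standards,
core Y ions, antennal B ions and reduced O-glycans, with the compositions
they correspond to. These are the worked examples the mass engine must
reproduce by truncation of the monoisotopic m/z."""

# (composition string, label state, ion mode sign, expected integer label)
# [M+H]+ precursors of pyridylaminated N-glycans
PRECURSOR_LABELS = [
    ("Hex3HexNAc2Fuc2", "PA", +1, 1281),
    ("Hex4HexNAc2Fuc2", "PA", +1, 1443),
    ("Hex5HexNAc2Fuc1", "PA", +1, 1459),
    ("Hex3HexNAc4Fuc1", "PA", +1, 1541),
    ("Hex4HexNAc2Fuc3", "PA", +1, 1589),
    ("Hex5HexNAc2Fuc2", "PA", +1, 1605),
    ("Hex5HexNAc2Fuc3", "PA", +1, 1751),
    ("Hex7HexNAc2", "PA", +1, 1637),
    ("Hex7HexNAc2Fuc4Me1", "PA", +1, 2235),
    # beta-galactosidase / HEX-4 digestion products
    ("Hex4HexNAc2Fuc1", "PA", +1, 1297),
    ("Hex3HexNAc3Fuc1", "PA", +1, 1338),
    # reduced O-glycans, [M-H]-
    ("Hex1HexNAc2HexA1PC1", "alditol", -1, 928),
    ("HexNAc2HexA1PC1", "alditol", -1, 766),
    ("HexNAc3HexA1PC1", "alditol", -1, 969),
    # the corresponding positive-mode species of the linear PC O-glycan
    ("Hex1HexNAc2HexA1PC1", "alditol", +1, 930),
]

# core Y ions: composition of the retained reducing-side part (label
# included via the PA state), positive mode
Y_ION_LABELS = [
    ("HexNAc1Fuc1", 446),
    ("HexNAc1Fuc2", 592),
    ("Hex1HexNAc1Fuc1", 608),
    ("Hex1HexNAc1Fuc2", 754),
    ("Hex2HexNAc1Fuc1", 770),
    ("Hex2HexNAc1Fuc2", 916),
    ("Hex1HexNAc2Fuc1", 811),
]

# B ions (oxocarbenium, residue sum + proton), positive mode
B_ION_LABELS = [
    ("HexNAc1PC1", 369),
    ("HexNAc2", 407),
    ("Hex1HexNAc1PC1", 531),
    ("HexNAc2PC1", 572),
    ("HexNAc2PC2", 737),
    ("HexNAc3PC2", 940),
    ("HexNAc4PC2", 1143),
    ("Hex1HexNAc2PC1", 734),
    ("Hex1HexNAc2PC2", 899),
    ("Hex1HexNAc3PC1", 937),
    ("Hex1HexNAc3PC2", 1102),
    ("Hex1HexNAc4PC2", 1305),
    ("HexNAc1HexA1PC1", 545),
]

# negative-mode B ion of the PC/HexA O-glycan unit
B_ION_LABELS_NEG = [
    ("HexNAc1HexA1PC1", 543),
]

# neutral-loss masses (Da) printed alongside digestion/fragmentation data
NEUTRAL_LOSSES = {
    "Fuc": 146.0579,
    "MeFuc": 160.0736,
    "Hex": 162.0528,
    "HexNAc": 203.0794,
    "PC": 165.0555,
    "HexNAc-PA-reducing": 299.1482,
    "HexFuc": 308.1107,
    "GalFuc-reducing": 607.2589,
    "trimethylamine": 59.0735,
}
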