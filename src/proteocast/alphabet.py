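"""Amino-acid alphabets, residue-name maps, and the maximum-ASA table."""

# Canonical ordering used for every 20-wide matrix axis in the package.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ORDER)
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Characters treated as gap-like in alignment columns. 'X' and any letter
# outside the 20-letter alphabet carry no substitution identity, so they are
# pooled with gaps for column statistics and baseline counts.
GAP_CHARS = frozenset("-.")

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Curated map from common modified/non-standard residues to their standard
# parent. Residues absent from both tables are dropped at parse time.
NON_STANDARD_TO_ONE = {
    "MSE": "M",   # selenomethionine
    "SEP": "S",   # phosphoserine
    "TPO": "T",   # phosphothreonine
    "PTR": "Y",   # phosphotyrosine
    "MLY": "K",   # N-dimethyl-lysine
    "M3L": "K",   # N-trimethyl-lysine
    "HYP": "P",   # hydroxyproline
    "CSO": "C",   # S-hydroxycysteine
    "KCX": "K",   # carboxy-lysine
    "PCA": "Q",   # pyroglutamate
}


def residue_one_letter(resname: str) -> str | None:
    """Map a 3-letter residue name to its standard 1-letter code.

    Returns None for residues that are neither standard nor in the curated
    non-standard dictionary (e.g. waters, ligands).
    """
    resname = resname.strip().upper()
    if resname in THREE_TO_ONE:
        return THREE_TO_ONE[resname]
    return NON_STANDARD_TO_ONE.get(resname)


# Theoretical maximum accessible surface areas (Å²) per residue type,
# Tien et al. (2013) "Maximum allowed solvent accessibilites of residues in
# proteins", theoretical column. Used to normalise ASA into RSA percent.
MAX_ASA_TIEN_2013_THEORETICAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
MAX_ASA_TABLE_NAME = "Tien2013-theoretical"
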