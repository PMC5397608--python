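"""Amino-acid property scales used by the propensity and stability surrogates.

All scales are keyed by one-letter code over the 20 canonical residues.
Normalised variants are min-max scaled to [0, 1] over the canonical 20.
"""

from __future__ import annotations

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle hydropathy (dimensionless).
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Chou & Fasman beta-sheet conformational preference P(beta).
CHOU_FASMAN_BETA = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}

# Side-chain formal charge at neutral pH; histidine neutral by convention.
CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

# Maximum accessible surface area per residue type in a Gly-X-Gly tripeptide
# (theoretical values of Tien et al. 2013), Angstrom^2.
MAX_ASA = {
    "A": 129.0, "C": 167.0, "D": 193.0, "E": 223.0, "F": 240.0,
    "G": 104.0, "H": 224.0, "I": 197.0, "K": 236.0, "L": 201.0,
    "M": 224.0, "N": 195.0, "P": 159.0, "Q": 225.0, "R": 274.0,
    "S": 155.0, "T": 172.0, "V": 174.0, "W": 285.0, "Y": 263.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

# Residues with a polar (H-bond capable) side chain; used by the ddG rule that
# polar->apolar substitutions lose their side-chain hydrogen bonds.
POLAR_SIDECHAIN = set("STNQYHKRDEW")


def _minmax(scale: dict[str, float]) -> dict[str, float]:
    lo, hi = min(scale.values()), max(scale.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in scale.items()}


# Normalised hydrophobicity and beta propensity in [0, 1].
HYDRO_NORM = _minmax(KYTE_DOOLITTLE)
BETA_NORM = _minmax(CHOU_FASMAN_BETA)
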