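"""Per-residue property tables and group schemes used by the descriptor encoders.

The 20-letter amino-acid alphabet is fixed throughout the package.  Tables fall
into four provenance classes, stated per table:

* published physicochemical scales entered verbatim (z-scales, Eisenberg
  consensus hydrophobicity, Grantham polarity);
* scales taken at import time from Biopython's ``ProtParamData`` (Kyte-
  Doolittle hydropathy, Hopp-Woods hydrophilicity, Janin buriability, Emini
  surface fraction, Bhaskaran-Ponnuswamy flexibility);
* small-molecule descriptors of the 20 free amino acids computed once with
  RDKit and frozen here (``RDKIT_TABLES``);
* package-defined composite tables (``EZ``, ``COUGAR``, ``ABHPRK``) -- these
  are synthetic stand-ins assembled from the tables above, named after the
  descriptor slots they fill; their construction is documented inline.
"""

from __future__ import annotations

import numpy as np
from Bio.SeqUtils import ProtParamData as _ppd

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_LIST = tuple(ALPHABET)
AA_SET = frozenset(ALPHABET)

# --- five physicochemical residue groups (composition descriptors) ----------
GROUPS5 = {
    "ali": "GAVLMI",   # aliphatic
    "aro": "FYW",      # aromatic
    "pos": "KRH",      # positively charged
    "neg": "DE",       # negatively charged
    "unc": "STCPNQ",   # uncharged polar
}
GROUP5_OF = {aa: g for g, members in GROUPS5.items() for aa in members}

# --- conjoint-triad classes (Shen et al. seven-class alphabet) ---------------
CTRIAD_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
CTRIAD_CLASS_OF = {aa: i + 1 for i, cls in enumerate(CTRIAD_CLASSES) for aa in cls}

# --- standard-genetic-code codon counts per residue (61 sense codons) --------
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}
assert sum(CODON_COUNTS.values()) == 61

# Mean GC fraction of each residue's sense codons (exact, standard code).
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
CODON_GC = {
    aa: float(np.mean([sum(c in "GC" for c in codon) / 3.0 for codon in codons]))
    for aa, codons in _CODONS.items()
}

# --- published 1-D scales ----------------------------------------------------
# Eisenberg consensus hydrophobicity.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}
# Grantham polarity.
GRANTHAM_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}

# Biopython ProtParamData scales (exact published values shipped with Biopython).
KYTE_DOOLITTLE = dict(_ppd.kd)
HOPP_WOODS = dict(_ppd.hw)
FLEXIBILITY = dict(_ppd.Flex)
EMINI_SURFACE = dict(_ppd.em)
JANIN = dict(_ppd.ja)

# --- multidimensional z-scales ----------------------------------------------
# Hellberg three-component z-scales (z1 hydrophilicity, z2 steric bulk, z3
# polarity/charge).
Z3 = {
    "A": (0.07, -1.73, 0.09), "R": (2.88, 2.52, -3.44), "N": (3.22, 1.45, 0.84),
    "D": (3.64, 1.13, 2.36), "C": (0.71, -0.97, 4.13), "Q": (2.18, 0.53, -1.14),
    "E": (3.08, 0.39, -0.07), "G": (2.23, -5.36, 0.30), "H": (2.41, 1.74, 1.11),
    "I": (-4.44, -1.68, -1.03), "L": (-4.19, -1.03, -0.98), "K": (2.84, 1.41, -3.14),
    "M": (-2.49, -0.27, -0.41), "F": (-4.92, 1.30, 0.45), "P": (-1.22, 0.88, 2.23),
    "S": (1.96, -1.63, 0.57), "T": (0.92, -2.09, -1.40), "W": (-4.75, 3.65, 0.85),
    "Y": (1.39, 2.32, 0.01), "V": (-2.69, -2.53, -1.29),
}
# Sandberg five-component extended z-scales.
Z5 = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30), "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61), "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65), "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25), "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09), "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84), "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98), "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00), "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40), "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47), "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

# --- RDKit-computed descriptors of the 20 free amino acids (frozen) ---------
# Computed once with RDKit (MolFromSmiles on the neutral free amino acids;
# Crippen logP/MR, TPSA, graph indices, atom counts, QED) and frozen here so
# the package does not import RDKit at run time.  A test recomputes them.
RDKIT_TABLES = {
    "rd_molwt": {"A": 89.09400, "C": 121.16100, "D": 133.10300, "E": 147.13000, "F": 165.19200, "G": 75.06700, "H": 155.15700, "I": 131.17500, "K": 146.19000, "L": 131.17500, "M": 149.21500, "N": 132.11900, "P": 115.13200, "Q": 146.14600, "R": 174.20400, "S": 105.09300, "T": 119.12000, "V": 117.14800, "W": 204.22900, "Y": 181.19100},
    "rd_heavy_atoms": {"A": 6.00000, "C": 7.00000, "D": 9.00000, "E": 10.00000, "F": 12.00000, "G": 5.00000, "H": 11.00000, "I": 9.00000, "K": 10.00000, "L": 9.00000, "M": 9.00000, "N": 9.00000, "P": 8.00000, "Q": 10.00000, "R": 12.00000, "S": 7.00000, "T": 8.00000, "V": 8.00000, "W": 15.00000, "Y": 13.00000},
    "rd_logp": {"A": -0.58180, "C": -0.67190, "D": -1.12700, "E": -0.73690, "F": 0.64100, "G": -0.97030, "H": -0.63590, "I": 0.44440, "K": -0.47270, "L": 0.44440, "M": 0.15140, "N": -1.72630, "P": -0.17700, "Q": -1.33620, "R": -1.33843, "S": -1.60940, "T": -1.22090, "V": 0.05430, "W": 1.12230, "Y": 0.34660},
    "rd_molar_refractivity": {"A": 21.28520, "C": 29.46420, "D": 27.86400, "E": 32.48100, "F": 45.75720, "G": 16.69020, "H": 37.90290, "I": 35.06620, "K": 38.51660, "L": 35.06620, "M": 38.61020, "N": 29.42260, "P": 28.66050, "Q": 34.03960, "R": 44.76200, "S": 22.69700, "T": 27.29200, "V": 30.44920, "W": 57.61390, "Y": 47.42200},
    "rd_tpsa": {"A": 63.32000, "C": 63.32000, "D": 100.62000, "E": 100.62000, "F": 63.32000, "G": 63.32000, "H": 92.00000, "I": 63.32000, "K": 89.34000, "L": 63.32000, "M": 63.32000, "N": 106.41000, "P": 49.33000, "Q": 106.41000, "R": 125.22000, "S": 83.55000, "T": 83.55000, "V": 63.32000, "W": 79.11000, "Y": 83.55000},
    "rd_hbond_donors": {"A": 2.00000, "C": 3.00000, "D": 3.00000, "E": 3.00000, "F": 2.00000, "G": 2.00000, "H": 3.00000, "I": 2.00000, "K": 3.00000, "L": 2.00000, "M": 2.00000, "N": 3.00000, "P": 2.00000, "Q": 3.00000, "R": 5.00000, "S": 3.00000, "T": 3.00000, "V": 2.00000, "W": 3.00000, "Y": 3.00000},
    "rd_hbond_acceptors": {"A": 2.00000, "C": 3.00000, "D": 3.00000, "E": 3.00000, "F": 2.00000, "G": 2.00000, "H": 3.00000, "I": 2.00000, "K": 3.00000, "L": 2.00000, "M": 3.00000, "N": 3.00000, "P": 2.00000, "Q": 3.00000, "R": 3.00000, "S": 3.00000, "T": 3.00000, "V": 2.00000, "W": 2.00000, "Y": 3.00000},
    "rd_rotatable_bonds": {"A": 1.00000, "C": 2.00000, "D": 3.00000, "E": 4.00000, "F": 3.00000, "G": 1.00000, "H": 3.00000, "I": 3.00000, "K": 5.00000, "L": 3.00000, "M": 4.00000, "N": 3.00000, "P": 1.00000, "Q": 4.00000, "R": 5.00000, "S": 2.00000, "T": 2.00000, "V": 2.00000, "W": 3.00000, "Y": 3.00000},
    "rd_aromatic_atoms": {"A": 0.00000, "C": 0.00000, "D": 0.00000, "E": 0.00000, "F": 6.00000, "G": 0.00000, "H": 5.00000, "I": 0.00000, "K": 0.00000, "L": 0.00000, "M": 0.00000, "N": 0.00000, "P": 0.00000, "Q": 0.00000, "R": 0.00000, "S": 0.00000, "T": 0.00000, "V": 0.00000, "W": 9.00000, "Y": 6.00000},
    "rd_ring_count": {"A": 0.00000, "C": 0.00000, "D": 0.00000, "E": 0.00000, "F": 1.00000, "G": 0.00000, "H": 1.00000, "I": 0.00000, "K": 0.00000, "L": 0.00000, "M": 0.00000, "N": 0.00000, "P": 1.00000, "Q": 0.00000, "R": 0.00000, "S": 0.00000, "T": 0.00000, "V": 0.00000, "W": 2.00000, "Y": 1.00000},
    "rd_fraction_csp3": {"A": 0.66667, "C": 0.66667, "D": 0.50000, "E": 0.60000, "F": 0.22222, "G": 0.50000, "H": 0.33333, "I": 0.83333, "K": 0.83333, "L": 0.83333, "M": 0.80000, "N": 0.50000, "P": 0.80000, "Q": 0.60000, "R": 0.66667, "S": 0.66667, "T": 0.75000, "V": 0.80000, "W": 0.18182, "Y": 0.22222},
    "rd_labute_asa": {"A": 35.76478, "C": 46.91985, "D": 51.08548, "E": 57.45042, "F": 70.82188, "G": 29.39984, "H": 63.25068, "I": 54.85961, "K": 60.19950, "L": 54.85961, "M": 58.61778, "N": 51.63114, "P": 47.69881, "Q": 57.99608, "R": 70.43471, "S": 40.55902, "T": 46.92396, "V": 48.49467, "W": 86.71270, "Y": 75.61611},
    "rd_nhoh_count": {"A": 3.00000, "C": 3.00000, "D": 4.00000, "E": 4.00000, "F": 3.00000, "G": 3.00000, "H": 4.00000, "I": 3.00000, "K": 5.00000, "L": 3.00000, "M": 3.00000, "N": 5.00000, "P": 2.00000, "Q": 5.00000, "R": 7.00000, "S": 4.00000, "T": 4.00000, "V": 3.00000, "W": 4.00000, "Y": 4.00000},
    "rd_no_count": {"A": 3.00000, "C": 3.00000, "D": 5.00000, "E": 5.00000, "F": 3.00000, "G": 3.00000, "H": 5.00000, "I": 3.00000, "K": 4.00000, "L": 3.00000, "M": 3.00000, "N": 5.00000, "P": 3.00000, "Q": 5.00000, "R": 6.00000, "S": 4.00000, "T": 4.00000, "V": 3.00000, "W": 4.00000, "Y": 4.00000},
    "rd_heteroatoms": {"A": 3.00000, "C": 4.00000, "D": 5.00000, "E": 5.00000, "F": 3.00000, "G": 3.00000, "H": 5.00000, "I": 3.00000, "K": 4.00000, "L": 3.00000, "M": 4.00000, "N": 5.00000, "P": 3.00000, "Q": 5.00000, "R": 6.00000, "S": 4.00000, "T": 4.00000, "V": 3.00000, "W": 4.00000, "Y": 4.00000},
    "rd_valence_electrons": {"A": 36.00000, "C": 42.00000, "D": 52.00000, "E": 58.00000, "F": 64.00000, "G": 30.00000, "H": 60.00000, "I": 54.00000, "K": 60.00000, "L": 54.00000, "M": 54.00000, "N": 52.00000, "P": 46.00000, "Q": 58.00000, "R": 70.00000, "S": 42.00000, "T": 48.00000, "V": 48.00000, "W": 78.00000, "Y": 70.00000},
    "rd_balaban_j": {"A": 3.25759, "C": 3.34342, "D": 3.63243, "E": 3.49073, "F": 2.58460, "G": 2.84738, "H": 2.49876, "I": 3.71614, "K": 3.21488, "L": 3.50169, "M": 3.26591, "N": 3.63243, "P": 2.34994, "Q": 3.49073, "R": 3.31184, "S": 3.34342, "T": 3.63768, "V": 3.63768, "W": 2.32349, "Y": 2.64176},
    "rd_bertz_ct": {"A": 59.81354, "C": 75.33516, "D": 132.52933, "E": 144.58338, "F": 258.49086, "G": 42.91261, "H": 231.98525, "I": 103.23098, "K": 105.92094, "L": 101.23098, "M": 96.95878, "N": 133.77444, "P": 96.60179, "Q": 145.82849, "R": 170.93102, "S": 72.58027, "T": 91.28421, "V": 90.42946, "W": 490.04851, "Y": 294.23305},
    "rd_chi0": {"A": 5.15470, "C": 5.86181, "D": 7.43916, "E": 8.14626, "F": 8.97469, "G": 4.28446, "H": 8.26758, "I": 7.43916, "K": 7.98313, "L": 7.43916, "M": 7.27602, "N": 7.43916, "P": 5.98313, "Q": 8.14626, "R": 9.56048, "S": 5.86181, "T": 6.73205, "V": 6.73205, "W": 10.83650, "Y": 9.84493},
    "rd_chi1": {"A": 2.64273, "C": 3.18074, "D": 4.03658, "E": 4.53658, "F": 5.69838, "G": 2.27006, "H": 5.19838, "I": 4.09142, "K": 4.68074, "L": 4.03658, "M": 4.18074, "N": 4.03658, "P": 3.80453, "Q": 4.53658, "R": 5.53658, "S": 3.18074, "T": 3.55342, "V": 3.55342, "W": 7.18154, "Y": 6.09222},
    "rd_kappa1": {"A": 5.43000, "C": 6.78000, "D": 7.90000, "E": 8.90000, "F": 8.74390, "G": 4.43000, "H": 7.74373, "I": 8.43000, "K": 9.39000, "L": 8.43000, "M": 8.78000, "N": 7.90000, "P": 5.56459, "Q": 8.90000, "R": 10.70000, "S": 6.39000, "T": 7.39000, "V": 7.43000, "W": 9.73391, "Y": 9.53734},
    "rd_kappa2": {"A": 1.76763, "C": 2.87292, "D": 3.03231, "E": 3.83756, "F": 3.87520, "G": 1.72155, "H": 3.15650, "I": 3.45452, "K": 5.19660, "L": 3.45452, "M": 4.63927, "N": 3.03231, "P": 2.13200, "Q": 3.83756, "R": 5.36338, "S": 2.54399, "T": 2.63727, "V": 2.66781, "W": 3.74448, "Y": 3.90952},
    "rd_kappa3": {"A": 1.72155, "C": 2.47204, "D": 3.47971, "E": 3.84857, "F": 2.35865, "G": 3.43000, "H": 2.04749, "I": 2.46357, "K": 4.28669, "L": 3.96836, "M": 4.29414, "N": 3.47971, "P": 0.97958, "Q": 3.84857, "R": 5.48223, "S": 2.13212, "T": 1.90208, "V": 1.93032, "W": 1.84536, "Y": 2.75739},
    "rd_hall_kier_alpha": {"A": -0.57000, "C": -0.22000, "D": -1.10000, "E": -1.10000, "F": -1.35000, "G": -0.57000, "H": -1.36000, "I": -0.57000, "K": -0.61000, "L": -0.57000, "M": -0.22000, "N": -1.10000, "P": -0.57000, "Q": -1.10000, "R": -1.30000, "S": -0.61000, "T": -0.61000, "V": -0.57000, "W": -1.81000, "Y": -1.55000},
    "rd_qed": {"A": 0.45135, "C": 0.42438, "D": 0.45202, "E": 0.48598, "F": 0.69046, "G": 0.42117, "H": 0.54119, "I": 0.58395, "K": 0.45718, "L": 0.58395, "M": 0.59700, "N": 0.42394, "P": 0.49821, "Q": 0.45609, "R": 0.20028, "S": 0.39424, "T": 0.42510, "V": 0.53698, "W": 0.70058, "Y": 0.62772},
    "rd_csp3_count": {"A": 2.00000, "C": 2.00000, "D": 2.00000, "E": 3.00000, "F": 2.00000, "G": 1.00000, "H": 2.00000, "I": 5.00000, "K": 5.00000, "L": 5.00000, "M": 4.00000, "N": 2.00000, "P": 4.00000, "Q": 3.00000, "R": 4.00000, "S": 2.00000, "T": 3.00000, "V": 4.00000, "W": 2.00000, "Y": 2.00000},
    "rd_sulfur_count": {"A": 0.00000, "C": 1.00000, "D": 0.00000, "E": 0.00000, "F": 0.00000, "G": 0.00000, "H": 0.00000, "I": 0.00000, "K": 0.00000, "L": 0.00000, "M": 1.00000, "N": 0.00000, "P": 0.00000, "Q": 0.00000, "R": 0.00000, "S": 0.00000, "T": 0.00000, "V": 0.00000, "W": 0.00000, "Y": 0.00000},
    "rd_nitrogen_count": {"A": 1.00000, "C": 1.00000, "D": 1.00000, "E": 1.00000, "F": 1.00000, "G": 1.00000, "H": 3.00000, "I": 1.00000, "K": 2.00000, "L": 1.00000, "M": 1.00000, "N": 2.00000, "P": 1.00000, "Q": 2.00000, "R": 4.00000, "S": 1.00000, "T": 1.00000, "V": 1.00000, "W": 2.00000, "Y": 1.00000},
    "rd_oxygen_count": {"A": 2.00000, "C": 2.00000, "D": 4.00000, "E": 4.00000, "F": 2.00000, "G": 2.00000, "H": 2.00000, "I": 2.00000, "K": 2.00000, "L": 2.00000, "M": 2.00000, "N": 3.00000, "P": 2.00000, "Q": 3.00000, "R": 2.00000, "S": 3.00000, "T": 3.00000, "V": 2.00000, "W": 2.00000, "Y": 3.00000},
    "rd_max_abs_partial_charge": {"A": 0.48009, "C": 0.48006, "D": 0.48118, "E": 0.48123, "F": 0.48008, "G": 0.48030, "H": 0.48008, "I": 0.48008, "K": 0.48009, "L": 0.48009, "M": 0.48009, "N": 0.48008, "P": 0.48008, "Q": 0.48009, "R": 0.48009, "S": 0.48002, "T": 0.48001, "V": 0.48008, "W": 0.48008, "Y": 0.50797},
}

# --- package-defined composite tables (synthetic stand-ins) ------------------
# Simple rule-based side-chain charge at neutral pH.
CHARGE = {aa: (1.0 if aa in "KR" else 0.5 if aa == "H" else -1.0 if aa in "DE" else 0.0)
          for aa in ALPHABET}
_AROMATIC_SNORKEL = {aa: (1.0 if aa in "FWY" else 0.5 if aa == "H" else 0.0)
                     for aa in ALPHABET}

# EZ: 3-D membrane-insertion composite (synthetic stand-in for a published
# depth-dependent insertion potential): transfer hydrophobicity, interface
# preference (inverted Hopp-Woods hydrophilicity), aromatic "snorkeling".
EZ = {aa: (EISENBERG[aa], -HOPP_WOODS[aa], _AROMATIC_SNORKEL[aa]) for aa in ALPHABET}

# COUGAR: 6-D composite (synthetic stand-in): z1, hydrophobicity, charge,
# polarity, size (heavy atoms), backbone flexibility.
COUGAR = {
    aa: (Z3[aa][0], EISENBERG[aa], CHARGE[aa], GRANTHAM_POLARITY[aa],
         RDKIT_TABLES["rd_heavy_atoms"][aa], FLEXIBILITY[aa])
    for aa in ALPHABET
}

# ABHPRK: 7-D binary pharmacophore encoding (package-defined class scheme):
# acidic, basic, hydrophobic, polar, aromatic(ring), small, turn-forming.
_ABHPRK_CLASSES = ("DE", "KRH", "ACFILMVW", "NQSTYCH", "FWYH", "ACDGNPSTV", "GPNDS")
ABHPRK = {
    aa: tuple(1.0 if aa in cls else 0.0 for cls in _ABHPRK_CLASSES)
    for aa in ALPHABET
}

# Multidimensional tables with per-dimension names, consumed by the
# autocorrelation descriptor.  Layout (dims x lags) is pinned in the registry.
MULTI_SCALES = {
    "Z3": (("z1", "z2", "z3"), Z3),
    "Z5": (("z1", "z2", "z3", "z4", "z5"), Z5),
    "Ez": (("transfer", "interface", "snorkel"), EZ),
    "Cougar": (("z1", "hphob", "charge", "polarity", "size", "flex"), COUGAR),
    "ABHPRK": (("acid", "base", "hphob", "polar", "ring", "small", "turn"), ABHPRK),
}

# --- 1-D scale registry for the single-scale autocorrelation descriptors -----
# The 7 classic hydropathy/surface scales additionally expose the raw
# sequence-global mean (a GRAVY-style summary); the rest are lag-only.
SCALES_1D = {
    "KD": KYTE_DOOLITTLE,
    "HoppWoods": HOPP_WOODS,
    "Janin": JANIN,
    "Emini": EMINI_SURFACE,
    "Flex": FLEXIBILITY,
    "Eisenberg": EISENBERG,
    "GranthamPol": GRANTHAM_POLARITY,
    "CodonCount": {aa: float(v) for aa, v in CODON_COUNTS.items()},
    "CodonGC": CODON_GC,
}
SCALES_1D.update(RDKIT_TABLES)
GLOBAL_MEAN_SCALES = frozenset(
    {"KD", "HoppWoods", "Janin", "Emini", "Eisenberg", "rd_logp", "rd_tpsa"})

# --- CTD property groupings (13 properties x 3 groups) -----------------------
def _tertile_groups(table):
    """Split the 20 residues into low-7 / mid-6 / high-7 groups by a scale."""
    ranked = sorted(ALPHABET, key=lambda aa: (table[aa], aa))
    return ("".join(ranked[:7]), "".join(ranked[7:13]), "".join(ranked[13:]))

# Seven canonical property groupings (Dubchak-style), entered verbatim.
CTD_PROPERTIES = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdwvolume": ("GASTPD", "NVEQCIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
    # Six further hydrophobicity-flavoured properties, defined as tertile
    # splits of exact scales shipped above (package-defined groupings).
    "hydropathy_kd": _tertile_groups(KYTE_DOOLITTLE),
    "hydrophilicity_hw": _tertile_groups(HOPP_WOODS),
    "buriability_janin": _tertile_groups(JANIN),
    "surface_emini": _tertile_groups(EMINI_SURFACE),
    "hydrophobicity_eisenberg": _tertile_groups(EISENBERG),
    "logp_rdkit": _tertile_groups(RDKIT_TABLES["rd_logp"]),
}
assert len(CTD_PROPERTIES) == 13
for _g1, _g2, _g3 in CTD_PROPERTIES.values():
    assert sorted(_g1 + _g2 + _g3) == sorted(ALPHABET)


def standardized(table):
    """Return a scale table standardized to mean 0 / population std 1 over the
    20 residues (per dimension for multi-dimensional tables)."""
    arr = np.asarray([table[aa] for aa in AA_LIST], dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd[sd == 0] = 1.0
    out = (arr - mu) / sd
    return {aa: tuple(out[i]) for i, aa in enumerate(AA_LIST)}

# Two near-redundant tables are excluded from the descriptor registry
# (max |partial charge| is almost constant; valence electrons track weight).
del SCALES_1D["rd_max_abs_partial_charge"]
del SCALES_1D["rd_valence_electrons"]
assert len(SCALES_1D) == 37
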