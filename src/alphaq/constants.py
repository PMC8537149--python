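"""Element data tables used across the package.

Atomic weights are the IUPAC 2021 abridged standard atomic weights (amu).
Van der Waals radii are Bondi's compilation (Å); they are used only for
sizing the common grid box, never in any energy expression.
"""

from __future__ import annotations

# IUPAC 2021 abridged standard atomic weights, amu.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403, "Ne": 20.180,
    "Na": 22.989769, "Mg": 24.305, "Al": 26.981538, "Si": 28.085,
    "P": 30.973762, "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.098, "Ca": 40.078, "Fe": 55.845, "Cu": 63.546, "Zn": 65.38,
    "As": 74.921595, "Se": 78.971, "Br": 79.904, "Kr": 83.798,
    "I": 126.90447, "Xe": 131.29,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Fe": 26, "Cu": 29,
    "Zn": 30, "As": 33, "Se": 34, "Br": 35, "Kr": 36, "I": 53, "Xe": 54,
}

# Bondi van der Waals radii, Å; elements missing from Bondi's set fall
# back to DEFAULT_VDW_RADIUS.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02, "I": 1.98, "Xe": 2.16,
    "Zn": 1.39, "Cu": 1.40, "Na": 2.27, "K": 2.75, "Li": 1.82, "Mg": 1.73,
}

DEFAULT_VDW_RADIUS = 1.70

# Bohr radius in Å (CODATA), used by the Gaussian cube reader/writer.
BOHR_TO_ANGSTROM = 0.529177
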