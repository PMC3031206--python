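"""Idealized base geometries and nucleotide nomenclature tables.

The planar base templates below are expressed in the standard nucleic-acid
reference frame: the origin sits in the basepair plane, x points toward the
major groove along the pseudo two-fold axis of an ideal Watson-Crick pair,
y runs along the long axis of the pair toward the strand-1 backbone, and z
completes a right-handed triad pointing in the 5'->3' direction of the
parent strand.  The complementary base of an ideal pair is generated by a
180 degree rotation about x (y and z negated).  Coordinates are in
Angstrom; only heavy atoms of the base plus the glycosidic C1' are listed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STANDARD_BASES",
    "RING_ATOMS",
    "PURINES",
    "PYRIMIDINES",
    "COMPLEMENT",
    "RESIDUE_TO_BASE",
    "base_template",
    "ring_coordinates",
]

STANDARD_BASES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000),
        "N3": (-0.302, 2.397, 0.000),
        "C4": (0.989, 2.884, 0.000),
        "O4": (1.935, 2.094, -0.001),
        "C5": (1.089, 4.311, 0.000),
        "C6": (-0.024, 5.053, 0.000),
    },
}

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "T", "U"})

# Ring atoms used for least-squares frame fitting.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    base: ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
    if base in PURINES
    else ("N1", "C2", "N3", "C4", "C5", "C6")
    for base in STANDARD_BASES
}

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

# PDB residue names mapped to the parent base letter.  Covers the standard
# deoxy/ribo names plus modified bases common in nucleosome entries.
RESIDUE_TO_BASE: dict[str, str] = {
    "DA": "A", "DT": "T", "DG": "G", "DC": "C", "DU": "U",
    "A": "A", "T": "T", "G": "G", "C": "C", "U": "U",
    "ADE": "A", "THY": "T", "GUA": "G", "CYT": "C", "URA": "U",
    "DA5": "A", "DT5": "T", "DG5": "G", "DC5": "C",
    "DA3": "A", "DT3": "T", "DG3": "G", "DC3": "C",
    "5CM": "C", "5MC": "C", "C5M": "C", "6OG": "G", "8OG": "G",
    "5IU": "U", "BRU": "U", "UMS": "U", "5BU": "U",
}


def base_template(base: str) -> dict[str, np.ndarray]:
    """Standard-frame heavy-atom coordinates for one base (copy)."""
    try:
        table = STANDARD_BASES[base]
    except KeyError:
        raise KeyError(f"no template for base {base!r}") from None
    return {name: np.array(xyz, dtype=float) for name, xyz in table.items()}


def ring_coordinates(base: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Ring atom names and their template coordinates for frame fitting."""
    names = RING_ATOMS[base]
    table = STANDARD_BASES[base]
    return names, np.array([table[n] for n in names], dtype=float)
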