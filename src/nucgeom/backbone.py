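"""Backbone and glycosidic torsions and their conformational classification.

The phosphodiester linkage between nucleotides n and n+1 of one strand is
described by epsilon and zeta on the 5' side of the phosphate and alpha,
beta, gamma on its 3' side.  B-DNA backbones populate two substates
distinguished by the sign of epsilon - zeta: BI (<= 0, the canonical t,g-
arrangement) and BII (> 0, g-,t).  Combined with the alpha/gamma ranges the
linkage falls into one of seven discrete states (or none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import signed_dihedral, wrap_angle
from .io import NucleotideUnit

__all__ = [
    "TorsionSet",
    "BackboneState",
    "torsion_angles",
    "classify_bi_bii",
    "classify_state",
    "step_backbone_combo",
    "STATE_TABLE",
    "STATE_PRECEDENCE",
]


@dataclass
class TorsionSet:
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    chi: float | None = None
    pseudorotation_P: float | None = None

    @property
    def eps_minus_zeta(self) -> float | None:
        if self.epsilon is None or self.zeta is None:
            return None
        return float(wrap_angle(self.epsilon - self.zeta))


@dataclass
class BackboneState:
    bi_bii: str | None
    state: int | None
    linkage: str
    torsions: TorsionSet


def _torsion360(*coords) -> float | None:
    if any(c is None for c in coords):
        return None
    return float(np.mod(signed_dihedral(*coords), 360.0))


def _pseudorotation(nt: NucleotideUnit) -> float | None:
    names = ("C4'", "O4'", "C1'", "C2'", "C3'")
    c = {n: nt.coord(n) for n in names}
    if any(v is None for v in c.values()):
        return None
    ring = [c["C4'"], c["O4'"], c["C1'"], c["C2'"], c["C3'"]]
    # endocyclic torsions nu0..nu4 starting at C4'-O4'-C1'-C2'
    nu = [
        signed_dihedral(ring[i], ring[(i + 1) % 5], ring[(i + 2) % 5], ring[(i + 3) % 5])
        for i in range(5)
    ]
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = 2.0 * nu[2] * (np.sin(np.deg2rad(36.0)) + np.sin(np.deg2rad(72.0)))
    return float(np.mod(np.rad2deg(np.arctan2(num, den)), 360.0))


def _chi360(nt: NucleotideUnit) -> float | None:
    names = ("O4'", "C1'", "N9", "C4") if nt.is_purine else ("O4'", "C1'", "N1", "C2")
    return _torsion360(*(nt.coord(n) for n in names))


def torsion_angles(nt: NucleotideUnit, nt_next: NucleotideUnit) -> TorsionSet:
    """Torsions for the phosphodiester linkage nt -> nt_next (same strand).

    epsilon and zeta belong to ``nt``'s 3' side; alpha, beta and gamma to
    ``nt_next``; delta, chi and the sugar pseudorotation P are reported for
    ``nt_next``.  Angles are mapped to [0, 360); missing atoms leave the
    corresponding angle unset.
    """
    c4, c3, o3 = (nt.coord(n) for n in ("C4'", "C3'", "O3'"))
    p1, o5_1, c5_1, c4_1, c3_1 = (
        nt_next.coord(n) for n in ("P", "O5'", "C5'", "C4'", "C3'")
    )
    return TorsionSet(
        epsilon=_torsion360(c4, c3, o3, p1),
        zeta=_torsion360(c3, o3, p1, o5_1),
        alpha=_torsion360(o3, p1, o5_1, c5_1),
        beta=_torsion360(p1, o5_1, c5_1, c4_1),
        gamma=_torsion360(o5_1, c5_1, c4_1, c3_1),
        delta=_torsion360(
            nt_next.coord("C5'"), c4_1, c3_1, nt_next.coord("O3'")
        ),
        chi=_chi360(nt_next),
        pseudorotation_P=_pseudorotation(nt_next),
    )


def classify_bi_bii(eps_minus_zeta: float) -> str:
    """BI for epsilon - zeta <= 0, BII for > 0 (value wrapped to (-180, 180])."""
    return "BI" if eps_minus_zeta <= 0.0 else "BII"


# (alpha range, gamma ranges, required BI/BII or None for either), by state.
STATE_TABLE: dict[int, tuple[tuple[float, float], tuple[tuple[float, float], ...], str | None]] = {
    1: ((150.0, 360.0), ((0.0, 125.0), (270.0, 360.0)), "BI"),
    2: ((220.0, 360.0), ((125.0, 270.0),), None),
    3: ((0.0, 220.0), ((125.0, 240.0),), "BII"),
    4: ((0.0, 150.0), ((0.0, 125.0),), None),
    5: ((0.0, 220.0), ((125.0, 240.0),), "BI"),
    6: ((0.0, 220.0), ((240.0, 270.0),), None),
    7: ((150.0, 360.0), ((0.0, 125.0), (270.0, 360.0)), "BII"),
}

# Rows with a specific BI/BII requirement take precedence over wildcard rows
# sharing the same angular ranges.
STATE_PRECEDENCE = (1, 7, 2, 3, 5, 4, 6)


def _in_ranges(value: float, ranges: tuple[tuple[float, float], ...]) -> bool:
    v = np.mod(value, 360.0)
    return any(lo <= v < hi or (hi == 360.0 and v == 0.0 and lo == 0.0) for lo, hi in ranges)


def classify_state(alpha: float, gamma: float, bi_bii: str) -> int | None:
    """Seven-state classification of a linkage from alpha, gamma and BI/BII.

    Ranges are half-open [lo, hi) with 360 wrapping to 0; combinations not
    covered by any row return None (unclassified).
    """
    a = np.mod(alpha, 360.0)
    g = np.mod(gamma, 360.0)
    for state in STATE_PRECEDENCE:
        a_range, g_ranges, required = STATE_TABLE[state]
        if not _in_ranges(a, (a_range,)):
            continue
        if not _in_ranges(g, g_ranges):
            continue
        if required is not None and required != bi_bii:
            continue
        return state
    return None


def step_backbone_combo(s1: "BackboneState | str", s2: "BackboneState | str") -> str | None:
    """Unordered BI/BII combination of the two linkages flanking a step."""
    flags = []
    for s in (s1, s2):
        flag = s if isinstance(s, str) or s is None else s.bi_bii
        if flag not in ("BI", "BII"):
            return None
        flags.append(flag)
    n_bii = sum(f == "BII" for f in flags)
    return ("BI/BI", "BI/BII", "BII/BII")[n_bii]
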