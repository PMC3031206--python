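"""Reference frames for bases and basepairs, and intra-basepair parameters.

A base frame is obtained by least-squares superposition of the idealized
planar base template (see :mod:`nucgeom.templates`) onto the observed ring
atoms.  The basepair frame is the mid frame between the strand-1 frame and
the strand-2 frame flipped into the strand-1 sense (y and z negated).
Buckle, propeller and opening are the relative rotation of the flipped
strand-2 frame with respect to the strand-1 frame decomposed symmetrically
about the pair x, y and z axes; they quantify basepair non-planarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import decompose_frames, orthonormalize, superpose
from .io import BasePairUnit, NucleotideUnit
from .templates import ring_coordinates

__all__ = [
    "ReferenceFrame",
    "BasePairGeometry",
    "fit_base_frame",
    "basepair_frame",
    "basepair_parameters",
    "FLIP",
]

# Strand-2 flip into the strand-1 sense: negate y and z axes.
FLIP = np.diag([1.0, -1.0, -1.0])


@dataclass
class ReferenceFrame:
    origin: np.ndarray
    triad: np.ndarray  # columns are the x, y, z unit vectors
    fit_rmsd: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.triad = np.asarray(self.triad, dtype=float)

    @property
    def x_axis(self) -> np.ndarray:
        return self.triad[:, 0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.triad[:, 1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.triad[:, 2]

    def flipped(self) -> "ReferenceFrame":
        return ReferenceFrame(self.origin.copy(), self.triad @ FLIP, self.fit_rmsd)


@dataclass
class BasePairGeometry:
    buckle: float
    propeller: float
    opening: float
    chi1: float | None
    chi2: float | None
    c1c1_dist: float | None
    c8c6_dist: float | None


def fit_base_frame(nt: NucleotideUnit, rmsd_warn: float = 1.0) -> ReferenceFrame:
    """Fit the standard base template to the observed ring atoms.

    Returns the template frame carried onto the structure by the rigid
    superposition; the fit RMSD is recorded on the frame.  Fails if fewer
    than 3 ring atoms are present; warns if the fit RMSD exceeds
    ``rmsd_warn`` (a distorted or misassigned base).
    """
    names, template = ring_coordinates(nt.base)
    observed, used = [], []
    for name, txyz in zip(names, template):
        xyz = nt.coord(name)
        if xyz is not None:
            observed.append(xyz)
            used.append(txyz)
    if len(observed) < 3:
        raise ValueError(
            f"base {nt.base} {nt.chain_id}{nt.residue_seq}: "
            f"only {len(observed)} ring atoms present, need >= 3"
        )
    rot, shift, rmsd = superpose(np.array(used), np.array(observed))
    if rmsd > rmsd_warn:
        warnings.warn(
            f"base frame fit RMSD {rmsd:.2f} A for "
            f"{nt.base} {nt.chain_id}{nt.residue_seq}"
        )
    return ReferenceFrame(origin=shift, triad=rot, fit_rmsd=rmsd)


def basepair_frame(f1: ReferenceFrame, f2: ReferenceFrame) -> ReferenceFrame:
    """Mid frame of a basepair from its two base frames.

    The strand-2 frame is flipped to the strand-1 sense first; the result is
    the half-rotation average of the triads with the origins averaged.
    """
    f2f = f2.flipped()
    if f1.z_axis @ f2f.z_axis < 0.0:
        warnings.warn("base frames anti-aligned after flipping (non-WC geometry)")
    _, _, om, tm = decompose_frames(f1.triad, f2f.triad, f1.origin, f2f.origin)
    return ReferenceFrame(origin=om, triad=orthonormalize(tm))


def _chi(nt: NucleotideUnit) -> float | None:
    from ._geometry import signed_dihedral

    names = ("O4'", "C1'", "N9", "C4") if nt.is_purine else ("O4'", "C1'", "N1", "C2")
    coords = [nt.coord(n) for n in names]
    if any(c is None for c in coords):
        return None
    return signed_dihedral(*coords)


def basepair_parameters(
    pair: BasePairUnit,
    f1: ReferenceFrame | None = None,
    f2: ReferenceFrame | None = None,
) -> BasePairGeometry:
    """Intra-basepair rotational parameters and companion distances.

    chi is the glycosidic torsion O4'-C1'-N9-C4 (purine) or O4'-C1'-N1-C2
    (pyrimidine); the C1'-C1' and C8-C6 separations use the purine C8 and
    pyrimidine C6 atoms.
    """
    if f1 is None:
        f1 = fit_base_frame(pair.nt1)
    if f2 is None:
        f2 = fit_base_frame(pair.nt2)
    f2f = f2.flipped()
    rotations, _, _, _ = decompose_frames(f1.triad, f2f.triad, f1.origin, f2f.origin)
    buckle, propeller, opening = rotations

    c1_1, c1_2 = pair.nt1.coord("C1'"), pair.nt2.coord("C1'")
    c1c1 = float(np.linalg.norm(c1_1 - c1_2)) if c1_1 is not None and c1_2 is not None else None

    def edge_atom(nt: NucleotideUnit) -> np.ndarray | None:
        return nt.coord("C8") if nt.is_purine else nt.coord("C6")

    e1, e2 = edge_atom(pair.nt1), edge_atom(pair.nt2)
    c8c6 = float(np.linalg.norm(e1 - e2)) if e1 is not None and e2 is not None else None

    return BasePairGeometry(
        buckle=float(buckle),
        propeller=float(propeller),
        opening=float(opening),
        chi1=_chi(pair.nt1),
        chi2=_chi(pair.nt2),
        c1c1_dist=c1c1,
        c8c6_dist=c8c6,
    )
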