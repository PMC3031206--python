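"""Dinucleotide step geometry: the six step parameters, Zp and helix axes.

Tilt, roll and twist measure the rotation between consecutive basepair
frames about the mid-step x, y and z directions; shift, slide and rise are
the origin displacement projected on the same mid-step frame.  Zp, the mean
z-coordinate of the step's backbone phosphates in the mid-step frame,
discriminates A-like (> 1.3 A) from B-like (<= 0.8 A) local geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import decompose_frames
from .frames import ReferenceFrame
from .io import BasePairUnit
from .templates import COMPLEMENT

__all__ = [
    "StepGeometry",
    "STEP_CLASSES",
    "canonical_step_class",
    "step_parameters",
    "zp",
    "classify_zp",
    "local_helix_axis",
    "successive_bending_angle",
]

# The ten canonical dinucleotide classes, in conventional order: a
# dinucleotide and its reverse complement belong to the same class.
STEP_CLASSES = (
    "AA/TT", "AG/CT", "GA/TC", "GG/CC", "AC/GT",
    "AT/AT", "GC/GC", "CA/TG", "CG/CG", "TA/TA",
)

_CLASS_BY_DINUC: dict[str, str] = {}
for label in STEP_CLASSES:
    fwd = label.split("/")[0]
    rc = COMPLEMENT[fwd[1]] + COMPLEMENT[fwd[0]]
    _CLASS_BY_DINUC[fwd] = label
    _CLASS_BY_DINUC[rc] = label


@dataclass
class StepGeometry:
    tilt: float
    roll: float
    twist: float
    shift: float
    slide: float
    rise: float
    zp: float | None = None
    local_axis: np.ndarray | None = None
    step_class: str | None = None
    dinuc: str | None = None
    is_terminal: bool = False
    mid_origin: np.ndarray | None = None
    mid_triad: np.ndarray | None = None


def canonical_step_class(dinuc: str) -> str:
    """Canonical class of a strand-1 dinucleotide (e.g. 'TG' -> 'CA/TG')."""
    key = dinuc.upper()
    if key not in _CLASS_BY_DINUC:
        raise ValueError(f"invalid dinucleotide {dinuc!r}; expected two of ACGT")
    return _CLASS_BY_DINUC[key]


def step_parameters(bp_i: ReferenceFrame, bp_i1: ReferenceFrame) -> StepGeometry:
    """Six step parameters between two consecutive basepair frames."""
    rotations, translations, om, tm = decompose_frames(
        bp_i.triad, bp_i1.triad, bp_i.origin, bp_i1.origin
    )
    tilt, roll, twist = rotations
    shift, slide, rise = translations
    if bp_i.z_axis @ bp_i1.z_axis < 0.0:
        warnings.warn("step frames anti-aligned; parameters are ill-conditioned")
    return StepGeometry(
        tilt=float(tilt),
        roll=float(roll),
        twist=float(twist),
        shift=float(shift),
        slide=float(slide),
        rise=float(rise),
        mid_origin=om,
        mid_triad=tm,
    )


def zp(
    step: StepGeometry,
    bp_i: BasePairUnit,
    bp_i1: BasePairUnit,
    convention: str = "linkage",
) -> float | None:
    """Mean phosphate z-coordinate in the mid-step frame.

    ``convention='linkage'`` (default, the published convention) uses the
    two phosphodiester phosphates bridging the step: on each strand the
    phosphate of the nucleotide on the step's 3' side, i.e. the strand-1 P
    of the 3' basepair and the strand-2 P of the 5' basepair.
    ``convention='pair3'`` instead takes both phosphates of the 3'-side
    basepair.  Returns None when a phosphate is missing, in which case the
    step is excluded from Zp tallies.
    """
    if convention == "pair3":
        p_atoms = [bp_i1.nt1.coord("P"), bp_i1.nt2.coord("P")]
    elif convention == "linkage":
        p_atoms = [bp_i1.nt1.coord("P"), bp_i.nt2.coord("P")]
    else:
        raise ValueError(f"unknown Zp convention {convention!r}")
    if any(p is None for p in p_atoms):
        return None
    z_axis = step.mid_triad[:, 2]
    z1 = float(z_axis @ (p_atoms[0] - step.mid_origin))
    # The strand-2 phosphate is measured in its own strand sense (the step
    # dyad flips z), otherwise the two contributions cancel by symmetry.
    z2 = -float(z_axis @ (p_atoms[1] - step.mid_origin))
    return 0.5 * (z1 + z2)


def classify_zp(zp_value: float, a_cutoff: float = 1.3, b_cutoff: float = 0.8) -> str:
    """A/B classification from Zp: > 1.3 A A-like, <= 0.8 A B-like."""
    if not np.isfinite(zp_value):
        raise ValueError("Zp must be finite")
    if zp_value > a_cutoff:
        return "A-like"
    if zp_value <= b_cutoff:
        return "B-like"
    return "intermediate"


def local_helix_axis(bp_i: ReferenceFrame, bp_i1: ReferenceFrame) -> np.ndarray:
    """Local helix axis of a step.

    Defined as the normalized cross product of the differences of the x and
    y vectors of the two basepair frames, with the sign chosen to point
    toward increasing basepair index.  A pure translation leaves the
    differences degenerate; the mid-frame z axis is returned instead.
    """
    dx = bp_i1.x_axis - bp_i.x_axis
    dy = bp_i1.y_axis - bp_i.y_axis
    axis = np.cross(dx, dy)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        warnings.warn("degenerate local helix axis (pure translation); using mid-frame z")
        _, _, _, tm = decompose_frames(bp_i.triad, bp_i1.triad, bp_i.origin, bp_i1.origin)
        return tm[:, 2].copy()
    axis = axis / norm
    disp = bp_i1.origin - bp_i.origin
    reference = disp if np.linalg.norm(disp) > 1e-9 else bp_i.z_axis
    if axis @ reference < 0.0:
        axis = -axis
    return axis


def successive_bending_angle(axis_i: np.ndarray, axis_i1: np.ndarray) -> float:
    """Unsigned angle in degrees between consecutive local helix axes."""
    a = np.asarray(axis_i, float)
    b = np.asarray(axis_i1, float)
    cosang = np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(cosang)))
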