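"""Synthetic full-atom DNA duplex construction from prescribed parameters.

This is the analysis inverse: basepair frames are generated by composing
step transforms under the same mid-frame convention the analysis uses, so
that re-analysing a noiseless synthetic duplex returns the input parameters
to machine precision.  Base atoms are placed rigidly from the standard-frame
templates; sugar and backbone atoms are constructed from B-DNA internal
coordinates (C2'-endo sugar, anti glycosidic torsion) with the phosphate of
each 3' linkage placed at an explicit epsilon/zeta pair, so BI and BII
backbone variants are exact template properties.

Synthetic duplexes emulate the nucleosome core particle study conditions:
145-147 bp, a left-handed superhelical wrap of radius ~42 A with a helical
period just over 10 steps, sinusoidal roll/slide modulation phased to the
superhelix location, and optional injected kinks.  They do not emulate
sequence-dependent fine structure, thermal disorder or protein contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from ._geometry import compose_frames, half_rotation, nerf_place
from .frames import FLIP
from .io import AtomRecord, BasePairUnit, DuplexModel, NucleotideUnit, assign_shl, write_pdb
from .templates import COMPLEMENT, PURINES, base_template

__all__ = [
    "BACKBONE_VARIANTS",
    "DuplexParameterSpec",
    "nucleotide_template",
    "rebuild_coordinates",
    "generate_nucleosome_like",
    "inject_kinks",
    "mixed_ab_spec",
    "straight_bdna_spec",
    "write_pdb",
]

# Internal coordinates of the three backbone conformers.  BI is the
# canonical B-DNA epsilon/zeta = t/g- arrangement, BII the g-/t swap with
# the same C2'-endo sugar, and A the C3'-endo A-form conformer.  Each set
# was calibrated once (design-time least squares) against an ideal helix of
# the corresponding form so that the assembled backbone is continuous
# (O5'-C5' ~1.45 A), the linkage torsions are canonical, and the bridging
# phosphate sits at the published mid-step position for that form
# (B: zp ~ 0.4 A; A: zp ~ 2.2 A).
_CONFORMERS: dict[str, dict[str, float]] = {
    "BI": dict(chi=252.99, o3_wedge=110.88, c5_wedge=-135.78, tau=35.92,
               pucker=181.99, ang_n_c1_o4=101.87, eps=181.79, zeta=256.84),
    "A": dict(chi=202.54, o3_wedge=111.90, c5_wedge=-122.11, tau=36.78,
              pucker=24.77, ang_n_c1_o4=108.59, eps=200.61, zeta=288.21),
}
_CONFORMERS["BII"] = dict(_CONFORMERS["BI"], eps=_CONFORMERS["BI"]["zeta"],
                          zeta=_CONFORMERS["BI"]["eps"])
BACKBONE_VARIANTS = tuple(_CONFORMERS)


@lru_cache(maxsize=None)
def nucleotide_template(base: str, variant: str = "BI") -> dict[str, np.ndarray]:
    """Heavy-atom template of one nucleotide in the standard base frame.

    Contains the base, the sugar ring, O3' and C5', plus the atoms of the
    3'-side phosphodiester linkage (P, O5' and the two OP oxygens of the
    *next* residue, stored as ``P+``, ``O5'+``, ``OP1+``, ``OP2+``), so that
    epsilon and zeta are internal template properties set by ``variant``
    (BI, BII or the A-form conformer).
    """
    if variant not in _CONFORMERS:
        raise ValueError(
            f"backbone variant must be one of {BACKBONE_VARIANTS}, got {variant!r}"
        )
    c = _CONFORMERS[variant]
    chi = c["chi"]

    def sugar_nu(j: int) -> float:
        return c["tau"] * np.cos(np.deg2rad(c["pucker"] + 144.0 * (j - 2)))

    atoms = base_template(base)
    n_g, c_g = ("N9", "C4") if base in PURINES else ("N1", "C2")
    c1 = atoms["C1'"]
    ng, cg = atoms[n_g], atoms[c_g]

    # O4' placement fixes the glycosidic torsion chi = O4'-C1'-N-C.
    atoms["O4'"] = nerf_place(cg, ng, c1, 1.420, c["ang_n_c1_o4"], chi)

    nu1, nu2, nu3 = sugar_nu(1), sugar_nu(2), sugar_nu(3)

    def ring_from(wedge: float) -> dict[str, np.ndarray]:
        c2 = nerf_place(cg, ng, c1, 1.519, 113.7, chi + wedge)
        c3 = nerf_place(atoms["O4'"], c1, c2, 1.516, 101.8, nu1)
        c4 = nerf_place(c1, c2, c3, 1.529, 102.6, nu2)
        return {"C2'": c2, "C3'": c3, "C4'": c4}

    # The C2' wedge about the glycosidic bond is solved so the five-ring
    # closes back onto O4' at the ideal C4'-O4' bond length; the negative
    # branch selects the natural D-deoxyribose configuration.
    def closure(wedge: float) -> float:
        ring = ring_from(wedge)
        return float(np.linalg.norm(ring["C4'"] - atoms["O4'"]) - 1.446)

    wedge = brentq(closure, -175.0, -65.0, xtol=1e-10)
    atoms.update(ring_from(float(wedge)))

    c1p, c2p, c3p, c4p = (atoms[k] for k in ("C1'", "C2'", "C3'", "C4'"))
    atoms["O3'"] = nerf_place(c1p, c2p, c3p, 1.423, 110.3, nu2 + c["o3_wedge"])
    atoms["C5'"] = nerf_place(c2p, c3p, c4p, 1.510, 114.7, nu3 + c["c5_wedge"])

    eps, zeta = c["eps"], c["zeta"]
    o3p = atoms["O3'"]
    p_next = nerf_place(c4p, c3p, o3p, 1.607, 119.7, eps)
    o5_next = nerf_place(c3p, o3p, p_next, 1.593, 104.0, zeta)
    atoms["P+"] = p_next
    atoms["O5'+"] = o5_next
    atoms["OP1+"] = nerf_place(c3p, o3p, p_next, 1.485, 108.1, zeta + 119.6)
    atoms["OP2+"] = nerf_place(c3p, o3p, p_next, 1.485, 108.1, zeta - 119.6)
    return {k: np.asarray(v, dtype=float) for k, v in atoms.items()}


@dataclass
class DuplexParameterSpec:
    """Complete parametric description of a synthetic duplex."""

    sequence: str
    tilt: np.ndarray = None
    roll: np.ndarray = None
    twist: np.ndarray = None
    shift: np.ndarray = None
    slide: np.ndarray = None
    rise: np.ndarray = None
    buckle: np.ndarray = None
    propeller: np.ndarray = None
    opening: np.ndarray = None
    backbone_strand1: list[str] = None
    backbone_strand2: list[str] = None
    noise_sigma_angles: float = 0.0
    noise_sigma_disp: float = 0.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 2:
            raise ValueError("sequence must have at least 2 basepairs")
        if any(b not in COMPLEMENT for b in self.sequence):
            raise ValueError("sequence must be over ACGTU")
        step_defaults = {
            "tilt": 0.0, "roll": 0.0, "twist": 36.0,
            "shift": 0.0, "slide": 0.0, "rise": 3.4,
        }
        for namep, default in step_defaults.items():
            value = getattr(self, namep)
            arr = (np.full(n - 1, default) if value is None
                   else np.asarray(value, dtype=float))
            if arr.shape != (n - 1,):
                raise ValueError(f"{namep} must have length {n - 1}")
            setattr(self, namep, arr)
        for namep in ("buckle", "propeller", "opening"):
            value = getattr(self, namep)
            arr = np.zeros(n) if value is None else np.asarray(value, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{namep} must have length {n}")
            setattr(self, namep, arr)
        for attr in ("backbone_strand1", "backbone_strand2"):
            value = getattr(self, attr)
            if value is None:
                value = ["BI"] * n
            if len(value) != n or any(v not in _CONFORMERS for v in value):
                raise ValueError(
                    f"{attr} must list one of {BACKBONE_VARIANTS} per basepair"
                )
            setattr(self, attr, list(value))

    @property
    def n_bp(self) -> int:
        return len(self.sequence)


def _make_unit(
    base: str,
    template: dict[str, np.ndarray],
    origin: np.ndarray,
    triad: np.ndarray,
    strand: int,
    position: int,
) -> tuple[NucleotideUnit, dict[str, np.ndarray]]:
    """Place one nucleotide; returns the unit and its lab-frame 3' linkage."""
    own, extension = {}, {}
    for name, xyz in template.items():
        lab = origin + triad @ xyz
        if name.endswith("+"):
            extension[name[:-1]] = lab
        else:
            own[name] = lab

    def record(name: str, xyz: np.ndarray) -> AtomRecord:
        return AtomRecord(
            name=name, element=name.strip("0123456789+'")[0], coords=xyz,
            residue_name=f"D{base}", residue_seq=position, chain_id="AB"[strand - 1],
        )

    atoms = {name: record(name, xyz) for name, xyz in own.items()}
    unit = NucleotideUnit(
        base=base, strand_index=strand, position_in_strand=position,
        atoms=atoms, residue_name=f"D{base}", residue_seq=position,
        chain_id="AB"[strand - 1],
    )
    return unit, extension


def rebuild_coordinates(spec: DuplexParameterSpec) -> DuplexModel:
    """Build full-atom duplex coordinates from a parameter specification.

    Basepair frames are chained with the step transforms; each base is
    placed by splitting the intra-pair rotation symmetrically between the
    two strands, so both step and basepair parameters are exactly
    recoverable by the analysis.  Gaussian parameter noise (if requested)
    is applied before construction using the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bp
    tilt, roll, twist = spec.tilt.copy(), spec.roll.copy(), spec.twist.copy()
    shift, slide, rise = spec.shift.copy(), spec.slide.copy(), spec.rise.copy()
    buckle, propeller, opening = (
        spec.buckle.copy(), spec.propeller.copy(), spec.opening.copy()
    )
    if spec.noise_sigma_angles > 0:
        for arr in (tilt, roll, twist):
            arr += rng.normal(0.0, spec.noise_sigma_angles, n - 1)
        for arr in (buckle, propeller, opening):
            arr += rng.normal(0.0, spec.noise_sigma_angles, n)
    if spec.noise_sigma_disp > 0:
        for arr in (shift, slide, rise):
            arr += rng.normal(0.0, spec.noise_sigma_disp, n - 1)

    origins = [np.zeros(3)]
    triads = [np.eye(3)]
    for k in range(n - 1):
        o2, t2 = compose_frames(
            triads[-1], origins[-1],
            [tilt[k], roll[k], twist[k]], [shift[k], slide[k], rise[k]],
        )
        origins.append(o2)
        triads.append(t2)

    units1: list[NucleotideUnit] = []
    units2: list[NucleotideUnit] = []
    ext1: list[dict[str, np.ndarray]] = []
    ext2: list[dict[str, np.ndarray]] = []
    for k in range(n):
        base1 = spec.sequence[k]
        base2 = COMPLEMENT[base1]
        _, rel = compose_frames(
            np.eye(3), np.zeros(3),
            [buckle[k], propeller[k], opening[k]], [0.0, 0.0, 0.0],
        )
        half = half_rotation(rel)
        t_s1 = triads[k] @ half.T
        t_s2 = (triads[k] @ half) @ FLIP
        u1, e1 = _make_unit(
            base1, nucleotide_template(base1, spec.backbone_strand1[k]),
            origins[k], t_s1, 1, k + 1,
        )
        u2, e2 = _make_unit(
            base2, nucleotide_template(base2, spec.backbone_strand2[k]),
            origins[k], t_s2, 2, n - k,
        )
        units1.append(u1)
        units2.append(u2)
        ext1.append(e1)
        ext2.append(e2)

    # Attach each linkage's phosphate group to its 3'-side residue.
    def attach(unit: NucleotideUnit, extension: dict[str, np.ndarray]) -> None:
        for name, xyz in extension.items():
            unit.atoms[name] = AtomRecord(
                name=name, element="P" if name == "P" else "O", coords=xyz,
                residue_name=unit.residue_name, residue_seq=unit.residue_seq,
                chain_id=unit.chain_id,
            )

    for k in range(1, n):
        attach(units1[k], ext1[k - 1])     # strand 1 runs 5'->3' with k
    for k in range(n - 1):
        attach(units2[k], ext2[k + 1])     # strand 2 runs 5'->3' against k

    pairs = [
        BasePairUnit(nt1=units1[k], nt2=units2[k], watson_crick=True)
        for k in range(n)
    ]
    duplex = DuplexModel(structure_id=spec.name, basepairs=pairs)
    return assign_shl(duplex)


# Preset matching the nucleosome core particle geometry: helical period just
# over 10 steps and a roll modulation whose net bend closes a superhelix of
# radius ~42 A.  The roll amplitude is set by the ring-closure condition
# (one full 360-deg bend per ~77 bp of superhelical circumference).
_NUCLEOSOME_PRESET = {
    "period": 10.2,
    "roll_amplitude": 9.3,
    "twist_base": 360.0 / 10.2,
    "rise": 3.4,
    "slide_mean": 0.2,
    "slide_amplitude": 0.35,
    "propeller": -12.0,
}


def generate_nucleosome_like(
    n_bp: int = 147,
    preset: dict | None = None,
    name: str | None = None,
    seed: int = 0,
) -> DuplexParameterSpec:
    """Parameter spec for a nucleosome-like superhelical duplex.

    Roll is modulated sinusoidally and phased to the superhelix location so
    that minor-groove-in regions (around SHL +-i.5) carry negative roll and
    major-groove-in regions (around integral SHL) positive roll; slide
    tracks the same phase.  The default period (10.2 steps) and roll
    amplitude reproduce a left-handed wrap with radius of curvature in the
    40-45 A band over 36-mer windows.
    """
    if n_bp not in (145, 146, 147):
        raise ValueError("nucleosome-like duplexes are 145-147 bp")
    p = dict(_NUCLEOSOME_PRESET)
    if preset:
        p.update(preset)
    rng = np.random.default_rng(seed)
    # alpha-satellite-like base composition
    sequence = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3]) for _ in range(n_bp))
    dyad = 73 if n_bp == 146 else (n_bp + 1) // 2
    step_pos = np.arange(n_bp - 1) + 1 - dyad + 0.5  # mid-step dyad offset
    phase = 2.0 * np.pi * step_pos / p["period"]
    roll = p["roll_amplitude"] * np.cos(phase)
    slide = p["slide_mean"] + p["slide_amplitude"] * np.cos(phase)
    twist = np.full(n_bp - 1, p["twist_base"])
    return DuplexParameterSpec(
        sequence=sequence,
        roll=roll,
        twist=twist,
        slide=slide,
        rise=np.full(n_bp - 1, p["rise"]),
        propeller=np.full(n_bp, p["propeller"]),
        seed=seed,
        name=name or f"synthetic-ncp-{n_bp}",
    )


def straight_bdna_spec(
    sequence: str, name: str = "synthetic-bdna", seed: int = 0
) -> DuplexParameterSpec:
    """Canonical straight B-DNA: twist 36 deg, rise 3.4 A, all else zero."""
    return DuplexParameterSpec(sequence=sequence, seed=seed, name=name)


def mixed_ab_spec(
    labels: "list[str] | str",
    seed: int = 0,
    name: str = "synthetic-mixed-ab",
) -> DuplexParameterSpec:
    """Duplex mixing A-form and B-form steps, for Zp discrimination studies.

    ``labels`` assigns 'A' or 'B' to every step (length n-1).  A-form steps
    take A-like step parameters (twist 31, roll 10, slide -1.8, rise 3.3)
    and the A backbone conformer on the flanking nucleotides whose
    phosphates bridge the step; B steps take canonical B values.  Small
    seeded jitter decorrelates roll from the A/B labels.
    """
    labels = list(labels)
    if any(l not in ("A", "B") for l in labels):
        raise ValueError("labels must be 'A' or 'B' per step")
    n = len(labels) + 1
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list("ACGT")) for _ in range(n))
    is_a = np.array([l == "A" for l in labels])
    twist = np.where(is_a, 31.0, 36.0) + rng.normal(0, 1.0, n - 1)
    roll = np.where(is_a, 10.0, 2.0) + rng.normal(0, 6.0, n - 1)
    slide = np.where(is_a, -1.8, 0.2) + rng.normal(0, 0.2, n - 1)
    rise = np.where(is_a, 3.3, 3.4) + rng.normal(0, 0.05, n - 1)
    # the step's bridging phosphates come from the 5' basepair's strand-1
    # nucleotide and the 3' basepair's strand-2 nucleotide
    bb1 = ["BI"] * n
    bb2 = ["BI"] * n
    for k, l in enumerate(labels):
        if l == "A":
            bb1[k] = "A"
            bb2[k + 1] = "A"
    return DuplexParameterSpec(
        sequence=sequence, twist=twist, roll=roll, slide=slide, rise=rise,
        backbone_strand1=bb1, backbone_strand2=bb2, seed=seed, name=name,
    )


def inject_kinks(
    spec: DuplexParameterSpec,
    positions: list[int],
    roll_deltas: list[float] | float = 0.0,
    tilt_deltas: list[float] | float = 0.0,
) -> DuplexParameterSpec:
    """Add tilt/roll deviations at the named step indices (0-based).

    Positions must refer to non-terminal steps; deltas may be scalars or
    per-position lists.  Returns a new spec, the input is left untouched.
    """
    n_steps = spec.n_bp - 1
    roll_d = np.broadcast_to(np.asarray(roll_deltas, float), (len(positions),))
    tilt_d = np.broadcast_to(np.asarray(tilt_deltas, float), (len(positions),))
    roll = spec.roll.copy()
    tilt = spec.tilt.copy()
    for pos, rd, td in zip(positions, roll_d, tilt_d):
        if not 1 <= pos <= n_steps - 2:
            raise ValueError(
                f"step index {pos} is terminal or out of range (1..{n_steps - 2})"
            )
        roll[pos] += rd
        tilt[pos] += td
    return replace(spec, roll=roll, tilt=tilt)
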