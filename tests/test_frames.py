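"""Base-frame fitting and intra-basepair parameters."""

import numpy as np
import pytest

from nucgeom._geometry import rotation_about
from nucgeom.builder import DuplexParameterSpec, rebuild_coordinates
from nucgeom.frames import basepair_frame, basepair_parameters, fit_base_frame
from nucgeom.io import AtomRecord, NucleotideUnit
from nucgeom.templates import STANDARD_BASES, ring_coordinates


def nucleotide_from_template(base, rot=np.eye(3), shift=np.zeros(3), jitter=None):
    atoms = {}
    for name, xyz in STANDARD_BASES[base].items():
        coords = rot @ np.asarray(xyz) + shift
        if jitter is not None:
            coords = coords + jitter[name]
        atoms[name] = AtomRecord(name, name[0], coords, f"D{base}", 1, "A")
    return NucleotideUnit(base=base, strand_index=1, position_in_strand=1, atoms=atoms)


def quaternion_superpose(mobile, target):
    """Independent superposition oracle (Horn's quaternion method)."""
    pm = mobile - mobile.mean(axis=0)
    pt = target - target.mean(axis=0)
    m = pm.T @ pt
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(k)
    w, x, y, z = vecs[:, np.argmax(vals)]
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def test_unperturbed_template_gives_identity_frame():
    frame = fit_base_frame(nucleotide_from_template("G"))
    np.testing.assert_allclose(frame.triad, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(frame.origin, np.zeros(3), atol=1e-9)
    assert frame.fit_rmsd == pytest.approx(0.0, abs=1e-9)


def test_frame_fitting_is_equivariant_under_rigid_motion():
    rot = rotation_about([0, 0, 1], 30.0)
    frame = fit_base_frame(nucleotide_from_template("A", rot=rot))
    np.testing.assert_allclose(frame.z_axis, [0, 0, 1], atol=1e-9)
    np.testing.assert_allclose(frame.x_axis, rot[:, 0], atol=1e-9)


def test_noisy_fit_matches_quaternion_oracle(rng):
    names, template = ring_coordinates("C")
    jitter = {
        name: rng.normal(0, 0.05, 3) for name in STANDARD_BASES["C"]
    }
    nt = nucleotide_from_template("C", jitter=jitter)
    frame = fit_base_frame(nt)
    observed = np.array([nt.coord(n) for n in names])
    # oracle maps template->observed; the frame triad is that same rotation
    rot_oracle = quaternion_superpose(template, observed)
    angle = np.rad2deg(
        np.arccos(np.clip((np.trace(frame.triad @ rot_oracle.T) - 1) / 2, -1, 1))
    )
    assert angle < 1e-6
    # the noisy frame stays close to the noiseless one at sigma = 0.05 A
    # (a six-atom pyrimidine ring constrains orientation to ~2 deg)
    clean = fit_base_frame(nucleotide_from_template("C"))
    rel = clean.triad.T @ frame.triad
    drift = np.rad2deg(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
    assert drift < 2.5
    # the frame origin sits off the ring centroid, so orientation noise
    # also displaces it through the lever arm
    assert np.linalg.norm(frame.origin - clean.origin) < 0.15


def test_fit_requires_three_ring_atoms():
    nt = nucleotide_from_template("G")
    for name in ("N9", "C8", "N7", "C5", "C6", "N1", "C2"):
        del nt.atoms[name]
    with pytest.raises(ValueError, match="ring atoms"):
        fit_base_frame(nt)


def test_basepair_frame_midpoint_properties():
    from nucgeom.frames import FLIP, ReferenceFrame

    f1 = fit_base_frame(nucleotide_from_template("G"))
    # a perfectly planar pair: strand-2 frame is the flip of strand 1
    f2 = f1.flipped()
    pair = basepair_frame(f1, f2)
    np.testing.assert_allclose(pair.triad, f1.triad, atol=1e-9)
    np.testing.assert_allclose(pair.origin, f1.origin, atol=1e-9)
    # a partner buckled +10 deg: the pair frame sits at the 5 deg midpoint
    buckled = ReferenceFrame(
        f1.origin, (rotation_about(f1.x_axis, 10.0) @ f1.triad) @ FLIP
    )
    mid = basepair_frame(f1, buckled)
    rel = f1.triad.T @ mid.triad
    angle = np.rad2deg(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
    assert angle == pytest.approx(5.0, abs=1e-6)


@pytest.mark.parametrize("buckle,propeller,opening", [
    (0.0, 0.0, 0.0),
    (0.0, -15.0, 0.0),
    (7.0, -12.0, 3.0),
])
def test_basepair_parameters_round_trip(buckle, propeller, opening):
    n = 5
    spec = DuplexParameterSpec(
        sequence="GATCG",
        buckle=np.full(n, buckle),
        propeller=np.full(n, propeller),
        opening=np.full(n, opening),
    )
    duplex = rebuild_coordinates(spec)
    geom = basepair_parameters(duplex.basepairs[2])
    assert geom.buckle == pytest.approx(buckle, abs=1e-6)
    assert geom.propeller == pytest.approx(propeller, abs=1e-6)
    assert geom.opening == pytest.approx(opening, abs=1e-6)


def test_basepair_parameters_equivariance(rng, straight_duplex):
    pair = straight_duplex.basepairs[5]
    ref = basepair_parameters(pair)
    rot = rotation_about(rng.normal(size=3), rng.uniform(10, 170))
    shift = rng.normal(size=3) * 7
    moved_atoms1 = {
        n: AtomRecord(n, a.element, rot @ a.coords + shift, a.residue_name, 1, "A")
        for n, a in pair.nt1.atoms.items()
    }
    moved_atoms2 = {
        n: AtomRecord(n, a.element, rot @ a.coords + shift, a.residue_name, 1, "B")
        for n, a in pair.nt2.atoms.items()
    }
    from nucgeom.io import BasePairUnit

    moved = BasePairUnit(
        nt1=NucleotideUnit(pair.nt1.base, 1, 1, moved_atoms1),
        nt2=NucleotideUnit(pair.nt2.base, 2, 1, moved_atoms2),
    )
    got = basepair_parameters(moved)
    assert got.buckle == pytest.approx(ref.buckle, abs=1e-8)
    assert got.propeller == pytest.approx(ref.propeller, abs=1e-8)
    assert got.opening == pytest.approx(ref.opening, abs=1e-8)
    assert got.c1c1_dist == pytest.approx(ref.c1c1_dist, abs=1e-8)


def test_strand_swap_decomposition_symmetry():
    """Under the symmetric mid-frame convention, exchanging strand roles
    negates buckle (the x rotation reverses with the inverse relative
    rotation) while propeller and opening are preserved (their axes flip
    together with the rotation sense)."""
    spec = DuplexParameterSpec(
        sequence="GATCG",
        buckle=np.full(5, 6.0),
        propeller=np.full(5, -14.0),
        opening=np.full(5, 2.5),
    )
    duplex = rebuild_coordinates(spec)
    pair = duplex.basepairs[2]
    from nucgeom.io import BasePairUnit

    swapped = BasePairUnit(nt1=pair.nt2, nt2=pair.nt1)
    ref = basepair_parameters(pair)
    got = basepair_parameters(swapped)
    assert got.buckle == pytest.approx(-ref.buckle, abs=1e-6)
    assert got.opening == pytest.approx(ref.opening, abs=1e-6)
    assert got.propeller == pytest.approx(ref.propeller, abs=1e-6)


def test_c1c1_distance_matches_direct_arithmetic():
    """Ideal G:C pair separation equals the template-coordinate distance."""
    spec = DuplexParameterSpec(sequence="GGG")
    duplex = rebuild_coordinates(spec)
    geom = basepair_parameters(duplex.basepairs[1])
    g = np.array(STANDARD_BASES["G"]["C1'"])
    c = np.array(STANDARD_BASES["C"]["C1'"]) * np.array([1, -1, -1])
    assert geom.c1c1_dist == pytest.approx(np.linalg.norm(g - c), abs=1e-6)


def test_returned_frames_are_orthonormal(superhelix_result):
    for frame in superhelix_result["pair_frames"]:
        t = frame.triad
        np.testing.assert_allclose(t.T @ t, np.eye(3), atol=1e-9)
        assert np.linalg.det(t) == pytest.approx(1.0, abs=1e-9)
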