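"""Trinucleotide-to-36-mer descriptors: groove width, fragment axes, curvature.

The minor-groove width is the fixed-offset interstrand phosphate-phosphate
separation P(i+4)..P(i') of the fibre model, a trinucleotide-scale quantity.
Global helix axes of short fragments are total-least-squares lines through
backbone C1' atoms; angles between successive non-overlapping fragment axes
probe bending at the octanucleotide/decanucleotide scale.  At the 36-mer
scale (just under half a superhelical circle) curvature is quantified by a
least-squares circle fit to the basepair centres (radius of curvature ROC),
the end-to-end to contour-length ratio d/l, and moment-of-inertia ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .frames import ReferenceFrame

__all__ = [
    "GrooveWidthSeries",
    "CurvatureMetrics",
    "minor_groove_widths",
    "fit_global_axis",
    "fragment_axis_angles",
    "fit_circle_3d",
    "curvature_window_scan",
]


@dataclass
class GrooveWidthSeries:
    """Minor-groove widths (A) indexed by the central basepair's dyad offset."""

    offsets: np.ndarray
    values: np.ndarray
    offset_convention: str = "central basepair of the spanned trinucleotide"


@dataclass
class CurvatureMetrics:
    roc: float
    circle_rmsd: float
    line_rmsd: float
    d_over_l: float
    imax_over_imin: float
    imaxmid_over_imin: float
    accepted: bool
    window_start_offset: int | None = None


def minor_groove_widths(duplex, mode: str = "fixed") -> GrooveWidthSeries:
    """Minor-groove width profile of a duplex.

    In the fibre-model convention the minimum interstrand P..P separation on
    the minor-groove side is between strand-1 phosphate i+4 (numbered 5'->3')
    and strand-2 phosphate i (numbered 3'->5', i.e. by basepair index); the
    span covers three basepairs and the width is assigned to the central
    one.  ``mode='minimum'`` instead searches strand-2 phosphates i-1..i+1
    for the per-position minimum (sensitivity analysis).
    """
    n = duplex.length
    offsets, values = [], []
    for i in range(1, n - 3):  # 1-based basepair index of the strand-2 phosphate
        p1 = duplex.basepairs[i + 4 - 1].nt1.coord("P")
        if p1 is None:
            continue
        if mode == "fixed":
            candidates = [duplex.basepairs[i - 1].nt2.coord("P")]
        elif mode == "minimum":
            candidates = [
                duplex.basepairs[j - 1].nt2.coord("P")
                for j in range(max(1, i - 1), min(n, i + 1) + 1)
            ]
        else:
            raise ValueError(f"unknown groove-width mode {mode!r}")
        dists = [
            float(np.linalg.norm(p1 - p2)) for p2 in candidates if p2 is not None
        ]
        if not dists:
            continue
        central = duplex.basepairs[i + 2 - 1]
        offsets.append(
            central.dyad_offset if central.dyad_offset is not None else i + 2
        )
        values.append(min(dists))
    return GrooveWidthSeries(
        offsets=np.array(offsets, dtype=int), values=np.array(values, dtype=float)
    )


def fit_global_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line through a point cloud.

    Returns ``(point_on_line, unit_direction, rmsd)`` where the direction is
    the principal axis through the centroid and the RMSD is the
    root-mean-square perpendicular distance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    perp = centred - np.outer(centred @ direction, direction)
    rmsd = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return centroid, direction, rmsd


# Fragment axes are fitted to basepair centres: a line fitted to raw C1'
# atoms (or anything that spirals with the helical phase) of a fragment as
# short as a tetranucleotide tilts with the phase of the partial turn it
# covers, whereas the centres sit on the helix axis at every size.


def fragment_axis_angles(
    duplex,
    fragment_size: int = 4,
    pair_frames: "list[ReferenceFrame] | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed angles between global axes of successive non-overlapping
    fragments of ``fragment_size`` basepairs (terminal basepairs excluded).

    Each axis is the total-least-squares line through the basepair centres
    of the fragment (see :func:`_fragment_axis_points`).
    The angle between consecutive axes takes the sign of its dot product
    with the average x-direction of the two basepairs at the fragment
    junction, and is assigned to the 4th/5th position of the leading
    octamer/decamer.  Returns ``(positions, angles_deg)`` with positions as
    dyad offsets when assigned, else 0-based basepair indices.
    """
    if fragment_size not in (4, 5):
        raise ValueError("fragment_size must be 4 or 5")
    if duplex.length < 2 * fragment_size + 2:
        raise ValueError("duplex too short for two non-overlapping fragments")
    interior = list(range(1, duplex.length - 1))  # exclude terminal basepairs

    if pair_frames is None:
        from .frames import basepair_frame, fit_base_frame

        pair_frames = [None] * duplex.length

        def frame_at(k: int) -> ReferenceFrame:
            if pair_frames[k] is None:
                bp = duplex.basepairs[k]
                pair_frames[k] = basepair_frame(
                    fit_base_frame(bp.nt1), fit_base_frame(bp.nt2)
                )
            return pair_frames[k]

    else:
        def frame_at(k: int) -> ReferenceFrame:
            return pair_frames[k]

    positions, angles = [], []
    for block in range(0, len(interior) - 2 * fragment_size + 1, fragment_size):
        i1 = interior[block]
        i2 = i1 + fragment_size
        if i2 + fragment_size - 1 > interior[-1]:
            break
        pts_a = np.array([frame_at(k).origin for k in range(i1, i1 + fragment_size)])
        pts_b = np.array([frame_at(k).origin for k in range(i2, i2 + fragment_size)])
        _, dir_a, _ = fit_global_axis(pts_a)
        _, dir_b, _ = fit_global_axis(pts_b)
        # orient both axes along the duplex before comparing
        chain = frame_at(i2 + fragment_size - 1).origin - frame_at(i1).origin
        if dir_a @ chain < 0:
            dir_a = -dir_a
        if dir_b @ chain < 0:
            dir_b = -dir_b
        cross = np.cross(dir_a, dir_b)
        cosang = float(np.clip(dir_a @ dir_b, -1.0, 1.0))
        angle = np.rad2deg(np.arccos(cosang))
        x_ref = 0.5 * (frame_at(i2 - 1).x_axis + frame_at(i2).x_axis)
        sign = 1.0 if cross @ x_ref >= 0 else -1.0
        bp_at = duplex.basepairs[i1 + fragment_size - 1]
        positions.append(
            bp_at.dyad_offset if bp_at.dyad_offset is not None else i1 + fragment_size - 1
        )
        angles.append(sign * angle)
    return np.array(positions), np.array(angles)


def fit_circle_3d(points: np.ndarray) -> tuple[float, float]:
    """Least-squares circle through 3D points: returns (radius, rmsd).

    The best-fit plane is found by principal axes; an algebraic (Kasa) fit
    in that plane seeds a geometric refinement, and the RMSD is the 3D
    distance from the points to the fitted circle.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("points are collinear; no circle fit")
    e1, e2, normal = vt[0], vt[1], vt[2]
    u = centred @ e1
    v = centred @ e2
    w = centred @ normal

    # Kasa algebraic fit in the plane: u^2+v^2 + D u + E v + F = 0
    a_mat = np.column_stack([u, v, np.ones_like(u)])
    rhs = -(u**2 + v**2)
    (d_c, e_c, f_c), *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    uc0, vc0 = -d_c / 2.0, -e_c / 2.0
    r0 = float(np.sqrt(max(uc0**2 + vc0**2 - f_c, 1e-12)))

    def residuals(params: np.ndarray) -> np.ndarray:
        uc, vc, r = params
        in_plane = np.sqrt((u - uc) ** 2 + (v - vc) ** 2)
        return np.sqrt((in_plane - r) ** 2 + w**2)

    fit = least_squares(
        residuals, x0=[uc0, vc0, r0], method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400,
    )
    uc, vc, radius = fit.x
    rmsd = float(np.sqrt(np.mean(fit.fun**2)))
    return float(abs(radius)), rmsd


def _inertia_ratios(points: np.ndarray) -> tuple[float, float]:
    """(Imax/Imin, (Imax+Imid)/Imin) of unit masses about the centroid."""
    centred = points - points.mean(axis=0)
    r2 = np.sum(centred**2, axis=1)
    inertia = np.eye(3) * r2.sum() - centred.T @ centred
    moments = np.sort(np.linalg.eigvalsh(inertia))  # Imin, Imid, Imax
    imin, imid, imax = moments
    if imin <= 0:
        imin = max(imin, 1e-12)
    return float(imax / imin), float((imax + imid) / imin)


def curvature_window_scan(
    duplex,
    pair_frames: list[ReferenceFrame],
    window: int = 36,
    circle_rmsd_max: float = 1.5,
    line_rmsd_min: float = 10.8,
) -> list[CurvatureMetrics]:
    """Curvature metrics for all overlapping windows of basepair centres.

    Terminal basepairs are excluded before windowing.  A window is accepted
    for summary statistics when its circle-fit RMSD is <= 1.5 A and its
    line-fit RMSD is >= 10.8 A (a straight fragment has no meaningful ROC).
    d/l is the end-to-end distance of the first and last centres divided by
    the contour length (sum of consecutive centre separations).
    """
    centres = np.array([f.origin for f in pair_frames[1:-1]])
    offsets = [
        bp.dyad_offset if bp.dyad_offset is not None else k + 1
        for k, bp in enumerate(duplex.basepairs[1:-1])
    ]
    n = len(centres)
    if n < window:
        raise ValueError(f"duplex interior ({n} bp) shorter than window ({window})")
    results: list[CurvatureMetrics] = []
    for start in range(0, n - window + 1):
        pts = centres[start : start + window]
        _, _, line_rmsd = fit_global_axis(pts)
        try:
            roc, circle_rmsd = fit_circle_3d(pts)
            fit_ok = True
        except ValueError:
            roc, circle_rmsd, fit_ok = np.nan, np.inf, False
        contour = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        d_end = float(np.linalg.norm(pts[-1] - pts[0]))
        imax_imin, imaxmid_imin = _inertia_ratios(pts)
        accepted = (
            fit_ok and circle_rmsd <= circle_rmsd_max and line_rmsd >= line_rmsd_min
        )
        results.append(
            CurvatureMetrics(
                roc=float(roc),
                circle_rmsd=float(circle_rmsd),
                line_rmsd=float(line_rmsd),
                d_over_l=d_end / contour if contour > 0 else np.nan,
                imax_over_imin=imax_imin,
                imaxmid_over_imin=imaxmid_imin,
                accepted=bool(accepted),
                window_start_offset=offsets[start],
            )
        )
    if not any(m.accepted for m in results):
        warnings.warn("no curvature window passed the acceptance thresholds")
    return results
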