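"""Orchestration: run the full multi-scale analysis over one or many duplexes.

``analyze_duplex`` turns one duplex into tidy per-basepair, per-linkage,
per-step, groove-width, fragment-angle and curvature tables.
``run_analysis`` drives a manifest of structures, writes per-structure CSVs
plus aggregate tables shaped like the published summaries (dinucleotide
census, backbone-state occurrence, region/combo-stratified parameter means,
kink census, per-structure curvature summary) and a correlation long table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import backbone as bb
from . import correlation as corr
from . import kinks as kk
from . import multiscale as ms
from . import regions as rg
from . import steps as st
from .frames import basepair_frame, basepair_parameters, fit_base_frame
from .io import DuplexModel, count_step_classes, load_duplex

__all__ = ["AnalysisConfig", "analyze_duplex", "run_analysis", "aggregate_parameter_stats"]

logger = logging.getLogger("nucgeom")


@dataclass
class AnalysisConfig:
    manifest: str | Path | None = None
    reference: kk.ReferenceDistributions = field(default_factory=kk.ReferenceDistributions)
    zp_convention: str = "linkage"
    zp_a_cutoff: float = 1.3
    zp_b_cutoff: float = 0.8
    curvature_window: int = 36
    circle_rmsd_max: float = 1.5
    line_rmsd_min: float = 10.8
    groove_mode: str = "fixed"
    max_lag: int = 15
    correlation_parameters: tuple[str, ...] = ("roll", "twist", "slide")
    reference_structure: str | None = None
    output_dir: str | Path = "nucgeom-out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("zp_a_cutoff", "zp_b_cutoff", "circle_rmsd_max", "line_rmsd_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _linkage_row(nt5, nt3, strand: int, offset5: int) -> dict:
    ts = bb.torsion_angles(nt5, nt3)
    emz = ts.eps_minus_zeta
    bi_bii = bb.classify_bi_bii(emz) if emz is not None else None
    state = (
        bb.classify_state(ts.alpha, ts.gamma, bi_bii)
        if ts.alpha is not None and ts.gamma is not None and bi_bii is not None
        else None
    )
    return {
        "strand": strand,
        "offset5": offset5,
        "alpha": ts.alpha,
        "beta": ts.beta,
        "gamma": ts.gamma,
        "delta": ts.delta,
        "epsilon": ts.epsilon,
        "zeta": ts.zeta,
        "chi": ts.chi,
        "pseudorotation_P": ts.pseudorotation_P,
        "eps_minus_zeta": emz,
        "bi_bii": bi_bii,
        "state": state,
    }


def analyze_duplex(duplex: DuplexModel, config: AnalysisConfig | None = None) -> dict:
    """Full multi-scale analysis of one duplex.

    Returns a dict of DataFrames/objects: ``basepairs``, ``linkages``,
    ``steps``, ``groove`` (GrooveWidthSeries), ``fragment_angles`` (per
    fragment size), ``curvature`` (per-window DataFrame) and
    ``curvature_summary``.
    """
    config = config or AnalysisConfig()
    n = duplex.length
    sid = duplex.structure_id
    frames1 = [fit_base_frame(bp.nt1) for bp in duplex.basepairs]
    frames2 = [fit_base_frame(bp.nt2) for bp in duplex.basepairs]
    pair_frames = [basepair_frame(f1, f2) for f1, f2 in zip(frames1, frames2)]

    bp_rows = []
    for k, bp in enumerate(duplex.basepairs):
        geom = basepair_parameters(bp, frames1[k], frames2[k])
        bp_rows.append(
            {
                "structure_id": sid,
                "offset": bp.dyad_offset,
                "shl_label": bp.shl_label,
                "half": bp.half,
                "base1": bp.nt1.base,
                "base2": bp.nt2.base,
                "watson_crick": bp.watson_crick,
                "buckle": geom.buckle,
                "propeller": geom.propeller,
                "opening": geom.opening,
                "chi1": geom.chi1,
                "chi2": geom.chi2,
                "c1c1_dist": geom.c1c1_dist,
                "c8c6_dist": geom.c8c6_dist,
                "is_terminal": k in (0, n - 1),
            }
        )
    basepairs = pd.DataFrame(bp_rows)

    link_rows = []
    for k in range(n - 1):
        off5 = duplex.basepairs[k].dyad_offset
        link_rows.append(
            {"structure_id": sid,
             **_linkage_row(duplex.basepairs[k].nt1, duplex.basepairs[k + 1].nt1, 1, off5)}
        )
        link_rows.append(
            {"structure_id": sid,
             **_linkage_row(duplex.basepairs[k + 1].nt2, duplex.basepairs[k].nt2, 2, off5)}
        )
    linkages = pd.DataFrame(link_rows)
    link_by = {(r["strand"], r["offset5"]): r for r in link_rows}

    axes = [st.local_helix_axis(pair_frames[k], pair_frames[k + 1]) for k in range(n - 1)]
    step_rows = []
    for k in range(n - 1):
        geom = st.step_parameters(pair_frames[k], pair_frames[k + 1])
        off5 = duplex.basepairs[k].dyad_offset
        dinuc = duplex.basepairs[k].nt1.base + duplex.basepairs[k + 1].nt1.base
        try:
            step_class = st.canonical_step_class(dinuc)
        except ValueError:
            step_class = None
        zp_val = st.zp(
            geom, duplex.basepairs[k], duplex.basepairs[k + 1],
            convention=config.zp_convention,
        )
        label = rg.classify_region(off5) if off5 is not None else None
        b1 = link_by[(1, off5)]["bi_bii"]
        b2 = link_by[(2, off5)]["bi_bii"]
        combo = bb.step_backbone_combo(b1, b2) if b1 and b2 else None
        bend = (
            st.successive_bending_angle(axes[k - 1], axes[k]) if k > 0 else None
        )
        step_rows.append(
            {
                "structure_id": sid,
                "offset5": off5,
                "dinuc": dinuc,
                "step_class": step_class,
                "tilt": geom.tilt,
                "roll": geom.roll,
                "twist": geom.twist,
                "shift": geom.shift,
                "slide": geom.slide,
                "rise": geom.rise,
                "zp": zp_val,
                "zp_class": (
                    st.classify_zp(zp_val, config.zp_a_cutoff, config.zp_b_cutoff)
                    if zp_val is not None else None
                ),
                "region": label.region if label else None,
                "nearest_shl": label.nearest_shl if label else None,
                "bi_bii_1": b1,
                "bi_bii_2": b2,
                "combo": combo,
                "bending_angle": bend,
                "is_terminal": k in (0, n - 2),
            }
        )
    steps_df = pd.DataFrame(step_rows)
    steps_df = kk.detect_kinks_table(steps_df, config.reference)

    groove = ms.minor_groove_widths(duplex, mode=config.groove_mode)
    frag_angles = {
        size: ms.fragment_axis_angles(duplex, size, pair_frames)
        for size in (4, 5)
        if duplex.length >= 2 * size + 2
    }
    curvature_df = pd.DataFrame()
    summary = {}
    if n - 2 >= config.curvature_window:
        metrics = ms.curvature_window_scan(
            duplex, pair_frames, window=config.curvature_window,
            circle_rmsd_max=config.circle_rmsd_max,
            line_rmsd_min=config.line_rmsd_min,
        )
        curvature_df = pd.DataFrame([vars(m) for m in metrics])
        curvature_df.insert(0, "structure_id", sid)
        accepted = curvature_df[curvature_df["accepted"]]
        summary = {
            "structure_id": sid,
            "n_windows": len(curvature_df),
            "n_accepted": int(len(accepted)),
        }
        for col in ("d_over_l", "imax_over_imin", "imaxmid_over_imin", "roc"):
            summary[f"{col}_mean"] = float(accepted[col].mean()) if len(accepted) else np.nan
            summary[f"{col}_sd"] = float(accepted[col].std(ddof=1)) if len(accepted) > 1 else np.nan

    return {
        "basepairs": basepairs,
        "linkages": linkages,
        "steps": steps_df,
        "groove": groove,
        "fragment_angles": frag_angles,
        "curvature": curvature_df,
        "curvature_summary": summary,
        "pair_frames": pair_frames,
    }


def aggregate_parameter_stats(
    steps: pd.DataFrame,
    value: str,
    by: tuple[str, ...] = ("step_class", "region", "combo"),
    min_n_for_sd: int = 5,
) -> pd.DataFrame:
    """Mean/sd/n table for one step parameter with the n >= 5 sd rule."""
    non_terminal = steps[~steps["is_terminal"]]
    return rg.region_census(non_terminal, value=value, by=by, min_n_for_sd=min_n_for_sd)


def _series(steps: pd.DataFrame, parameter: str, sid: str) -> corr.PositionalSeries:
    sub = steps.dropna(subset=[parameter, "offset5"]).sort_values("offset5")
    return corr.PositionalSeries(
        sub["offset5"].to_numpy(int), sub[parameter].to_numpy(float),
        parameter_name=parameter, structure_id=sid,
    )


def run_analysis(config: AnalysisConfig, duplexes: list[DuplexModel] | None = None) -> dict:
    """Run the pipeline over a manifest (or pre-loaded duplexes).

    The manifest is a CSV with columns ``structure_id, path`` and optional
    ``dyad_index, sequence_number``.  Structures that fail to parse are
    skipped with a logged reason.  Returns the report bundle (dict of
    DataFrames) and writes CSVs under ``config.output_dir``.
    """
    if duplexes is None:
        if config.manifest is None:
            raise ValueError("either a manifest or pre-loaded duplexes are required")
        manifest = pd.read_csv(config.manifest)
        if manifest.empty:
            raise ValueError("empty manifest")
        duplexes = []
        for _, row in manifest.iterrows():
            dyad = row.get("dyad_index")
            dyad = int(dyad) if pd.notna(dyad) else None
            try:
                duplexes.append(
                    load_duplex(row["path"], structure_id=row["structure_id"], dyad_index=dyad)
                )
            except (ValueError, OSError) as exc:
                logger.warning("skipping %s: %s", row["structure_id"], exc)
    if not duplexes:
        raise ValueError("no structures could be analysed")

    per_structure = {d.structure_id: analyze_duplex(d, config) for d in duplexes}
    all_steps = pd.concat([r["steps"] for r in per_structure.values()], ignore_index=True)
    all_bps = pd.concat([r["basepairs"] for r in per_structure.values()], ignore_index=True)
    all_links = pd.concat([r["linkages"] for r in per_structure.values()], ignore_index=True)

    # dinucleotide census (per structure and overall)
    census_rows = []
    for d in duplexes:
        counts = count_step_classes(d.sequence)
        census_rows.append({"structure_id": d.structure_id, **counts})
    step_census = pd.DataFrame(census_rows).fillna(0).set_index("structure_id")
    step_census.loc["Overall"] = step_census.sum()

    # backbone-state occurrence (percentages over classified linkages)
    state_counts = (
        all_links.groupby("state", dropna=False).size().rename("n").reset_index()
    )
    classified = all_links["state"].notna().sum()
    state_counts["percent"] = 100.0 * state_counts["n"] / max(classified, 1)

    non_terminal = all_steps[~all_steps["is_terminal"]]
    param_tables = {
        p: aggregate_parameter_stats(all_steps, p)
        for p in ("roll", "twist", "slide", "tilt", "shift", "rise")
    }
    kink_table = kk.kink_census(non_terminal)
    kinks_per_structure = (
        non_terminal.groupby("structure_id")["kink"].sum().rename("kinks").reset_index()
    )

    curvature_summary = pd.DataFrame(
        [r["curvature_summary"] for r in per_structure.values() if r["curvature_summary"]]
    )

    # correlations
    corr_rows = []
    for sid, r in per_structure.items():
        for p in config.correlation_parameters:
            series = _series(r["steps"], p, sid)
            if len(series.values) <= config.max_lag + 2:
                continue
            ac = corr.autocorrelation(series, config.max_lag)
            for lag, val in enumerate(ac):
                corr_rows.append(
                    {"kind": "auto", "structure_a": sid, "structure_b": sid,
                     "parameter": p, "lag": lag, "value": val}
                )
    ref_id = config.reference_structure
    if ref_id is not None and ref_id in per_structure:
        for sid, r in per_structure.items():
            if sid == ref_id:
                continue
            for p in config.correlation_parameters:
                a = _series(r["steps"], p, sid)
                b = _series(per_structure[ref_id]["steps"], p, ref_id)
                try:
                    lags, vals = corr.crosscorrelation(a, b, config.max_lag)
                except ValueError:
                    continue
                for lag, val in zip(lags, vals):
                    corr_rows.append(
                        {"kind": "cross", "structure_a": sid, "structure_b": ref_id,
                         "parameter": p, "lag": int(lag), "value": val}
                    )
    correlations = pd.DataFrame(corr_rows)

    bundle = {
        "steps": all_steps,
        "basepairs": all_bps,
        "linkages": all_links,
        "step_census": step_census,
        "state_occurrence": state_counts,
        "parameter_tables": param_tables,
        "kink_census": kink_table,
        "kinks_per_structure": kinks_per_structure,
        "curvature_summary": curvature_summary,
        "correlations": correlations,
        "per_structure": per_structure,
    }

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_steps.sort_values(["structure_id", "offset5"]).to_csv(out / "steps.csv", index=False)
    all_bps.sort_values(["structure_id", "offset"]).to_csv(out / "basepairs.csv", index=False)
    all_links.sort_values(["structure_id", "strand", "offset5"]).to_csv(
        out / "linkages.csv", index=False
    )
    step_census.to_csv(out / "step_census.csv")
    state_counts.to_csv(out / "state_occurrence.csv", index=False)
    for p, table in param_tables.items():
        table.to_csv(out / f"stats_{p}.csv", index=False)
    kink_table.to_csv(out / "kink_census.csv", index=False)
    kinks_per_structure.to_csv(out / "kinks_per_structure.csv", index=False)
    if not curvature_summary.empty:
        curvature_summary.to_csv(out / "curvature_summary.csv", index=False)
    if not correlations.empty:
        correlations.to_csv(out / "correlations.csv", index=False)
    logger.info("analysis complete: %d structures, %d steps", len(duplexes), len(all_steps))
    return bundle
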