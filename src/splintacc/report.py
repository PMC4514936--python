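"""End-to-end accuracy analysis of a specimen set and report generation.

``run_analysis`` turns a complete specimen set (3 regions x 2 timepoints per
head) into the study's five tables:

1. overall accuracy — RMSD per region and per axis/angle, with cutoff flags;
2. overall Bland-Altman limits of agreement with 95% CIs;
3. splint accuracy — RMSD of the splint error SE = MxRE - MdRE;
4. splint Bland-Altman limits with CIs;
5. screw-deformation RMSD per region and axis, with the deformation share of
   the overall translational RMSD.

plus the per-specimen pose-difference table and a limits<->RMSD consistency
self-check.  All numbers are stored at full precision; rounding happens only
in the plain-text rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import (
    DifferenceSeries,
    MeasureKind,
    bland_altman,
    classify_accuracy,
    rmsd,
    round_half_up,
    stats_from_limits,
)
from .decomposition import (
    COMPONENTS,
    RegionErrorSeries,
    ipd_deformation,
    splint_error,
)
from .geometry import FiducialTriad, Region, Timepoint, barycenter, vector_triad
from .pose import estimate_rotation, pose_difference
from .study import RegistrationFrame, SpecimenSet, StudyConfig

__all__ = ["StudyReport", "run_analysis", "check_consistency",
           "region_error_series", "write_report", "render_report"]

_AXIS_NAMES = {
    "dx_mm": "mediolateral",
    "dy_mm": "anteroposterior",
    "dz_mm": "superoinferior",
    "pitch_deg": "pitch",
    "roll_deg": "roll",
    "yaw_deg": "yaw",
}
_KIND = {
    "dx_mm": MeasureKind.TRANSLATIONAL,
    "dy_mm": MeasureKind.TRANSLATIONAL,
    "dz_mm": MeasureKind.TRANSLATIONAL,
    "pitch_deg": MeasureKind.ROTATIONAL,
    "roll_deg": MeasureKind.ROTATIONAL,
    "yaw_deg": MeasureKind.ROTATIONAL,
}


@dataclass
class StudyReport:
    """All tables produced by one analysis run."""

    config: StudyConfig
    pose: pd.DataFrame            # per head x region pose differences
    overall_rmsd: pd.DataFrame    # region x component RMSD + cutoff flag
    overall_limits: pd.DataFrame  # region x component Bland-Altman limits + CIs
    splint_rmsd: pd.DataFrame     # component RMSD of SE
    splint_limits: pd.DataFrame   # component Bland-Altman limits of SE
    ipd_rmsd: pd.DataFrame        # region x axis deformation RMSD + share
    consistency: pd.DataFrame     # limits<->RMSD self-check
    splint_series: pd.DataFrame   # per-specimen SE components


def _to_mandible_frame(specimen_set: SpecimenSet) -> SpecimenSet:
    """Re-express every post-operative triad in the mandible-fixed frame.

    For each head the rigid transform mapping the post-operative mandible
    back onto its planned pose is estimated and applied to all three
    post-operative triads, so residual maxilla differences isolate the
    splint error."""
    out = SpecimenSet()
    for head in specimen_set.head_ids:
        md_plan = specimen_set.get(head, Region.MANDIBLE, Timepoint.PLANNED)
        md_post = specimen_set.get(head, Region.MANDIBLE, Timepoint.POSTOP)
        est = estimate_rotation(vector_triad(md_post), vector_triad(md_plan))
        b_post = barycenter(md_post).point.as_array()
        b_plan = barycenter(md_plan).point.as_array()
        for region in Region:
            out.add(head, specimen_set.get(head, region, Timepoint.PLANNED))
            post = specimen_set.get(head, region, Timepoint.POSTOP)
            moved = (post.coords - b_post) @ est.matrix.T + b_plan
            out.add(
                head, FiducialTriad.from_coords(region, Timepoint.POSTOP, moved)
            )
    return out


def _pose_table(specimen_set: SpecimenSet, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for head in specimen_set.head_ids:
        for region in Region:
            plan = specimen_set.get(head, region, Timepoint.PLANNED)
            post = specimen_set.get(head, region, Timepoint.POSTOP)
            pd_ = pose_difference(plan, post, config.convention)
            rows.append(
                {
                    "head_id": head,
                    "region": region.value,
                    "dx_mm": pd_.translation.dx,
                    "dy_mm": pd_.translation.dy,
                    "dz_mm": pd_.translation.dz,
                    "magnitude_mm": pd_.translation.magnitude,
                    "pitch_deg": pd_.rotation.pitch,
                    "roll_deg": pd_.rotation.roll,
                    "yaw_deg": pd_.rotation.yaw,
                    "convention": pd_.rotation.convention.value,
                    "residual_rmse_mm": pd_.rotation_estimate.residual_rmse,
                    "gimbal_lock": pd_.rotation.gimbal_lock,
                }
            )
    return pd.DataFrame(rows)


def region_error_series(pose: pd.DataFrame, region: Region | str) -> RegionErrorSeries:
    """Per-specimen signed error components of one region, from the pose table."""
    region = Region(region)
    sub = pose[pose["region"] == region.value].set_index("head_id")
    return RegionErrorSeries(region, sub.loc[:, list(COMPONENTS)])


def _rmsd_table(
    series_frame: pd.DataFrame, config: StudyConfig, region_label: str | None
) -> list[dict]:
    rows = []
    for comp in COMPONENTS:
        series = DifferenceSeries(
            f"{region_label or 'splint'}/{_AXIS_NAMES[comp]}",
            series_frame[comp].to_numpy(),
        )
        value = rmsd(series)
        kind = _KIND[comp]
        rows.append(
            {
                **({"region": region_label} if region_label else {}),
                "component": _AXIS_NAMES[comp],
                "kind": kind.value,
                "rmsd": value,
                "within_cutoff": classify_accuracy(value, kind, config.cutoffs),
            }
        )
    return rows


def _limits_table(
    series_frame: pd.DataFrame, config: StudyConfig, region_label: str | None
) -> list[dict]:
    rows = []
    for comp in COMPONENTS:
        series = DifferenceSeries(
            f"{region_label or 'splint'}/{_AXIS_NAMES[comp]}",
            series_frame[comp].to_numpy(),
        )
        res = bland_altman(series, config.df_mode)
        rows.append(
            {
                **({"region": region_label} if region_label else {}),
                "component": _AXIS_NAMES[comp],
                "kind": _KIND[comp].value,
                "n": res.n,
                "mean_diff": res.mean_diff,
                "sd": res.sd,
                "lower_limit": res.lower_limit,
                "upper_limit": res.upper_limit,
                "lower_ci_low": res.ci_lower_limit[0],
                "lower_ci_high": res.ci_lower_limit[1],
                "upper_ci_low": res.ci_upper_limit[0],
                "upper_ci_high": res.ci_upper_limit[1],
            }
        )
    return rows


def _ipd_table(
    specimen_set: SpecimenSet, overall_rmsd: pd.DataFrame
) -> pd.DataFrame:
    axis_names = ("mediolateral", "anteroposterior", "superoinferior")
    rows = []
    for region in Region:
        residuals = np.stack(
            [
                ipd_deformation(
                    specimen_set.get(head, region, Timepoint.PLANNED),
                    specimen_set.get(head, region, Timepoint.POSTOP),
                )
                for head in specimen_set.head_ids
            ]
        )  # heads x screws x axes
        per_axis = np.sqrt((residuals**2).mean(axis=(0, 1)))
        for axis, value in zip(axis_names, per_axis):
            overall = overall_rmsd.loc[
                (overall_rmsd["region"] == region.value)
                & (overall_rmsd["component"] == axis),
                "rmsd",
            ].item()
            rows.append(
                {
                    "region": region.value,
                    "component": axis,
                    "ipd_rmsd": float(value),
                    "overall_rmsd": overall,
                    "fraction_pct": (
                        100.0 * float(value) / overall if overall > 0 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def check_consistency(
    limits: pd.DataFrame, rmsd_table: pd.DataFrame, n: int,
    keys: list[str] | None = None,
) -> pd.DataFrame:
    """Recompute each RMSD cell from its Bland-Altman limits and compare.

    ``limits`` needs columns ``lower_limit``/``upper_limit``, ``rmsd_table``
    a column ``rmsd``; both are matched on ``keys`` (default: whichever of
    region/component both tables share).  The discrepancy column exposes
    internally inconsistent table pairs.
    """
    if keys is None:
        keys = [k for k in ("region", "component") if k in limits.columns
                and k in rmsd_table.columns]
        if not keys:
            raise ValueError("no shared key columns to match tables on")
    merged = limits.merge(rmsd_table, on=keys, suffixes=("_limits", "_rmsd"))
    if len(merged) != len(limits) or len(merged) != len(rmsd_table):
        raise ValueError(
            f"table shapes do not match on keys {keys}: "
            f"{len(limits)} limit rows, {len(rmsd_table)} RMSD rows, "
            f"{len(merged)} matched"
        )
    implied = [
        stats_from_limits(row.lower_limit, row.upper_limit, n)[2]
        for row in merged.itertuples()
    ]
    merged["implied_rmsd"] = implied
    merged["discrepancy"] = (merged["implied_rmsd"] - merged["rmsd"]).abs()
    cols = keys + ["lower_limit", "upper_limit", "rmsd", "implied_rmsd",
                   "discrepancy"]
    return merged.loc[:, cols]


def run_analysis(specimen_set: SpecimenSet, config: StudyConfig | None = None) -> StudyReport:
    """Run the full accuracy analysis on a complete specimen set."""
    config = config or StudyConfig()
    specimen_set.validate_complete()
    if config.frame is RegistrationFrame.MANDIBLE:
        specimen_set = _to_mandible_frame(specimen_set)

    pose = _pose_table(specimen_set, config)

    rmsd_rows, limit_rows = [], []
    for region in Region:
        series = region_error_series(pose, region)
        rmsd_rows += _rmsd_table(series.frame, config, region.value)
        limit_rows += _limits_table(series.frame, config, region.value)
    overall_rmsd = pd.DataFrame(rmsd_rows)
    overall_limits = pd.DataFrame(limit_rows)

    se = splint_error(
        region_error_series(pose, Region.MAXILLA),
        region_error_series(pose, Region.MANDIBLE),
    )
    splint_rmsd = pd.DataFrame(_rmsd_table(se.frame, config, None))
    splint_limits = pd.DataFrame(_limits_table(se.frame, config, None))

    ipd = _ipd_table(specimen_set, overall_rmsd)

    consistency = check_consistency(
        overall_limits, overall_rmsd, specimen_set.n_heads
    )

    return StudyReport(
        config=config,
        pose=pose,
        overall_rmsd=overall_rmsd,
        overall_limits=overall_limits,
        splint_rmsd=splint_rmsd,
        splint_limits=splint_limits,
        ipd_rmsd=ipd,
        consistency=consistency,
        splint_series=se.frame,
    )


def _rounded(frame: pd.DataFrame, decimals: int) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: round_half_up(v, decimals))
    return out


def render_report(report: StudyReport) -> str:
    """Human-readable aligned-text rendering of all tables (rounded)."""
    d = report.config.report_decimals
    blocks = [
        ("Overall accuracy (RMSD)", report.overall_rmsd),
        ("Overall Bland-Altman limits (95% CI)", report.overall_limits),
        ("Splint accuracy (RMSD of SE = MxRE - MdRE)", report.splint_rmsd),
        ("Splint Bland-Altman limits (95% CI)", report.splint_limits),
        ("Screw deformation (per-axis RMSD and share of overall RMSD)",
         report.ipd_rmsd),
        ("Limits <-> RMSD consistency self-check", report.consistency),
    ]
    parts = []
    for title, frame in blocks:
        parts.append(title)
        parts.append("-" * len(title))
        parts.append(_rounded(frame, d).to_string(index=False))
        parts.append("")
    return "\n".join(parts)


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write all report tables as CSV plus the rendered text report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "pose_differences.csv": report.pose,
        "overall_rmsd.csv": report.overall_rmsd,
        "overall_limits.csv": report.overall_limits,
        "splint_rmsd.csv": report.splint_rmsd,
        "splint_limits.csv": report.splint_limits,
        "ipd_rmsd.csv": report.ipd_rmsd,
        "consistency.csv": report.consistency,
        "splint_series.csv": report.splint_series.reset_index(),
    }
    for name, frame in tables.items():
        frame.to_csv(outdir / name, index=False, lineterminator="\n")
    (outdir / "report.txt").write_text(render_report(report))
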