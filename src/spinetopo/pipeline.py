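"""Per-subject and cohort orchestration of the profile analysis.

Phase 1 compares the spinal column profile (SCP, MRI spinous processes)
against the fiducial marker profile (FMP, MRI skin markers): matched-station
RMSD overall and by spinal region, plus a two-sample KS test on the
curvature distributions. Phase 2 compares the FMP against the surface-scan
marker profile (3MP) after rigid alignment into the MRI frame, using a KS
test on the sampled coordinates rather than curvature. Cohort-level analysis
relates the phase-1 RMSDs to BMI, age and gender through a Pearson
correlation matrix, summarises KS outcomes by BMI class, and evaluates
observer reliability with per-axis ICCs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .frames import (
    AnatomicalFrame,
    PlanarSeries,
    RigidTransform,
    align_scan_to_mri,
    frame_from_landmarks,
    project_to_plane,
)
from .profiles import (
    DistanceSummary,
    PointwiseLateral,
    ProfileModel,
    RegionBounds,
    SampledProfile,
    compute_curvature,
    fit_profile,
    marker_pointwise_lateral,
    profile_rmsd,
    sample_profile,
)
from .stats import (
    ALPHA_DEFAULT,
    CorrelationEntry,
    ICCResult,
    KSResult,
    correlation_frame,
    group_percent_change,
    icc_two_session,
    ks_two_sample,
    pearson_matrix,
)
from .synthetic import (
    SOURCE_MRI_FIDUCIAL,
    SOURCE_MRI_SPINOUS,
    SOURCE_SCAN_MARKER,
    LandmarkSet,
    SubjectDemographics,
)

logger = logging.getLogger("spinetopo")

PAIR_SCP_FMP = "SCP_vs_FMP"
PAIR_FMP_3MP = "FMP_vs_3MP"
PLANES = ("sagittal", "coronal")

#: ICC axes and the coordinate column each one reads.
ICC_AXES = (("lateral", 0), ("antero-posterior", 1), ("cephalo-caudal", 2))


@dataclass
class ProfileComparison:
    """One profile pair compared in one plane for one subject."""

    subject_id: str
    pair: str  # SCP_vs_FMP or FMP_vs_3MP
    plane: str
    rmsd_overall: float
    rmsd_thoracic: float
    rmsd_lumbar: float
    distance_summary: DistanceSummary
    ks: KSResult  # curvature KS for SCP_vs_FMP, coordinate KS for FMP_vs_3MP
    fit_rmse_a: float
    fit_rmse_b: float
    n_stations: int


@dataclass
class SubjectAnalysis:
    """Everything computed for a single subject."""

    subject_id: str
    comparisons: list[ProfileComparison]
    pointwise_lateral: PointwiseLateral  # FMP vs SCP, per-vertebra, coronal
    lateral_diffs: np.ndarray  # signed per-level fiducial - spine, mm
    fit_rmse: dict[tuple[str, str], float]  # (source, plane) -> mm
    alignment: RigidTransform | None
    frame: AnatomicalFrame

    def comparison(self, pair: str, plane: str) -> ProfileComparison:
        for c in self.comparisons:
            if c.pair == pair and c.plane == plane:
                return c
        raise KeyError(f"no comparison {pair}/{plane} for {self.subject_id}")


def _fit_and_sample_pair(
    a: PlanarSeries,
    b: PlanarSeries,
    degree: int,
    interval: float,
) -> tuple[ProfileModel, ProfileModel, SampledProfile, SampledProfile]:
    """Fit both series and sample them on a common station grid over the
    overlap of their fitted domains (anchored at the shared cephalad end)."""
    ma = fit_profile(a.z, a.v, degree=degree, plane=a.plane, source=a.source)
    mb = fit_profile(b.z, b.v, degree=degree, plane=b.plane, source=b.source)
    z_hi = min(ma.domain[1], mb.domain[1])
    z_lo = max(ma.domain[0], mb.domain[0])
    sa = sample_profile(ma, interval=interval, domain=(z_lo, z_hi))
    sb = sample_profile(mb, interval=interval, domain=(z_lo, z_hi))
    return ma, mb, sa, sb


def _compare(
    subject_id: str,
    pair: str,
    a: PlanarSeries,
    b: PlanarSeries,
    bounds: RegionBounds,
    degree: int,
    interval: float,
    alpha: float,
) -> ProfileComparison:
    ma, mb, sa, sb = _fit_and_sample_pair(a, b, degree, interval)
    overall = profile_rmsd(sa, sb, region="overall")
    thoracic = profile_rmsd(sa, sb, region="thoracic", region_bounds=bounds)
    lumbar = profile_rmsd(sa, sb, region="lumbar", region_bounds=bounds)
    # round KS inputs below physical resolution (nm coordinates, 1e-12/mm
    # curvature) so profiles that are equal up to floating-point noise give
    # D = 0 rather than spurious tie-breaks
    if pair == PAIR_SCP_FMP:
        ks = ks_two_sample(
            np.round(compute_curvature(sa), 12),
            np.round(compute_curvature(sb), 12),
            alpha=alpha,
        )
    else:
        ks = ks_two_sample(np.round(sa.values, 9), np.round(sb.values, 9), alpha=alpha)
    return ProfileComparison(
        subject_id=subject_id,
        pair=pair,
        plane=a.plane,
        rmsd_overall=overall.rmsd,
        rmsd_thoracic=thoracic.rmsd,
        rmsd_lumbar=lumbar.rmsd,
        distance_summary=overall,
        ks=ks,
        fit_rmse_a=ma.fit_rmse,
        fit_rmse_b=mb.fit_rmse,
        n_stations=overall.n_stations,
    )


def analyze_subject(
    spine: LandmarkSet,
    fiducials: LandmarkSet,
    scan: LandmarkSet | None = None,
    substrate_normal: Sequence[float] = (0.0, 1.0, 0.0),
    degree: int = 7,
    interval: float = 20.0,
    alpha: float = ALPHA_DEFAULT,
) -> SubjectAnalysis:
    """Full single-subject analysis.

    Builds the anatomical frame from the fiducial set (L1 origin, PSIS pair,
    substrate normal), rigidly aligns the scan markers into the MRI frame,
    projects every source into the sagittal and coronal planes, fits
    degree-7 profiles, samples them at 20 mm stations and emits the
    SCP-vs-FMP (RMSD + curvature KS) and FMP-vs-3MP (RMSD + coordinate KS)
    comparisons for both planes.
    """
    if spine.source != SOURCE_MRI_SPINOUS:
        raise ValueError(f"expected {SOURCE_MRI_SPINOUS} set, got {spine.source}")
    if fiducials.source != SOURCE_MRI_FIDUCIAL:
        raise ValueError(f"expected {SOURCE_MRI_FIDUCIAL} set, got {fiducials.source}")
    for s in (spine, fiducials):
        missing = [lb for lb in ("T1", "T12", "L1", "L5") if not s.has_label(lb)]
        if missing:
            raise ValueError(
                f"{s.source} set of {s.subject_id} missing labels {missing}"
            )

    frame = frame_from_landmarks(fiducials, substrate_normal)
    transform = None
    aligned_scan = None
    if scan is not None:
        transform, aligned_scan = align_scan_to_mri(scan, fiducials)

    comparisons: list[ProfileComparison] = []
    fit_rmse: dict[tuple[str, str], float] = {}
    pointwise = None
    lateral_diffs = np.array([])
    for plane in PLANES:
        p_spine = project_to_plane(spine, frame, plane)
        p_fid = project_to_plane(fiducials, frame, plane)
        bounds = RegionBounds.from_vertebral_z(p_spine.labels, p_spine.z)
        c1 = _compare(
            spine.subject_id, PAIR_SCP_FMP, p_spine, p_fid, bounds,
            degree, interval, alpha,
        )
        comparisons.append(c1)
        fit_rmse[(SOURCE_MRI_SPINOUS, plane)] = c1.fit_rmse_a
        fit_rmse[(SOURCE_MRI_FIDUCIAL, plane)] = c1.fit_rmse_b
        if plane == "coronal":
            common = [lb for lb in p_spine.labels if lb in p_fid.labels]
            ps = _subset_series(p_spine, common)
            pf = _subset_series(p_fid, common)
            pointwise = marker_pointwise_lateral(ps, pf)
            lateral_diffs = np.asarray(pf.v) - np.asarray(ps.v)
        if aligned_scan is not None:
            p_scan = project_to_plane(aligned_scan, frame, plane)
            c2 = _compare(
                spine.subject_id, PAIR_FMP_3MP, p_fid, p_scan, bounds,
                degree, interval, alpha,
            )
            comparisons.append(c2)
            fit_rmse[(SOURCE_SCAN_MARKER, plane)] = c2.fit_rmse_b

    return SubjectAnalysis(
        subject_id=spine.subject_id,
        comparisons=comparisons,
        pointwise_lateral=pointwise,
        lateral_diffs=lateral_diffs,
        fit_rmse=fit_rmse,
        alignment=transform,
        frame=frame,
    )


def _subset_series(series: PlanarSeries, labels: list[str]) -> PlanarSeries:
    idx = [series.labels.index(lb) for lb in labels]
    return PlanarSeries(
        subject_id=series.subject_id,
        source=series.source,
        plane=series.plane,
        labels=labels,
        z=series.z[idx],
        v=series.v[idx],
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

GENDER_CODE = {"F": 1, "M": 2}  # point-biserial coding used in correlations


@dataclass
class CohortResults:
    """Aggregate outputs of a cohort run."""

    subject_table: pd.DataFrame  # one row per subject, phase-1 metrics + demographics
    analyses: list[SubjectAnalysis]
    correlations: list[CorrelationEntry]
    ks_summary: pd.DataFrame  # non-significance fractions per pair/plane/class
    group_changes: dict[str, float]  # percent change underweight -> overweight
    reliability: list[tuple[str, str, ICCResult]]  # (subject, source, result)
    fit_rmse_summary: pd.DataFrame  # mean/sd fit RMSE per source and plane
    pooled_lateral_mean: float
    pooled_lateral_sd: float
    subject_left_fraction: float
    n_subjects: int
    n_with_scan: int


def _group_by_subject(
    landmark_sets: Sequence[LandmarkSet],
) -> dict[str, dict[tuple[str, int], LandmarkSet]]:
    grouped: dict[str, dict[tuple[str, int], LandmarkSet]] = {}
    for s in landmark_sets:
        grouped.setdefault(s.subject_id, {})[(s.source, s.session)] = s
    return grouped


def analyze_cohort(
    demographics: Sequence[SubjectDemographics],
    landmark_sets: Sequence[LandmarkSet],
    substrate_normal: Sequence[float] = (0.0, 1.0, 0.0),
    degree: int = 7,
    interval: float = 20.0,
    alpha: float = ALPHA_DEFAULT,
) -> CohortResults:
    """Cohort-level analysis over per-subject comparisons.

    Subjects lacking a scan set are retained for the SCP-vs-FMP phase and
    excluded, with a log message, from the FMP-vs-3MP phase. Correlations
    pair the per-plane overall/thoracic/lumbar RMSDs with BMI, age and
    gender (coded F=1, M=2).
    """
    if len(demographics) < 4:
        raise ValueError("cohort analysis needs at least 4 subjects")
    grouped = _group_by_subject(landmark_sets)
    demo_by_id = {d.subject_id: d for d in demographics}

    analyses: list[SubjectAnalysis] = []
    rows = []
    n_with_scan = 0
    for demo in demographics:
        sets = grouped.get(demo.subject_id)
        if sets is None:
            raise ValueError(f"no landmark sets for subject {demo.subject_id}")
        spine = sets.get((SOURCE_MRI_SPINOUS, 1))
        fid = sets.get((SOURCE_MRI_FIDUCIAL, 1))
        if spine is None or fid is None:
            raise ValueError(
                f"subject {demo.subject_id} lacks a session-1 MRI spinous or "
                f"fiducial set"
            )
        scan = sets.get((SOURCE_SCAN_MARKER, 1))
        if scan is None:
            logger.info(
                "subject %s has no scan set; skipping FMP-vs-3MP phase",
                demo.subject_id,
            )
        else:
            n_with_scan += 1
        ana = analyze_subject(
            spine, fid, scan,
            substrate_normal=substrate_normal,
            degree=degree, interval=interval, alpha=alpha,
        )
        analyses.append(ana)
        row = {
            "subject_id": demo.subject_id,
            "gender": demo.gender,
            "gender_code": GENDER_CODE[demo.gender],
            "age": demo.age,
            "bmi": demo.bmi,
            "bmi_class": demo.bmi_class,
        }
        for c in ana.comparisons:
            key = f"{c.pair}_{c.plane}"
            row[f"rmsd_overall_{key}"] = c.rmsd_overall
            row[f"rmsd_thoracic_{key}"] = c.rmsd_thoracic
            row[f"rmsd_lumbar_{key}"] = c.rmsd_lumbar
            row[f"ks_p_{key}"] = c.ks.p_value
            row[f"ks_nonsignificant_{key}"] = c.ks.nonsignificant
        row["lateral_mean_mm"] = ana.pointwise_lateral.mean
        row["lateral_left_fraction"] = ana.pointwise_lateral.left_fraction
        rows.append(row)
    table = pd.DataFrame(rows)

    # correlations: phase-1 RMSDs vs demographics
    corr_cols = {
        "sagittal RMSD": f"rmsd_overall_{PAIR_SCP_FMP}_sagittal",
        "sagittal thoracic RMSD": f"rmsd_thoracic_{PAIR_SCP_FMP}_sagittal",
        "sagittal lumbar RMSD": f"rmsd_lumbar_{PAIR_SCP_FMP}_sagittal",
        "coronal RMSD": f"rmsd_overall_{PAIR_SCP_FMP}_coronal",
        "coronal thoracic RMSD": f"rmsd_thoracic_{PAIR_SCP_FMP}_coronal",
        "coronal lumbar RMSD": f"rmsd_lumbar_{PAIR_SCP_FMP}_coronal",
        "BMI": "bmi",
        "age": "age",
        "gender": "gender_code",
    }
    corr_table = table[list(corr_cols.values())].copy()
    corr_table.columns = list(corr_cols)
    correlations = pearson_matrix(corr_table)

    ks_summary = _ks_summary(table)

    group_changes: dict[str, float] = {}
    classes = table["bmi_class"].to_numpy()
    for plane in PLANES:
        col = f"rmsd_overall_{PAIR_SCP_FMP}_{plane}"
        if {"underweight", "overweight"} <= set(classes):
            group_changes[plane] = group_percent_change(
                table[col].to_numpy(), classes, "underweight", "overweight"
            )

    reliability = _cohort_reliability(grouped)

    fit_rows = []
    for source in (SOURCE_MRI_SPINOUS, SOURCE_MRI_FIDUCIAL, SOURCE_SCAN_MARKER):
        for plane in PLANES:
            vals = [a.fit_rmse[(source, plane)] for a in analyses
                    if (source, plane) in a.fit_rmse]
            if vals:
                fit_rows.append({
                    "source": source, "plane": plane, "n": len(vals),
                    "fit_rmse_mean_mm": float(np.mean(vals)),
                    "fit_rmse_sd_mm": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                })
    fit_summary = pd.DataFrame(fit_rows)

    all_diffs = np.concatenate([a.lateral_diffs for a in analyses])
    left_frac = float(np.mean(table["lateral_mean_mm"] > 0))

    logger.info(
        "cohort analysis: %d subjects, %d with scan sets, %d comparisons",
        len(analyses), n_with_scan, sum(len(a.comparisons) for a in analyses),
    )
    return CohortResults(
        subject_table=table,
        analyses=analyses,
        correlations=correlations,
        ks_summary=ks_summary,
        group_changes=group_changes,
        reliability=reliability,
        fit_rmse_summary=fit_summary,
        pooled_lateral_mean=float(all_diffs.mean()),
        pooled_lateral_sd=float(all_diffs.std(ddof=1)),
        subject_left_fraction=left_frac,
        n_subjects=len(analyses),
        n_with_scan=n_with_scan,
    )


def _ks_summary(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pair in (PAIR_SCP_FMP, PAIR_FMP_3MP):
        for plane in PLANES:
            col = f"ks_nonsignificant_{pair}_{plane}"
            if col not in table.columns:
                continue
            flags = table[col].dropna()
            groups = [("all", flags)]
            for cls, grp in table.groupby("bmi_class"):
                groups.append((cls, grp[col].dropna()))
            for name, g in groups:
                if len(g) == 0:
                    continue
                rows.append({
                    "pair": pair, "plane": plane, "bmi_class": name,
                    "n": int(len(g)),
                    "nonsignificant_fraction": float(np.mean(g.astype(bool))),
                })
    return pd.DataFrame(rows)


def run_reliability(
    session1: LandmarkSet, session2: LandmarkSet
) -> dict[str, ICCResult]:
    """Per-axis ICC(2,1) between two observer-selection sessions of the same
    landmark set (matched by label)."""
    if set(session1.labels) != set(session2.labels):
        raise ValueError(
            "session label sets differ: "
            f"{sorted(set(session1.labels) ^ set(session2.labels))}"
        )
    labels = list(session1.labels)
    c1 = np.vstack([session1.point(lb) for lb in labels])
    c2 = np.vstack([session2.point(lb) for lb in labels])
    return {
        axis: icc_two_session(c1[:, col], c2[:, col], axis=axis)
        for axis, col in ICC_AXES
    }


def _cohort_reliability(
    grouped: dict[str, dict[tuple[str, int], LandmarkSet]],
) -> list[tuple[str, str, ICCResult]]:
    out = []
    for sid, sets in grouped.items():
        for (source, session), s2 in sorted(sets.items()):
            if session != 2:
                continue
            s1 = sets.get((source, 1))
            if s1 is None:
                continue
            for axis, res in run_reliability(s1, s2).items():
                out.append((sid, source, res))
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def comparison_frame(results: CohortResults) -> pd.DataFrame:
    """Long-format comparison table: one row per subject, pair and plane."""
    rows = []
    for a in results.analyses:
        for c in a.comparisons:
            rows.append({
                "subject_id": c.subject_id,
                "pair": c.pair,
                "plane": c.plane,
                "rmsd_overall_mm": c.rmsd_overall,
                "rmsd_thoracic_mm": c.rmsd_thoracic,
                "rmsd_lumbar_mm": c.rmsd_lumbar,
                "mean_distance_mm": c.distance_summary.mean_distance,
                "sd_distance_mm": c.distance_summary.sd_distance,
                "ks_d": c.ks.d_statistic,
                "ks_p": c.ks.p_value,
                "ks_nonsignificant": c.ks.nonsignificant,
                "fit_rmse_a_mm": c.fit_rmse_a,
                "fit_rmse_b_mm": c.fit_rmse_b,
                "n_stations": c.n_stations,
            })
    return pd.DataFrame(rows)


def report(
    results: CohortResults,
    outdir,
    config: dict | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write the cohort report: long-format per-subject comparison CSV, the
    wide subject table, correlation CSV, KS summary CSV and a JSON run
    manifest. Returns the written paths."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}") from exc

    paths = []
    per_subject = outdir / "per_subject.csv"
    comparison_frame(results).to_csv(per_subject, index=False, float_format="%.9f")
    paths.append(per_subject)

    subject_table = outdir / "subject_table.csv"
    results.subject_table.to_csv(subject_table, index=False, float_format="%.9f")
    paths.append(subject_table)

    corr = outdir / "correlations.csv"
    correlation_frame(results.correlations).to_csv(corr, index=False, float_format="%.9f")
    paths.append(corr)

    ks = outdir / "ks_summary.csv"
    results.ks_summary.to_csv(ks, index=False, float_format="%.9f")
    paths.append(ks)

    manifest = {
        "package": "spinetopo",
        "version": __version__,
        "n_subjects": results.n_subjects,
        "n_with_scan": results.n_with_scan,
        "group_percent_change_underweight_to_overweight": results.group_changes,
        "pooled_lateral_mean_mm": results.pooled_lateral_mean,
        "pooled_lateral_sd_mm": results.pooled_lateral_sd,
        "subject_left_fraction": results.subject_left_fraction,
        "fit_rmse_summary": results.fit_rmse_summary.to_dict(orient="records"),
        "reliability": [
            {"subject": sid, "source": src, "axis": r.axis,
             "icc": r.icc, "agreement": r.agreement}
            for sid, src, r in results.reliability
        ],
        "n_correlation_tests": len(results.correlations),
    }
    if config is not None:
        manifest["config"] = config
    if seed is not None:
        manifest["seed"] = seed
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths.append(man_path)

    logger.info("report written to %s (%d files)", outdir, len(paths))
    return paths
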