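"""Quantification of interfraction rectum and PTV motion.

Three factors are tracked between planning and each treatment fraction:

1. rectal volume change, reported as planned-minus-delivered percent of the
   planned volume (positive = smaller rectum on the day);
2. anterior and posterior rectal-wall positions relative to the linac
   isocentre, read off the DSM sampling points (posterior wall = column 0,
   anterior wall = mean of the two columns straddling the anterior midline);
3. PTV position relative to the rectum, via the displacement vector from the
   inferior-most rectal slice centroid to the isocentre.  Deviations from
   the planning baseline are reported as (left-right, ant-post, sup-inf)
   with positive = patient-left / posterior / superior, so a positive SI
   component is a superior shift of the PTV (and dose wash) relative to the
   rectum.

Cohort summaries pair these factors with dose metrics (DVH VX% and DSM probe
pixels 18/36/54 mm up the anterior and posterior walls) via Wilcoxon
signed-rank tests and Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .core import CohortData, ContourStack, DSM
from .dsm_generation import ANTERIOR_COLUMNS
from .stats_compare import pearson, wilcoxon_signed_rank

#: DSM probe rows at 18, 36 and 54 mm above the inferior border (3 mm rows)
PROBE_ROWS = (6, 12, 18)
V_METRIC_PCTS = (20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass
class MotionRecord:
    patient_id: str
    fraction_index: int
    volume_change_pct: float
    posterior_wall_ap_mm: np.ndarray  # per common DSM row, relative to isocentre
    anterior_wall_ap_mm: np.ndarray
    ptv_offset_mm: np.ndarray  # (LR, AP, SI) deviation from planning baseline


def structure_volume(s: ContourStack) -> float:
    """Volume by trapezoidal integration of slice polygon areas along z."""
    if len(s.slices) < 2:
        raise ValueError("volume needs at least 2 slices")
    zs = s.z_values
    areas = np.array([Polygon(v).area for _, v in s.slices])
    return float(np.trapezoid(areas, zs))


def volume_change(planning: ContourStack, daily: ContourStack) -> float:
    """Percent change, planned minus delivered relative to planned."""
    vp = structure_volume(planning)
    vd = structure_volume(daily)
    return 100.0 * (vp - vd) / vp


def wall_traces(dsm: DSM, isocentre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row AP (y) positions of the posterior and anterior walls vs isocentre."""
    if dsm.points.size == 0:
        raise ValueError("DSM carries no sampled surface points")
    iso_y = float(np.asarray(isocentre)[1])
    posterior = dsm.points[:, 0, 1] - iso_y
    c1, c2 = ANTERIOR_COLUMNS
    anterior = 0.5 * (dsm.points[:, c1, 1] + dsm.points[:, c2, 1]) - iso_y
    return posterior, anterior


def ptv_offset(
    rectum: ContourStack,
    isocentre: np.ndarray,
    baseline: np.ndarray,
) -> np.ndarray:
    """Deviation of the PTV-vs-rectum displacement from the planning baseline.

    The displacement is measured from the inferior-most rectal slice centroid
    to the isocentre (which is fixed relative to the planned dose, proxying
    the PTV under soft-tissue matching).  ``baseline`` is the same vector at
    planning.  Components are (LR, AP, SI), positive toward patient-left /
    posterior / superior.
    """
    c = Polygon(rectum.slices[0][1]).centroid
    inf_centroid = np.array([c.x, c.y, rectum.slices[0][0]])
    v_day = np.asarray(isocentre, dtype=float) - inf_centroid
    return v_day - np.asarray(baseline, dtype=float)


def ptv_baseline(rectum: ContourStack, isocentre: np.ndarray) -> np.ndarray:
    """Planning-time displacement from the inferior rectal centroid to isocentre."""
    c = Polygon(rectum.slices[0][1]).centroid
    inf_centroid = np.array([c.x, c.y, rectum.slices[0][0]])
    return np.asarray(isocentre, dtype=float) - inf_centroid


def motion_records(
    cohort: CohortData, dsms: dict[str, dict[int, DSM]]
) -> list[MotionRecord]:
    """One MotionRecord per treatment fraction of every patient.

    ``dsms[patient_id][fraction_index]`` must hold the DSM of each record
    (index 0 = planning); wall traces are compared on the rows common to the
    planning and daily maps.
    """
    records: list[MotionRecord] = []
    for pt in cohort.patients:
        plan_dsm = dsms[pt.patient_id][0]
        base = ptv_baseline(pt.planning.rectum, pt.planning.isocentre_mm)
        for fr in pt.fractions:
            day_dsm = dsms[pt.patient_id][fr.fraction_index]
            n = min(plan_dsm.n_rows, day_dsm.n_rows)
            post_p, ant_p = wall_traces(plan_dsm, pt.planning.isocentre_mm)
            post_d, ant_d = wall_traces(day_dsm, fr.isocentre_mm)
            records.append(
                MotionRecord(
                    patient_id=pt.patient_id,
                    fraction_index=fr.fraction_index,
                    volume_change_pct=volume_change(pt.planning.rectum, fr.rectum),
                    posterior_wall_ap_mm=post_d[:n] - post_p[:n],
                    anterior_wall_ap_mm=ant_d[:n] - ant_p[:n],
                    ptv_offset_mm=ptv_offset(fr.rectum, fr.isocentre_mm, base),
                )
            )
    return records


def _record_scalars(rec: MotionRecord) -> dict[str, float]:
    return {
        "volume_change_pct": rec.volume_change_pct,
        "posterior_wall_shift_mm": float(np.mean(rec.posterior_wall_ap_mm)),
        "anterior_wall_shift_mm": float(np.mean(rec.anterior_wall_ap_mm)),
        "ptv_lr_mm": float(rec.ptv_offset_mm[0]),
        "ptv_ap_mm": float(rec.ptv_offset_mm[1]),
        "ptv_si_mm": float(rec.ptv_offset_mm[2]),
    }


def motion_table(records: list[MotionRecord]) -> pd.DataFrame:
    """Long-format table: patient, fraction, metric, value."""
    rows = []
    for rec in records:
        for metric, value in _record_scalars(rec).items():
            rows.append(
                {
                    "patient": rec.patient_id,
                    "fraction": rec.fraction_index,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def motion_summary(
    cohort: CohortData,
    dsms: dict[str, dict[int, DSM]],
    dose_metrics: pd.DataFrame | None = None,
    fraction_range: tuple[int, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort motion summary tables.

    Returns a dict with:

    * ``records`` — long-format per-fraction motion table;
    * ``per_patient`` — per-patient mean of each metric with a Wilcoxon
      signed-rank p of the per-fraction deviations against zero;
    * ``cohort`` — cohort mean/sd of per-patient means with a Wilcoxon p of
      the patient means against zero;
    * ``correlations`` — if ``dose_metrics`` is supplied (long format:
      patient, fraction, dose_metric, value, holding fraction-level
      deviations of DVH/DSM dose metrics), pooled Pearson r and r^2 between
      every motion metric and every dose metric.

    ``fraction_range`` (lo, hi) restricts all tables to fractions with
    lo <= index <= hi (e.g. the first or last five fractions).
    """
    records = motion_records(cohort, dsms)
    if fraction_range is not None:
        lo, hi = fraction_range
        records = [r for r in records if lo <= r.fraction_index <= hi]
    table = motion_table(records)
    per_patient_rows = []
    for (patient, metric), grp in table.groupby(["patient", "metric"]):
        vals = grp["value"].to_numpy()
        per_patient_rows.append(
            {
                "patient": patient,
                "metric": metric,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                "wilcoxon_p": wilcoxon_signed_rank(vals),
            }
        )
    per_patient = pd.DataFrame(per_patient_rows)
    cohort_rows = []
    for metric, grp in per_patient.groupby("metric"):
        means = grp["mean"].to_numpy()
        cohort_rows.append(
            {
                "metric": metric,
                "mean": means.mean(),
                "sd": means.std(ddof=1) if means.size > 1 else 0.0,
                "wilcoxon_p": wilcoxon_signed_rank(means),
            }
        )
    out = {
        "records": table,
        "per_patient": per_patient,
        "cohort": pd.DataFrame(cohort_rows),
    }
    if dose_metrics is not None:
        merged_rows = []
        motion_wide = table.pivot_table(
            index=["patient", "fraction"], columns="metric", values="value"
        )
        dose_wide = dose_metrics.pivot_table(
            index=["patient", "fraction"], columns="dose_metric", values="value"
        )
        joined = motion_wide.join(dose_wide, how="inner")
        for mcol in motion_wide.columns:
            for dcol in dose_wide.columns:
                x = joined[mcol].to_numpy()
                y = joined[dcol].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                    continue
                r, r2 = pearson(x[ok], y[ok])
                merged_rows.append(
                    {"motion_metric": mcol, "dose_metric": dcol, "r": r, "r2": r2}
                )
        out["correlations"] = pd.DataFrame(merged_rows)
    return out
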