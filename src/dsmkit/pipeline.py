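"""End-to-end study replica on a cohort.

For every patient: DSMs for the planning record and each fraction,
accumulation into a delivered-dose estimate, a planned-minus-accumulated
dose-difference map, DVHs, patient-level one-sample permutation tests (DVH
run rule, DSM cluster rule), and interfraction-motion metrics.  Cohort-wide:
paired tests of planned versus average-delivered DVHs and planned versus
accumulated DSMs, the cohort-average DDM, and motion/dose correlations.
The headline contrast is the number of patients flagged as receiving
significantly different dose by the DVH route versus the DSM route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CohortData, DVH, DSM
from .dose_accumulation import accumulate, align_truncate, dose_difference
from .dsm_generation import ANTERIOR_COLUMNS, compute_dsm
from .dvh_analysis import average_dvh, compute_dvh, pad_dvh_to, v_metrics
from .motion_metrics import PROBE_ROWS, V_METRIC_PCTS, motion_summary
from .rt_io import read_fixture_cohort, write_map_csv
from .stats_compare import dvh_comparison, mcp_test


@dataclass
class RunConfig:
    cohort_path: str
    out_dir: str | None = None
    n_perm: int = 2000
    seed: int = 0
    connectivity: int = 4
    cluster_min: int = 5
    run_min: int = 3
    dvh_step_gy: float = 5.0
    slice_step_mm: float = 3.0
    angular_count: int = 45
    dvh_bin_gy: float = 0.1

    def __post_init__(self) -> None:
        if min(self.cluster_min, self.run_min) <= 0 or self.dvh_step_gy <= 0:
            raise ValueError("thresholds must be positive")
        if self.angular_count != 45:
            # supported, but flagged: 45 is the standard sampling density
            import warnings

            warnings.warn(
                f"angular_count={self.angular_count} is a non-standard configuration",
                RuntimeWarning,
            )


@dataclass
class PatientResult:
    patient_id: str
    planned_dsm: DSM
    accumulated_dsm: DSM
    ddm: object
    planned_dvh: DVH
    daily_dvhs: list[DVH]
    dvh_test: object
    dsm_test: object


@dataclass
class RunResult:
    patients: dict[str, PatientResult]
    cohort_dvh_test: object
    cohort_dsm_test: object
    cohort_ddm: object
    motion: dict[str, pd.DataFrame]
    n_flagged_dvh: int
    n_flagged_dsm: int
    manifest: dict = field(default_factory=dict)


def _probe_deviation_rows(pid, fraction, plan_dsm, day_dsm):
    """Fraction-level DSM probe-point dose deviations (daily minus planned)."""
    rows = []
    n = min(plan_dsm.n_rows, day_dsm.n_rows)
    c1, c2 = ANTERIOR_COLUMNS
    for r in PROBE_ROWS:
        if r >= n:
            continue
        mm = int(r * plan_dsm.row_spacing_mm)
        post = day_dsm.dose[r, 0] - plan_dsm.dose[r, 0]
        ant = 0.5 * (day_dsm.dose[r, c1] + day_dsm.dose[r, c2]) - 0.5 * (
            plan_dsm.dose[r, c1] + plan_dsm.dose[r, c2]
        )
        rows.append(
            {"patient": pid, "fraction": fraction,
             "dose_metric": f"dsm_posterior_{mm}mm_gy", "value": post}
        )
        rows.append(
            {"patient": pid, "fraction": fraction,
             "dose_metric": f"dsm_anterior_{mm}mm_gy", "value": ant}
        )
    return rows


def analyze_cohort(cohort: CohortData, config: RunConfig) -> RunResult:
    """Run the full analysis on an in-memory cohort (deterministic given config)."""
    rng = np.random.default_rng(config.seed)
    top_gy = cohort.prescription_gy + 5.0
    patients: dict[str, PatientResult] = {}
    dsms: dict[str, dict[int, DSM]] = {}
    dose_metric_rows: list[dict] = []
    paired_dvhs: list[tuple[DVH, DVH]] = []
    paired_maps: list[tuple[DSM, DSM]] = []

    for pt in cohort.patients:
        plan_dsm = compute_dsm(
            pt.planning.rectum, pt.planning.dose, {"patient": pt.patient_id, "fraction": 0}
        )
        daily_dsms = [
            compute_dsm(fr.rectum, fr.dose, {"patient": pt.patient_id,
                                             "fraction": fr.fraction_index})
            for fr in pt.fractions
        ]
        dsms[pt.patient_id] = {0: plan_dsm}
        for fr, m in zip(pt.fractions, daily_dsms):
            dsms[pt.patient_id][fr.fraction_index] = m
        accumulated = accumulate(daily_dsms, mode="mean_full_course")
        ddm = dose_difference(plan_dsm, accumulated)

        plan_dvh = pad_dvh_to(
            compute_dvh(pt.planning.dose, pt.planning.rectum, config.dvh_bin_gy), top_gy
        )
        daily_dvhs = [
            pad_dvh_to(compute_dvh(fr.dose, fr.rectum, config.dvh_bin_gy), top_gy)
            for fr in pt.fractions
        ]

        seed_dvh = int(rng.integers(2**31))
        seed_dsm = int(rng.integers(2**31))
        dvh_test = dvh_comparison(
            daily_dvhs, cohort.prescription_gy, "one_sample",
            n_perm=config.n_perm, seed=seed_dvh, reference=plan_dvh,
        )
        dsm_test = mcp_test(
            daily_dsms, reference_map=plan_dsm, mode="one_sample",
            n_perm=config.n_perm, seed=seed_dsm,
            connectivity=config.connectivity, cluster_min=config.cluster_min,
        )
        patients[pt.patient_id] = PatientResult(
            pt.patient_id, plan_dsm, accumulated, ddm, plan_dvh, daily_dvhs,
            dvh_test, dsm_test,
        )
        paired_dvhs.append((plan_dvh, average_dvh(daily_dvhs)))
        paired_maps.append((plan_dsm, accumulated))

        plan_v = v_metrics(plan_dvh, cohort.prescription_gy, list(V_METRIC_PCTS))
        for fr, ddvh, ddsm in zip(pt.fractions, daily_dvhs, daily_dsms):
            day_v = v_metrics(ddvh, cohort.prescription_gy, list(V_METRIC_PCTS))
            for pct in V_METRIC_PCTS:
                dose_metric_rows.append(
                    {"patient": pt.patient_id, "fraction": fr.fraction_index,
                     "dose_metric": f"v{int(pct)}pct",
                     "value": day_v[pct] - plan_v[pct]}
                )
            dose_metric_rows.extend(
                _probe_deviation_rows(pt.patient_id, fr.fraction_index, plan_dsm, ddsm)
            )

    # cohort-wide paired comparisons on the common truncated grid
    seed_cohort_dvh = int(rng.integers(2**31))
    seed_cohort_dsm = int(rng.integers(2**31))
    cohort_dvh_test = dvh_comparison(
        paired_dvhs, cohort.prescription_gy, "paired",
        n_perm=config.n_perm, seed=seed_cohort_dvh,
    )
    flat = [m for pair in paired_maps for m in pair]
    aligned = align_truncate(flat)
    common_pairs = [(aligned[2 * i], aligned[2 * i + 1]) for i in range(len(paired_maps))]
    cohort_dsm_test = mcp_test(
        common_pairs, mode="paired", n_perm=config.n_perm, seed=seed_cohort_dsm,
        connectivity=config.connectivity, cluster_min=config.cluster_min,
    )
    # cohort-average DDM = mean of patient DDMs on the common grid
    n_common = min(p.ddm.values.shape[0] for p in patients.values())
    from .core import DDM as _DDM

    cohort_ddm = _DDM(
        np.mean([p.ddm.values[:n_common] for p in patients.values()], axis=0),
        convention="planned_minus_delivered",
        metadata={"n_patients": len(patients)},
    )

    motion = motion_summary(cohort, dsms, dose_metrics=pd.DataFrame(dose_metric_rows))
    n_flagged_dvh = sum(p.dvh_test.significant for p in patients.values())
    n_flagged_dsm = sum(p.dsm_test.significant for p in patients.values())
    manifest = {
        "dsmkit_version": __version__,
        "config": asdict(config),
        "n_patients": len(patients),
        "prescription_gy": cohort.prescription_gy,
        "n_fractions": cohort.n_fractions,
        "n_flagged_dvh": n_flagged_dvh,
        "n_flagged_dsm": n_flagged_dsm,
        "cohort_dvh_significant": bool(cohort_dvh_test.significant),
        "cohort_dsm_significant": bool(cohort_dsm_test.significant),
    }
    return RunResult(
        patients, cohort_dvh_test, cohort_dsm_test, cohort_ddm, motion,
        n_flagged_dvh, n_flagged_dsm, manifest,
    )


def write_results(result: RunResult, out_dir) -> None:
    """Persist per-patient maps and cohort tables as CSV/JSON text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, pr in result.patients.items():
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        write_map_csv(pr.planned_dsm, pdir / "planned_dsm.csv")
        write_map_csv(pr.accumulated_dsm, pdir / "accumulated_dsm.csv")
        write_map_csv(pr.ddm, pdir / "ddm.csv")
        pd.DataFrame(
            {"dose_gy": pr.dvh_test.test_points_gy, "p": pr.dvh_test.p_values}
        ).to_csv(pdir / "dvh_test.csv", index=False)
    write_map_csv(result.cohort_ddm, out / "cohort_ddm.csv")
    summary_rows = [
        {"patient": pid,
         "dvh_significant": pr.dvh_test.significant,
         "dsm_significant": pr.dsm_test.significant}
        for pid, pr in result.patients.items()
    ]
    pd.DataFrame(summary_rows).to_csv(out / "patient_flags.csv", index=False)
    for name, df in result.motion.items():
        df.to_csv(out / f"motion_{name}.csv", index=False)
    pd.DataFrame(
        {"dose_gy": result.cohort_dvh_test.test_points_gy,
         "p": result.cohort_dvh_test.p_values}
    ).to_csv(out / "cohort_dvh_test.csv", index=False)
    np.savetxt(out / "cohort_dsm_p_map.csv", result.cohort_dsm_test.p_map,
               fmt="%.6f", delimiter=",")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> RunResult:
    """Load a fixture cohort from disk, analyse it, optionally write results."""
    cohort = read_fixture_cohort(config.cohort_path)
    result = analyze_cohort(cohort, config)
    if config.out_dir is not None:
        write_results(result, config.out_dir)
    return result
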