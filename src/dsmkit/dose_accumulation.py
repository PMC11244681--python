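"""Alignment, truncation and combination of daily dose-surface maps.

Daily rectal contours vary in length, so daily DSMs are aligned at their
inferior borders (row 0) and truncated to the shortest map before any
pointwise arithmetic — the inferior rectal border is the landmark least
affected by interfraction change.  Each daily dose grid is a full-course
recalculation, so the accumulated full-course map is the mean of daily
full-course maps (equivalently the sum of per-fraction maps, each a daily
map divided by the number of fractions).
"""

from __future__ import annotations

import numpy as np

from .core import DDM, DSM


def align_truncate(maps: list[DSM]) -> list[DSM]:
    """Truncate every map to the row count of the shortest, keeping rows 0..min-1."""
    if not maps:
        raise ValueError("no maps to align")
    cols = {m.angular_count for m in maps}
    if len(cols) != 1:
        raise ValueError(f"mixed angular counts {sorted(cols)}")
    n = min(m.n_rows for m in maps)
    return [
        DSM(
            m.dose[:n],
            m.points[:n],
            m.row_spacing_mm,
            m.angular_count,
            dict(m.metadata),
        )
        for m in maps
    ]


def accumulate(daily: list[DSM], mode: str = "mean_full_course") -> DSM:
    """Combine daily maps into one estimate of the delivered dose.

    ``sum_per_fraction`` adds maps already scaled to single fractions;
    ``mean_full_course`` averages daily full-course maps.  The two coincide
    when daily full-course maps are divided by the fraction count first.
    """
    if not daily:
        raise ValueError("no daily maps to accumulate")
    if mode not in ("sum_per_fraction", "mean_full_course"):
        raise ValueError(f"unknown accumulation mode {mode!r}")
    aligned = align_truncate(daily)
    stack = np.stack([m.dose for m in aligned])
    values = stack.sum(axis=0) if mode == "sum_per_fraction" else stack.mean(axis=0)
    ref = aligned[0]
    meta = {"accumulation_mode": mode, "n_maps": len(daily)}
    return DSM(values, ref.points.copy(), ref.row_spacing_mm, ref.angular_count, meta)


def dose_difference(a: DSM, b: DSM) -> DDM:
    """Pointwise a - b on the common truncated grid (planned minus delivered)."""
    ta, tb = align_truncate([a, b])
    return DDM(
        values=ta.dose - tb.dose,
        row_spacing_mm=ta.row_spacing_mm,
        angular_count=ta.angular_count,
        convention="first_minus_second",
        metadata={"a": a.metadata, "b": b.metadata},
    )


def cohort_average(maps: list[DSM]) -> DSM:
    """Pointwise mean across patients after inferior alignment and truncation."""
    if not maps:
        raise ValueError("no maps to average")
    aligned = align_truncate(maps)
    stack = np.stack([m.dose for m in aligned])
    ref = aligned[0]
    return DSM(
        stack.mean(axis=0),
        ref.points.copy(),
        ref.row_spacing_mm,
        ref.angular_count,
        {"n_maps": len(maps), "cohort_average": True},
    )
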