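"""Permutation inference for DVH curves and dose-surface maps.

Planned and delivered doses are compared with sign-flip permutation tests on
the mean difference, two-sided throughout:

* DVH curves are tested at 5 Gy steps across the prescription range, and a
  patient/cohort is flagged only when three or more consecutive test points
  (a continuous 10 Gy range) have p <= 0.05;
* DSMs are tested per pixel with one shared sequence of sign-flip draws
  across all pixels (preserving spatial correlation of the null maps), and a
  map is flagged only when five or more contiguous p <= 0.05 pixels form a
  cluster.  Contiguity is 4-neighbour by default and wraps across the
  lateral map edges, which are spatially adjacent at the posterior cut.

For n <= 12 subjects all 2^n sign patterns are enumerated and p-values are
exact; otherwise Monte-Carlo draws give p = (1 + #extreme) / (1 + n_perm),
never exactly zero.  Wilcoxon signed-rank and Pearson correlation (used for
the interfraction-motion analysis) delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import DSM, DVH
from .dose_accumulation import align_truncate
from .dvh_analysis import rel_volume_at

P_THRESHOLD = 0.05
RUN_MIN = 3  # consecutive DVH test points
CLUSTER_MIN = 5  # contiguous DSM pixels
DVH_STEP_GY = 5.0
EXACT_ENUM_MAX = 12
_EPS = 1e-12


@dataclass
class PointwiseTestResult:
    test_points_gy: np.ndarray
    p_values: np.ndarray
    significant: bool
    significant_ranges_gy: list[tuple[float, float]]


@dataclass
class MapTestResult:
    p_map: np.ndarray
    significant_mask: np.ndarray
    significant: bool
    clusters: list[set[tuple[int, int]]] = field(default_factory=list)
    mean_difference: np.ndarray | None = None


def _sign_matrix(
    n: int, n_perm: int, seed: int | None, method: str = "auto"
) -> tuple[np.ndarray, bool]:
    """(P, n) matrix of +-1 sign patterns.

    ``method='auto'`` enumerates all 2^n patterns exactly when n <= 12 and
    falls back to seeded Monte-Carlo draws otherwise; 'exact' and
    'monte_carlo' force the respective mode.
    """
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    exact = method == "exact" or (method == "auto" and n <= EXACT_ENUM_MAX)
    if exact:
        if n > 20:
            raise ValueError(f"exact enumeration infeasible for n={n}")
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        return 2.0 * bits - 1.0, True
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_perm, n)), False


def _p_from_signs(diffs: np.ndarray, signs: np.ndarray, exact: bool) -> np.ndarray:
    """Two-sided sign-flip p-values for columns of ``diffs`` ((n,) or (n, k))."""
    d = np.atleast_2d(np.asarray(diffs, dtype=float).T).T  # (n, k)
    t_obs = np.abs(d.mean(axis=0))  # (k,)
    t_perm = np.abs(signs @ d) / d.shape[0]  # (P, k)
    extreme = t_perm >= t_obs[None, :] - _EPS
    if exact:
        p = extreme.mean(axis=0)
    else:
        p = (1.0 + extreme.sum(axis=0)) / (1.0 + signs.shape[0])
    return p


def perm_test_one_sample(
    samples: list[float] | np.ndarray,
    reference: float,
    n_perm: int = 2000,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """Sign-flip test of mean(samples - reference) against zero."""
    diffs = np.asarray(samples, dtype=float) - float(reference)
    if diffs.size < 2:
        raise ValueError("need at least 2 samples")
    if np.all(diffs == 0):
        return 1.0
    signs, exact = _sign_matrix(diffs.size, n_perm, seed, method)
    return float(_p_from_signs(diffs, signs, exact)[0])


def perm_test_paired(
    a: list[float] | np.ndarray,
    b: list[float] | np.ndarray,
    n_perm: int = 2000,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """Paired comparison: pair-label swap is a sign flip of within-pair differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0
    signs, exact = _sign_matrix(diffs.size, n_perm, seed, method)
    return float(_p_from_signs(diffs, signs, exact)[0])


def _runs_at_threshold(p: np.ndarray, run_min: int) -> list[tuple[int, int]]:
    """Index ranges [i, j] of runs of p <= threshold with length >= run_min."""
    sig = p <= P_THRESHOLD + _EPS
    ranges = []
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            if j - i + 1 >= run_min:
                ranges.append((i, j))
            i = j + 1
        else:
            i += 1
    return ranges


def dvh_test_points(prescription_gy: float) -> np.ndarray:
    """5, 10, ... Gy up to the prescription (36.25 -> last point 35)."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    return DVH_STEP_GY * np.arange(1, int(prescription_gy // DVH_STEP_GY) + 1)


def dvh_comparison(
    curves,
    prescription_gy: float,
    mode: str,
    n_perm: int = 2000,
    seed: int | None = None,
    reference: DVH | None = None,
) -> PointwiseTestResult:
    """Pointwise DVH permutation tests with the >=3-consecutive-points rule.

    ``mode='one_sample'``: ``curves`` are one patient's daily DVHs tested
    against the planned ``reference`` DVH.  ``mode='paired'``: ``curves`` is a
    list of (planned, delivered) DVH pairs across patients.  One shared set
    of sign-flip draws is used across all test points so the run criterion
    acts on coherent p-values.
    """
    points = dvh_test_points(prescription_gy)
    if len(points) < RUN_MIN:
        raise ValueError("prescription range yields fewer than 3 test points")
    if mode == "one_sample":
        if reference is None:
            raise ValueError("one_sample mode requires a reference DVH")
        diffs = np.array(
            [
                [rel_volume_at(c, d) - rel_volume_at(reference, d) for d in points]
                for c in curves
            ]
        )
    elif mode == "paired":
        diffs = np.array(
            [
                [rel_volume_at(b, d) - rel_volume_at(a, d) for d in points]
                for a, b in curves
            ]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if diffs.shape[0] < 2:
        raise ValueError("need at least 2 curves/pairs")
    return pointwise_run_test(diffs, points, n_perm=n_perm, seed=seed)


def pointwise_run_test(
    diffs: np.ndarray,
    test_points_gy: np.ndarray,
    n_perm: int = 2000,
    seed: int | None = None,
    run_min: int = RUN_MIN,
    method: str = "auto",
) -> PointwiseTestResult:
    """Run-rule permutation test on a raw (n_subjects, n_points) difference matrix.

    One shared set of sign-flip draws across the test points; significance
    requires >= ``run_min`` consecutive points with p <= 0.05.
    """
    diffs = np.asarray(diffs, dtype=float)
    points = np.asarray(test_points_gy, dtype=float)
    signs, exact = _sign_matrix(diffs.shape[0], n_perm, seed, method)
    p = _p_from_signs(diffs, signs, exact)
    p = np.where(np.all(diffs == 0, axis=0), 1.0, p)
    runs = _runs_at_threshold(p, run_min)
    ranges = [(float(points[i]), float(points[j])) for i, j in runs]
    return PointwiseTestResult(points, p, bool(ranges), ranges)


def _cluster_mask(
    sig: np.ndarray, connectivity: int = 4, wrap_columns: bool = True
) -> list[set[tuple[int, int]]]:
    """Connected components of a boolean map; columns optionally wrap."""
    from scipy import ndimage

    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3))
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(sig, structure=structure)
    if n == 0:
        return []
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    if wrap_columns and sig.shape[1] > 1:
        rows = np.arange(sig.shape[0])
        for r in rows:
            if sig[r, 0] and sig[r, -1]:
                union(labels[r, 0], labels[r, -1])
            if connectivity == 8:
                for dr in (-1, 1):
                    rr = r + dr
                    if 0 <= rr < sig.shape[0]:
                        if sig[r, 0] and sig[rr, -1]:
                            union(labels[r, 0], labels[rr, -1])
    groups: dict[int, set[tuple[int, int]]] = {}
    it = np.nonzero(sig)
    for r, c in zip(*it):
        root = find(labels[r, c])
        groups.setdefault(root, set()).add((int(r), int(c)))
    return list(groups.values())


def mcp_test(
    maps,
    reference_map: DSM | None = None,
    mode: str = "one_sample",
    n_perm: int = 2000,
    seed: int | None = None,
    connectivity: int = 4,
    wrap_columns: bool = True,
    cluster_min: int = CLUSTER_MIN,
    familywise: bool = False,
) -> MapTestResult:
    """Multiple-comparisons permutation test on dose maps.

    ``mode='one_sample'``: ``maps`` are one patient's daily full-course DSMs
    tested against the planned ``reference_map``.  ``mode='paired'``:
    ``maps`` is a list of (planned, delivered) DSM pairs across patients.
    Per-pixel two-sided sign-flip p-values use one shared sequence of draws
    across pixels; a map is significant when a cluster of >= ``cluster_min``
    contiguous p <= 0.05 pixels exists, and ``significant_mask`` marks
    exactly the pixels of qualifying clusters.

    ``familywise=True`` selects instead the max-statistic familywise
    correction (p = fraction of permutations whose maximum |mean difference|
    over pixels exceeds the pixel's observed value); the contiguity rule is
    still applied to the resulting p-map.
    """
    if mode == "one_sample":
        if reference_map is None:
            raise ValueError("one_sample mode requires a reference map")
        aligned = align_truncate(list(maps) + [reference_map])
        ref = aligned[-1]
        diffs = np.stack([m.dose - ref.dose for m in aligned[:-1]])
    elif mode == "paired":
        pairs = [align_truncate([a, b]) for a, b in maps]
        shapes = {p[0].dose.shape for p in pairs}
        if len(shapes) != 1:
            raise ValueError("paired maps must share a common truncated shape")
        diffs = np.stack([b.dose - a.dose for a, b in pairs])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n, rows, cols = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 maps/pairs")
    flat = diffs.reshape(n, rows * cols)
    signs, exact = _sign_matrix(n, n_perm, seed)
    if familywise:
        t_obs = np.abs(flat.mean(axis=0))
        t_perm = np.abs(signs @ flat) / n  # (P, K)
        t_max = t_perm.max(axis=1)  # (P,)
        extreme = t_max[:, None] >= t_obs[None, :] - _EPS
        if exact:
            p = extreme.mean(axis=0)
        else:
            p = (1.0 + extreme.sum(axis=0)) / (1.0 + signs.shape[0])
    else:
        p = _p_from_signs(flat, signs, exact)
    p = np.where(np.all(flat == 0, axis=0), 1.0, p).reshape(rows, cols)
    sig = p <= P_THRESHOLD + _EPS
    clusters = _cluster_mask(sig, connectivity, wrap_columns)
    qualifying = [c for c in clusters if len(c) >= cluster_min]
    mask = np.zeros_like(sig)
    for c in qualifying:
        for r, col in c:
            mask[r, col] = True
    return MapTestResult(
        p_map=p,
        significant_mask=mask,
        significant=bool(qualifying),
        clusters=qualifying,
        mean_difference=flat.mean(axis=0).reshape(rows, cols),
    )


def wilcoxon_signed_rank(differences) -> float:
    """Two-sided Wilcoxon signed-rank p; zeros dropped; exact for n <= 25.

    The exact null distribution is used when, after zero removal, n <= 25
    and the absolute differences are tie-free; otherwise the normal
    approximation with tie correction is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.abs(d) > 1e-9]  # zero-difference removal, with float-residue tolerance
    if d.size == 0:
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    return float(
        sps.wilcoxon(d, alternative="two-sided", method=method).pvalue
    )


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation r and r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1D samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


def mcp_test_arrays(
    diffs: np.ndarray,
    n_perm: int = 2000,
    seed: int | None = None,
    connectivity: int = 4,
    wrap_columns: bool = True,
    cluster_min: int = CLUSTER_MIN,
) -> MapTestResult:
    """MCP test on a raw (n_subjects, rows, cols) stack of difference maps.

    Convenience entry point used for calibration studies where maps are
    produced directly as arrays rather than DSM objects.
    """
    diffs = np.asarray(diffs, dtype=float)
    n, rows, cols = diffs.shape
    flat = diffs.reshape(n, rows * cols)
    signs, exact = _sign_matrix(n, n_perm, seed)
    p = _p_from_signs(flat, signs, exact)
    p = np.where(np.all(flat == 0, axis=0), 1.0, p).reshape(rows, cols)
    sig = p <= P_THRESHOLD + _EPS
    clusters = _cluster_mask(sig, connectivity, wrap_columns)
    qualifying = [c for c in clusters if len(c) >= cluster_min]
    mask = np.zeros_like(sig)
    for c in qualifying:
        for r, col in c:
            mask[r, col] = True
    return MapTestResult(
        p_map=p,
        significant_mask=mask,
        significant=bool(qualifying),
        clusters=qualifying,
        mean_difference=flat.mean(axis=0).reshape(rows, cols),
    )
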