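"""Per-joint summary metrics and paired longitudinal comparison.

For every joint/view/timepoint the pipeline records the overall mean
density and the maximum density over the articular surface (in mg HA/cm³,
via the phantom calibration), the maximum area ratio, and the grid
coordinates of the detected density maxima.  Cohorts of paired (t1, t2)
scans are then compared metric by metric: paired differences are checked
for normality with the Shapiro–Wilk test and evaluated with a two-sided
paired Student's t-test (α = .05 by default).

Maxima locations are compared by matching each subject's t2 maxima to its
t1 maxima by nearest grid centroid, averaging the matched (Δx, Δy) per
subject, and testing the per-subject displacements — per coordinate with
paired t-tests and jointly with a Hotelling T² test (how x and y should be
combined into a single per-view p-value is a genuinely open convention, so
both are reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationFit, apply_calibration
from .densitometry import MarResult, QuantizedDensitogram
from .errors import CohortError, ConsistencyError, PairingError
from .projection import Densitogram

__all__ = [
    "JointMetrics",
    "PairedCohortResult",
    "summarize_joint",
    "compare_paired",
    "match_maxima",
    "metrics_to_frame",
]

#: scalar metrics compared between time points (mar on the ×100 scale)
METRICS = ("mean_density", "max_density", "mar_pct")


@dataclass
class JointMetrics:
    """Per-joint, per-view, per-timepoint summary."""

    subject_id: str
    timepoint: str
    view: str
    mean_density: float          # mg HA/cm³, mean over surface pixels
    max_density: float           # mg HA/cm³, max over surface pixels
    mean_hu: float
    max_hu: float
    mar: float                   # ratio in [0, 1]
    mar_pct: float
    maxima_grid: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.max_density < self.mean_density:
            raise ConsistencyError("max density below mean density")


def summarize_joint(
    dg: Densitogram,
    q: QuantizedDensitogram,
    mar: MarResult,
    fit: CalibrationFit,
) -> JointMetrics:
    """Collapse one calibrated densitogram into its scalar metrics.

    All inputs must describe the same joint/view/timepoint; the quantized
    densitogram must have been derived from ``dg``.
    """
    if q.source is not dg and (
        q.source.subject_id != dg.subject_id
        or q.source.view_name != dg.view_name
        or q.source.timepoint != dg.timepoint
    ):
        raise ConsistencyError(
            "quantized densitogram does not match the densitogram "
            f"({q.source.subject_id}/{q.source.view_name}/{q.source.timepoint} vs "
            f"{dg.subject_id}/{dg.view_name}/{dg.timepoint})"
        )
    if dg.values_density is None:
        dg.values_density = apply_calibration(dg.values_hu, fit)
    hu = dg.values_hu[dg.surface_mask]
    dens = dg.values_density[dg.surface_mask]
    # locations are characterized by the density peak (scale-invariant),
    # falling back to the area centroid if a peak was not mapped
    maxima = [
        r["peak_grid"] if r["peak_grid"] is not None else r["centroid_grid"]
        for r in mar.per_region
        if r["peak_grid"] is not None or r["centroid_grid"] is not None
    ]
    return JointMetrics(
        subject_id=dg.subject_id or "",
        timepoint=dg.timepoint or "",
        view=dg.view_name,
        mean_density=float(dens.mean()),
        max_density=float(dens.max()),
        mean_hu=float(hu.mean()),
        max_hu=float(hu.max()),
        mar=mar.mar,
        mar_pct=mar.mar_pct,
        maxima_grid=maxima,
    )


def metrics_to_frame(metrics: list[JointMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        row = {
            "subject_id": m.subject_id,
            "timepoint": m.timepoint,
            "view": m.view,
            "mean_density": m.mean_density,
            "max_density": m.max_density,
            "mean_hu": m.mean_hu,
            "max_hu": m.max_hu,
            "mar": m.mar,
            "mar_pct": m.mar_pct,
            "n_maxima": len(m.maxima_grid),
        }
        for i, (x, y) in enumerate(m.maxima_grid):
            row[f"max{i + 1}_x"] = x
            row[f"max{i + 1}_y"] = y
        rows.append(row)
    return pd.DataFrame(rows)


def match_maxima(
    t1: list[tuple[float, float]], t2: list[tuple[float, float]]
) -> list[tuple[int, int]]:
    """Greedy nearest-centroid matching of t2 maxima to t1 maxima.

    Returns index pairs (i1, i2); unmatched maxima are dropped.
    """
    pairs = []
    if not t1 or not t2:
        return pairs
    cand = [
        (np.hypot(a[0] - b[0], a[1] - b[1]), i, j)
        for i, a in enumerate(t1)
        for j, b in enumerate(t2)
    ]
    used1: set[int] = set()
    used2: set[int] = set()
    for _, i, j in sorted(cand):
        if i in used1 or j in used2:
            continue
        pairs.append((i, j))
        used1.add(i)
        used2.add(j)
    return pairs


@dataclass
class PairedCohortResult:
    """Table-style result of the paired comparison.

    ``table`` has one row per (view, metric) with t1/t2 mean (SD), the
    Shapiro–Wilk p of the paired differences, the paired t statistic and
    its two-sided p; ``coordinates`` has one row per view with the
    per-coordinate and Hotelling tests of maximum displacement.
    """

    table: pd.DataFrame
    coordinates: pd.DataFrame
    alpha: float
    n_subjects: int


def _paired_test(diffs: np.ndarray):
    """(shapiro_p, t, p, flag) for one vector of paired differences."""
    flag = ""
    diffs = np.asarray(diffs, dtype=float)
    shapiro_p = np.nan
    if len(diffs) >= 3 and np.ptp(diffs) > 0:
        shapiro_p = float(stats.shapiro(diffs).pvalue)
    if np.std(diffs, ddof=1) == 0:
        if np.all(diffs == 0):
            return shapiro_p, 0.0, 1.0, "identical"
        return shapiro_p, np.nan, np.nan, "zero_variance"
    t, p = stats.ttest_rel(diffs, np.zeros_like(diffs))
    return shapiro_p, float(t), float(p), flag


def _hotelling_one_sample(d: np.ndarray):
    """One-sample Hotelling T² against zero mean; returns (T², F, p)."""
    n, p = d.shape
    if n <= p:
        return np.nan, np.nan, np.nan
    mean = d.mean(axis=0)
    cov = np.cov(d, rowvar=False, ddof=1)
    try:
        t2 = float(n * mean @ np.linalg.solve(cov, mean))
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    f = (n - p) / (p * (n - 1)) * t2
    return t2, float(f), float(stats.f.sf(f, p, n - p))


def compare_paired(
    metrics: list[JointMetrics] | pd.DataFrame,
    alpha: float = 0.05,
    maxima: dict[tuple[str, str, str], list[tuple[float, float]]] | None = None,
) -> PairedCohortResult:
    """Paired t1-vs-t2 comparison of all metrics, per view.

    Parameters
    ----------
    metrics:
        Long-format metrics (one entry per subject/timepoint/view).
    alpha:
        Significance level (two-sided).
    maxima:
        Optional maxima coordinates keyed by (subject, timepoint, view);
        when ``metrics`` is a list of :class:`JointMetrics` they are taken
        from there.

    Raises
    ------
    PairingError
        If any subject lacks one of the two time points for a view.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics.copy()
        if maxima is None:
            maxima = {}
    else:
        df = metrics_to_frame(metrics)
        maxima = {
            (m.subject_id, m.timepoint, m.view): m.maxima_grid for m in metrics
        }
    views = sorted(df["view"].unique())
    rows = []
    coord_rows = []
    n_subjects = df["subject_id"].nunique()
    if n_subjects < 2:
        raise CohortError("paired comparison needs at least 2 subjects")
    for view in views:
        sub = df[df["view"] == view]
        piv: dict[str, pd.DataFrame] = {}
        for tp in ("t1", "t2"):
            piv[tp] = sub[sub["timepoint"] == tp].set_index("subject_id")
        missing = sorted(set(piv["t1"].index) ^ set(piv["t2"].index))
        if missing:
            raise PairingError(
                f"view {view}: subjects missing a time point: {', '.join(missing)}"
            )
        subjects = sorted(piv["t1"].index)
        for metric in METRICS:
            a = piv["t1"].loc[subjects, metric].to_numpy(dtype=float)
            b = piv["t2"].loc[subjects, metric].to_numpy(dtype=float)
            shapiro_p, t, p, flag = _paired_test(b - a)
            rows.append(
                {
                    "view": view,
                    "metric": metric,
                    "t1_mean": a.mean(),
                    "t1_sd": a.std(ddof=1),
                    "t2_mean": b.mean(),
                    "t2_sd": b.std(ddof=1),
                    "n": len(subjects),
                    "shapiro_p": shapiro_p,
                    "t_stat": t,
                    "p_value": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                    "flag": flag,
                }
            )
        # maximum displacement per subject (t2 − t1, matched by proximity)
        disp = []
        for sid in subjects:
            m1 = maxima.get((sid, "t1", view), [])
            m2 = maxima.get((sid, "t2", view), [])
            pairs = match_maxima(m1, m2)
            if not pairs:
                continue
            dd = np.array([[m2[j][0] - m1[i][0], m2[j][1] - m1[i][1]] for i, j in pairs])
            disp.append(dd.mean(axis=0))
        if disp:
            d = np.asarray(disp)
            _, tx, px, _ = _paired_test(d[:, 0])
            _, ty, py, _ = _paired_test(d[:, 1])
            t2s, f, ph = _hotelling_one_sample(d)
            coord_rows.append(
                {
                    "view": view,
                    "n": len(d),
                    "dx_mean": d[:, 0].mean(),
                    "dy_mean": d[:, 1].mean(),
                    "t_x": tx,
                    "p_x": px,
                    "t_y": ty,
                    "p_y": py,
                    "hotelling_T2": t2s,
                    "hotelling_p": ph,
                    "significant": bool(ph < alpha) if np.isfinite(ph) else False,
                }
            )
        else:
            coord_rows.append(
                {
                    "view": view, "n": 0, "dx_mean": np.nan, "dy_mean": np.nan,
                    "t_x": np.nan, "p_x": np.nan, "t_y": np.nan, "p_y": np.nan,
                    "hotelling_T2": np.nan, "hotelling_p": np.nan, "significant": False,
                }
            )
    return PairedCohortResult(
        table=pd.DataFrame(rows),
        coordinates=pd.DataFrame(coord_rows),
        alpha=alpha,
        n_subjects=n_subjects,
    )
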