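"""Joint summaries and paired longitudinal statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_densitogram
from ctoam.calibration import CalibrationFit
from ctoam.cohort import (
    JointMetrics,
    compare_paired,
    match_maxima,
    summarize_joint,
)
from ctoam.densitometry import GridFrame, compute_mar, detect_maxima, quantize
from ctoam.errors import ConsistencyError, PairingError


def _identity_fit():
    return CalibrationFit(
        slope=1.0, intercept=0.0, r_squared=1.0,
        residuals=np.zeros(2), mean_hu=np.array([0.0, 1.0]),
        densities=np.array([0.0, 1.0]),
    )


def _summarize(arr, **kw):
    dg = make_densitogram(arr, **kw)
    q = quantize(dg)
    maxima = detect_maxima(q)
    frame = GridFrame.from_surface_mask(dg.surface_mask)
    for r in maxima:
        r.centroid_grid = frame.pixel_to_grid(*r.centroid_px)
        r.peak_grid = frame.pixel_to_grid(*r.peak_px)
    return summarize_joint(dg, q, compute_mar(maxima, dg.surface_mask), _identity_fit())


class TestSummarizeJoint:
    def test_constant_surface(self):
        m = _summarize(np.full((6, 6), 450.0), subject="S01", timepoint="t1")
        assert m.mean_density == pytest.approx(450.0)
        assert m.max_density == pytest.approx(450.0)

    def test_mixed_surface_arithmetic(self):
        arr = np.full((10, 10), 600.0)
        arr[0, 0] = 1100.0
        m = _summarize(arr)
        assert m.mean_density == pytest.approx(605.0)
        assert m.max_density == pytest.approx(1100.0)

    def test_provenance_mismatch_rejected(self):
        dg1 = make_densitogram(np.full((4, 4), 500.0), subject="S01", timepoint="t1")
        dg2 = make_densitogram(np.full((4, 4), 500.0), subject="S02", timepoint="t1")
        q2 = quantize(dg2)
        mar = compute_mar([], dg1.surface_mask)
        with pytest.raises(ConsistencyError):
            summarize_joint(dg1, q2, mar, _identity_fit())


def _metric(sid, tp, mean, view="proximal", maxima=None):
    return JointMetrics(
        subject_id=sid, timepoint=tp, view=view,
        mean_density=mean, max_density=mean + 300.0,
        mean_hu=mean, max_hu=mean + 300.0,
        mar=0.1, mar_pct=10.0, maxima_grid=maxima or [],
    )


class TestComparePaired:
    def test_identical_timepoints_give_t_zero_p_one(self):
        metrics = []
        for i, v in enumerate([500.0, 520.0, 540.0, 610.0]):
            metrics += [_metric(f"S{i}", "t1", v), _metric(f"S{i}", "t2", v)]
        res = compare_paired(metrics)
        row = res.table[res.table["metric"] == "mean_density"].iloc[0]
        assert row["t_stat"] == 0.0
        assert row["p_value"] == 1.0
        assert row["flag"] == "identical"

    def test_constant_offset_flagged_degenerate(self):
        metrics = []
        for i, v in enumerate([500.0, 520.0, 540.0]):
            metrics += [_metric(f"S{i}", "t1", v), _metric(f"S{i}", "t2", v + 25.0)]
        res = compare_paired(metrics)
        row = res.table[res.table["metric"] == "mean_density"].iloc[0]
        assert row["flag"] == "zero_variance"
        assert np.isnan(row["p_value"])

    def test_subject_order_irrelevant_and_swap_flips_sign(self, rng):
        vals1 = rng.normal(600, 40, size=8)
        vals2 = vals1 + rng.normal(30, 20, size=8)
        m = []
        for i, (a, b) in enumerate(zip(vals1, vals2)):
            m += [_metric(f"S{i}", "t1", a), _metric(f"S{i}", "t2", b)]
        res_fwd = compare_paired(m)
        res_rev = compare_paired(m[::-1])
        pd.testing.assert_frame_equal(res_fwd.table, res_rev.table)
        swapped = [
            _metric(x.subject_id, {"t1": "t2", "t2": "t1"}[x.timepoint], x.mean_density)
            for x in m
        ]
        res_sw = compare_paired(swapped)
        r1 = res_fwd.table[res_fwd.table["metric"] == "mean_density"].iloc[0]
        r2 = res_sw.table[res_sw.table["metric"] == "mean_density"].iloc[0]
        assert r2["t_stat"] == pytest.approx(-r1["t_stat"])
        assert r2["p_value"] == pytest.approx(r1["p_value"])

    def test_missing_pair_lists_subject(self):
        m = [_metric("S0", "t1", 500.0), _metric("S0", "t2", 510.0),
             _metric("S1", "t1", 520.0)]
        with pytest.raises(PairingError, match="S1"):
            compare_paired(m)

    def test_table_schema_mirrors_summary_layout(self):
        m = []
        for i in range(3):
            for view in ("proximal", "dorsal"):
                m += [_metric(f"S{i}", "t1", 500.0 + i, view=view),
                      _metric(f"S{i}", "t2", 560.0 + 2 * i, view=view)]
        res = compare_paired(m)
        assert set(res.table["view"]) == {"proximal", "dorsal"}
        assert set(res.table["metric"]) == {"mean_density", "max_density", "mar_pct"}
        for col in ("t1_mean", "t1_sd", "t2_mean", "t2_sd", "shapiro_p", "p_value"):
            assert col in res.table.columns

    def test_empirical_power_matches_noncentral_t(self):
        """Paired shift of 1 SD, n = 10: empirical rejection over 1000
        replicates agrees with the closed-form noncentral-t power."""
        n, delta, sd, alpha = 10, 1.0, 1.0, 0.05
        # closed-form oracle
        nc = delta / (sd / np.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        power = (1 - stats.nct.cdf(tcrit, n - 1, nc)) + stats.nct.cdf(-tcrit, n - 1, nc)
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 1000
        for _ in range(reps):
            base = rng.normal(600.0, 35.0, size=n)
            diff = rng.normal(delta, sd, size=n)
            m = []
            for i in range(n):
                m += [_metric(f"S{i}", "t1", base[i]),
                      _metric(f"S{i}", "t2", base[i] + diff[i])]
            res = compare_paired(m, alpha=alpha)
            row = res.table[res.table["metric"] == "mean_density"].iloc[0]
            hits += row["p_value"] < alpha
        assert abs(hits / reps - power) < 0.04


class TestMatchMaxima:
    def test_nearest_pairing(self):
        t1 = [(5.0, 5.0), (20.0, 10.0)]
        t2 = [(19.5, 10.5), (5.5, 4.5)]
        assert sorted(match_maxima(t1, t2)) == [(0, 1), (1, 0)]

    def test_empty_lists(self):
        assert match_maxima([], [(1.0, 1.0)]) == []
        assert match_maxima([(1.0, 1.0)], []) == []

    def test_unbalanced_drops_extra(self):
        pairs = match_maxima([(0.0, 0.0), (10.0, 10.0)], [(9.0, 9.0)])
        assert pairs == [(1, 0)]
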