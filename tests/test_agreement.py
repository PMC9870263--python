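"""Bland-Altman agreement, regression, error metrics, timepoint tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rollgait import (
    DegenerateInputError,
    InvalidInputError,
    bland_altman,
    compare_timepoints,
    error_metrics,
    linear_fit,
    paired_ttest,
    summarize_cohort,
)
from rollgait.errors import ZeroVarianceTTestWarning


class TestBlandAltman:
    def test_constant_offset(self, rng):
        r = rng.normal(size=100)
        res = bland_altman(r + 2.0, r)
        assert res.m_dif == pytest.approx(2.0)
        assert res.sd == pytest.approx(0.0, abs=1e-12)
        assert res.rpc == pytest.approx(0.0, abs=1e-12)
        assert res.ula == pytest.approx(2.0)
        assert res.lla == pytest.approx(2.0)

    def test_unit_sd_gives_rpc_196(self):
        # Differences [-1, 0, 1] have sample sd exactly 1.
        res = bland_altman(np.array([-1.0, 0.0, 1.0]), np.zeros(3))
        assert res.sd == 1.0
        assert res.rpc == 1.96

    def test_random_series_match_direct_oracle(self, rng):
        for _ in range(20):
            s = rng.normal(5, 3, size=rng.integers(2, 50))
            r = s + rng.normal(1, 2, size=len(s))
            res = bland_altman(s, r)
            d = s - r
            assert res.m_dif == pytest.approx(d.mean(), rel=1e-12, abs=1e-12)
            assert res.sd == pytest.approx(d.std(ddof=1), rel=1e-12)
            assert res.rpc == pytest.approx(1.96 * d.std(ddof=1), rel=1e-12)
            assert res.ula == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), rel=1e-9)
            assert res.lla == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), rel=1e-9)

    @given(st.integers(0, 1000))
    def test_limits_span_twice_rpc(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=10)
        r = rng.normal(size=10)
        res = bland_altman(s, r)
        assert res.ula - res.lla == pytest.approx(2 * res.rpc, rel=1e-12, abs=1e-12)

    def test_swap_symmetry(self, rng):
        s, r = rng.normal(size=(2, 40))
        fwd, rev = bland_altman(s, r), bland_altman(r, s)
        assert rev.m_dif == pytest.approx(-fwd.m_dif)
        assert rev.rpc == pytest.approx(fwd.rpc)
        assert rev.ula == pytest.approx(-fwd.lla)
        assert rev.lla == pytest.approx(-fwd.ula)

    def test_scale_equivariance(self, rng):
        s, r = rng.normal(size=(2, 40))
        k = -3.7
        base, scaled = bland_altman(s, r), bland_altman(k * s, k * r)
        assert scaled.rpc == pytest.approx(abs(k) * base.rpc)
        assert scaled.m_dif == pytest.approx(k * base.m_dif)

    def test_reference_rezeroing_shifts_bias_only(self, rng):
        s, r = rng.normal(size=(2, 200))
        c = 4.2
        base, shifted = bland_altman(s, r), bland_altman(s, r - c)
        assert shifted.m_dif == pytest.approx(base.m_dif + c)
        assert shifted.sd == pytest.approx(base.sd, rel=1e-12)
        assert shifted.rpc == pytest.approx(base.rpc, rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            bland_altman([1.0], [1.0])


class TestLinearFit:
    def test_exact_line(self, rng):
        s = rng.normal(size=50)
        res = linear_fit(s, 0.85 * s + 2.0)
        assert res.m == pytest.approx(0.85)
        assert res.b == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_identity(self, rng):
        s = rng.normal(size=50)
        res = linear_fit(s, s)
        assert (res.m, res.b, res.r2) == (
            pytest.approx(1.0),
            pytest.approx(0.0, abs=1e-12),
            pytest.approx(1.0),
        )

    def test_noisy_data_match_normal_equations_oracle(self, rng):
        x = rng.normal(size=300)
        y = 1.4 * x - 0.7 + rng.normal(0, 0.5, size=300)
        res = linear_fit(x, y)
        # Closed-form normal equations, independent of scipy.
        xm, ym = x.mean(), y.mean()
        m = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        b = ym - m * xm
        r2 = (np.sum((x - xm) * (y - ym)) ** 2) / (
            np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)
        )
        assert res.m == pytest.approx(m, abs=1e-9)
        assert res.b == pytest.approx(b, abs=1e-9)
        assert res.r2 == pytest.approx(r2, abs=1e-9)

    def test_scaling_both_preserves_r2(self, rng):
        x = rng.normal(size=100)
        y = 0.9 * x + rng.normal(0, 0.3, size=100)
        assert linear_fit(3.3 * x, 3.3 * y).r2 == pytest.approx(
            linear_fit(x, y).r2, rel=1e-12
        )

    def test_predictor_switch(self, rng):
        x = rng.normal(size=100)
        y = 0.8 * x + rng.normal(0, 0.2, size=100)
        fwd = linear_fit(x, y, predictor="sensor")
        rev = linear_fit(x, y, predictor="reference")
        assert fwd.r2 == pytest.approx(rev.r2, rel=1e-12)
        assert fwd.m != pytest.approx(rev.m)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateInputError):
            linear_fit(np.full(10, 2.0), np.arange(10.0))


class TestErrorMetrics:
    def test_identical_series(self, rng):
        s = rng.normal(size=20)
        res = error_metrics(s, s)
        assert res.mae == 0.0 and res.rmse == 0.0

    def test_constant_offset(self, rng):
        r = rng.normal(size=20)
        res = error_metrics(r + 3.0, r)
        assert res.mae == pytest.approx(3.0)
        assert res.rmse == pytest.approx(3.0)

    def test_hand_computed_values(self):
        res = error_metrics(np.array([-1.0, 0.0, 1.0, 2.0]), np.zeros(4))
        assert res.mae == pytest.approx(1.0)
        assert res.rmse == pytest.approx(np.sqrt(1.5))

    def test_mae_never_exceeds_rmse(self, rng):
        for _ in range(30):
            s, r = rng.normal(size=(2, 25))
            res = error_metrics(s, r)
            assert 0.0 <= res.mae <= res.rmse + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            error_metrics([1.0, 2.0], [1.0])


class TestPairedTTest:
    def test_matches_textbook_formula(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 30))
            t1 = rng.normal(size=n)
            t2 = t1 + rng.normal(0.2, 0.5, size=n)
            t_stat, p = paired_ttest(t1, t2)
            d = t2 - t1
            t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p_oracle = 2 * stats.t.sf(abs(t_oracle), df=n - 1)
            assert t_stat == pytest.approx(t_oracle, rel=1e-9)
            assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(ZeroVarianceTTestWarning):
            t_stat, p = paired_ttest(x, x)
        assert (t_stat, p) == (0.0, 1.0)

    def test_constant_shift_flagged_significant(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(ZeroVarianceTTestWarning):
            _, p = paired_ttest(x, x + 2.0)
        assert p == 0.0


class TestCompareTimepoints:
    @staticmethod
    def _table(rng, ids):
        from rollgait import METRICS

        return pd.DataFrame(
            rng.normal(size=(len(ids), len(METRICS))), index=ids, columns=METRICS
        )

    def test_equal_timepoints_all_null(self, rng):
        t1 = self._table(rng, ["P1", "P2", "P3"])
        with pytest.warns(ZeroVarianceTTestWarning):
            comps = compare_timepoints(t1, t1.copy())
        assert len(comps) == 9
        for c in comps:
            assert c.mean_diff == 0.0 and c.p_value == 1.0 and not c.significant

    def test_random_tables_match_scipy(self, rng):
        ids = [f"P{i}" for i in range(8)]
        t1, t2 = self._table(rng, ids), self._table(rng, ids)
        comps = {c.metric: c for c in compare_timepoints(t1, t2)}
        for metric in t1.columns:
            res = stats.ttest_rel(t2[metric], t1[metric])
            assert comps[metric].t_stat == pytest.approx(res.statistic, rel=1e-9)
            assert comps[metric].p_value == pytest.approx(res.pvalue, rel=1e-9)
            assert comps[metric].significant == (res.pvalue < 0.05)

    def test_participant_mismatch_rejected(self, rng):
        t1 = self._table(rng, ["P1", "P2"])
        t2 = self._table(rng, ["P1", "P3"])
        with pytest.raises(InvalidInputError, match="P3"):
            compare_timepoints(t1, t2)


class TestSummarizeCohort:
    @staticmethod
    def _frame(rng, participants):
        from rollgait import METRICS

        rows = []
        for p in participants:
            for joint in ("hip", "knee"):
                for tp in ("T1",):
                    rows.append(
                        {
                            "participant": p,
                            "joint": joint,
                            "timepoint": tp,
                            "variant": "raw",
                            **{m: float(rng.normal()) for m in METRICS},
                            "n": 100,
                        }
                    )
        return pd.DataFrame(rows)

    def test_single_participant_mean_is_value_sd_zero(self, rng):
        frame = self._frame(rng, ["P1"])
        out = summarize_cohort(frame)["summary"]
        row = out[out.joint == "hip"].iloc[0]
        src = frame[frame.joint == "hip"].iloc[0]
        assert row["m_dif_mean"] == pytest.approx(src["m_dif"])
        assert row["m_dif_std"] == 0.0
        assert row["n_participants"] == 1

    def test_cohort_means_match_average_oracle(self, rng):
        frame = self._frame(rng, [f"P{i}" for i in range(6)])
        out = summarize_cohort(frame)["summary"]
        row = out[out.joint == "knee"].iloc[0]
        sub = frame[frame.joint == "knee"]
        assert row["rpc_mean"] == pytest.approx(sub["rpc"].mean(), rel=1e-12)
        assert row["rpc_std"] == pytest.approx(sub["rpc"].std(ddof=1), rel=1e-12)

    def test_pooled_series_computed(self, rng):
        frame = self._frame(rng, ["P1", "P2"])
        s, r = rng.normal(size=(2, 500))
        out = summarize_cohort(frame, pooled_series={"knee|T1|raw": (s, r)})
        pooled = out["pooled"]["knee|T1|raw"]
        assert pooled["n"] == 500
        assert pooled["m_dif"] == pytest.approx((s - r).mean(), rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize_cohort(pd.DataFrame())
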