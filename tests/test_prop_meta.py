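"""Logit-proportion pooling: effects, heterogeneity statistics, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from armspill import _pooling
from armspill.arm_data import ArmRole, StudyTable
from armspill.prop_meta import ArmEffect, arm_summary_table, logit_effect, pool_arms
from conftest import make_record


class TestLogitEffect:
    def test_symmetric_half(self):
        eff = logit_effect(10, 20)
        assert eff.y == pytest.approx(0.0)
        assert eff.v == pytest.approx(0.2)

    def test_zero_events_corrected(self):
        # e' = 0.5, n' = 21 -> y = ln(0.5/20.5)
        eff = logit_effect(0, 20, correction=0.5)
        assert eff.y == pytest.approx(math.log(0.5 / 20.5), abs=1e-12)
        assert eff.v == pytest.approx(1 / 0.5 + 1 / 20.5, abs=1e-12)

    def test_interior_counts_uncorrected(self):
        eff = logit_effect(15, 20)
        assert eff.y == pytest.approx(math.log(3.0))
        assert eff.v == pytest.approx(1 / 15 + 1 / 5)

    def test_all_events_corrected_symmetrically(self):
        hi = logit_effect(20, 20)
        lo = logit_effect(0, 20)
        assert hi.y == pytest.approx(-lo.y)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            logit_effect(0, 0)


def _effects(ys, vs):
    return [ArmEffect(str(i), y, v, 0, 1) for i, (y, v) in enumerate(zip(ys, vs))]


class TestPooling:
    def test_no_dispersion(self):
        pooled = pool_arms(_effects([0.0, 0.0], [0.2, 0.2]))
        assert pooled.summary_prop == pytest.approx(0.5)
        assert pooled.Q == pytest.approx(0.0)
        assert pooled.tau2 == pytest.approx(0.0, abs=1e-8)
        assert pooled.I2 == pytest.approx(0.0, abs=1e-6)
        assert pooled.H2 == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_dl_example(self):
        """y = (0, 1, 2), v = 0.2: Q = 5(1+0+1) = 10, df = 2,
        tau2_DL = (10-2)/(15 - 75/15) = 0.8, s2 = 0.2 -> I2 = 80, H2 = 5."""
        pooled = pool_arms(_effects([0.0, 1.0, 2.0], [0.2, 0.2, 0.2]), tau2_method="DL")
        assert pooled.Q == pytest.approx(10.0, abs=1e-10)
        assert pooled.df == 2
        assert pooled.tau2 == pytest.approx(0.8, abs=1e-10)
        assert pooled.I2 == pytest.approx(80.0, abs=1e-8)
        assert pooled.H2 == pytest.approx(5.0, abs=1e-8)

    def test_pi_wider_than_ci(self):
        pooled = pool_arms(_effects([0.0, 1.0, 2.0], [0.2, 0.2, 0.2]))
        assert pooled.pi95[0] < pooled.ci95[0]
        assert pooled.pi95[1] > pooled.ci95[1]

    def test_tau2_zero_pi_is_t_vs_normal_factor(self):
        # identical effects: PI wider than CI only by t_{k-2}/z on the logit scale
        eff = _effects([0.3, 0.3, 0.3, 0.3], [0.1, 0.1, 0.1, 0.1])
        pooled = pool_arms(eff)
        from scipy import stats

        width_ci = math.log(pooled.ci95[1] / (1 - pooled.ci95[1])) - math.log(
            pooled.ci95[0] / (1 - pooled.ci95[0])
        )
        width_pi = math.log(pooled.pi95[1] / (1 - pooled.pi95[1])) - math.log(
            pooled.pi95[0] / (1 - pooled.pi95[0])
        )
        factor = stats.t.ppf(0.975, 2) / stats.norm.ppf(0.975)
        assert width_pi / width_ci == pytest.approx(factor, rel=1e-6)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            pool_arms(_effects([0.0], [0.1]))

    def test_nonfinite_effect_named(self):
        effects = _effects([0.0, math.inf], [0.1, 0.1])
        with pytest.raises(ValueError, match="1"):
            pool_arms(effects)


@st.composite
def effect_sets(draw):
    k = draw(st.integers(3, 6))
    ys = draw(
        st.lists(st.floats(-3, 3, allow_nan=False), min_size=k, max_size=k)
    )
    vs = draw(
        st.lists(st.floats(0.01, 2.0, allow_nan=False), min_size=k, max_size=k)
    )
    return np.array(ys), np.array(vs)


class TestPoolingProperties:
    @given(effect_sets())
    @settings(max_examples=100, deadline=None)
    def test_dl_matches_closed_form(self, data):
        """DL tau2 equals (Q - df) / (sum w - sum w^2 / sum w), truncated at 0."""
        y, v = data
        w = 1 / v
        mu = np.sum(w * y) / np.sum(w)
        Q = np.sum(w * (y - mu) ** 2)
        expected = max(0.0, (Q - (len(y) - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        assert _pooling.dl_tau2(y, v) == pytest.approx(expected, rel=1e-10, abs=1e-12)

    @given(effect_sets(), st.sampled_from(["REML", "DL"]))
    @settings(max_examples=100, deadline=None)
    def test_h2_i2_pairing(self, data, method):
        """H2 = 1 / (1 - I2/100) to numerical tolerance, for either estimator."""
        y, v = data
        res = _pooling.pool_effects(y, v, tau2_method=method)
        assert res.H2 == pytest.approx(1.0 / (1.0 - res.I2 / 100.0), abs=1e-9)
        assert res.tau2 >= 0
        assert 0 <= res.I2 < 100

    @given(effect_sets())
    @settings(max_examples=50, deadline=None)
    def test_back_transform_order_preserving(self, data):
        y, v = data
        eff = _effects(list(y), list(v))
        pooled = pool_arms(eff)
        assert pooled.ci95[0] < pooled.summary_prop < pooled.ci95[1]
        assert pooled.pi95[0] <= pooled.ci95[0]
        assert pooled.pi95[1] >= pooled.ci95[1]
        assert 0 < pooled.pi95[0] < pooled.pi95[1] < 1


class TestSummaryTable:
    def _table(self):
        records = []
        cats = ["non_antimicrobial", "antimicrobial", "antimicrobial_duplex"]
        for c, cat in enumerate(cats):
            for i in range(3):
                records.append(
                    make_record(f"{cat}_{i}", "control", 5 + i + c, 40, category=cat)
                )
                records.append(
                    make_record(f"{cat}_{i}", "intervention", 4 + i, 40, category=cat)
                )
        return StudyTable(records)

    def test_category_grouping_has_eight_rows(self):
        df = arm_summary_table(self._table(), grouping="category")
        assert len(df) == 8  # all + 3 categories, x 2 arm roles
        assert list(df["group"][:2]) == ["all", "all"]
        # control precedes intervention within each block
        assert list(df["arm_role"][::2]) == ["control"] * 4

    def test_single_study_group_flagged(self):
        records = [
            make_record("a", "control", 5, 40),
            make_record("a", "intervention", 4, 40),
            make_record("b", "control", 6, 40, category="antimicrobial"),
            make_record("b", "intervention", 3, 40, category="antimicrobial"),
            make_record("c", "control", 9, 40, category="antimicrobial"),
            make_record("c", "intervention", 7, 40, category="antimicrobial"),
        ]
        df = arm_summary_table(StudyTable(records), grouping="category")
        non_am = df[(df.group == "non_antimicrobial")]
        assert non_am["flagged"].all()
        am = df[(df.group == "antimicrobial")]
        assert not am["flagged"].any()
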