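"""Pooled genotype ratios, cross-condition ANOVA, and Tukey HSD."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nadphnet import (
    Dataset,
    compare_conditions,
    calibrated_default_config,
    generate_dataset,
    pooled_ratio,
    ratio_anova,
    tukey_hsd,
)
from nadphnet.conditions import RatioRecord
from nadphnet.design import ExperimentalDesign
from nadphnet.simulate import GeneratorConfig
from nadphnet._srange import srange_ppf, srange_sf


def one_way_anova_oracle(groups):
    """Hand-coded one-way ANOVA from the classical decomposition."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, stats.f.sf(F, df_b, df_w)


def _records(values_by_condition):
    recs = []
    for cond, vals in values_by_condition.items():
        for i, v in enumerate(vals):
            recs.append(RatioRecord("Men", "activity_idh", f"BG{i}", cond, v))
    return recs


class TestPooledRatio:
    def test_identical_groups(self, default_dataset):
        frame = default_dataset.frame.copy()
        men = frame["gene_series"] == "Men"
        # make both genotype groups of one cell identical on the response
        cell = men & (frame["background"] == "CT21") & (frame["condition"] == "control")
        frame.loc[cell, "activity_idh"] = 7.0
        ds = Dataset(frame=frame, design=default_dataset.design)
        rec = pooled_ratio(ds, "Men", "activity_idh", "CT21", "control")
        assert rec.ratio == pytest.approx(1.0, rel=1e-12)

    def test_mean_ratio_arithmetic(self, default_dataset):
        frame = default_dataset.frame.copy()
        cell = (
            (frame["gene_series"] == "Men")
            & (frame["background"] == "MD76")
            & (frame["condition"] == "oxidative")
        )
        idx = frame.index[cell]
        frame.loc[idx, "activity_g6pd"] = 0.0
        reduced_idx = idx[(frame.loc[idx, "genotype_class"] == "reduced")][:2]
        full_idx = idx[(frame.loc[idx, "genotype_class"] == "full")][:2]
        frame.loc[reduced_idx, "activity_g6pd"] = [2.0, 4.0]
        frame.loc[full_idx, "activity_g6pd"] = [4.0, 8.0]
        keep = ~cell | frame.index.isin(list(reduced_idx) + list(full_idx))
        ds = Dataset(frame=frame[keep], design=default_dataset.design)
        rec = pooled_ratio(ds, "Men", "activity_g6pd", "MD76", "oxidative")
        assert rec.ratio == pytest.approx(0.5, rel=1e-12)

    def test_noise_free_idh_ratio(self, quiet_config):
        ds = generate_dataset(quiet_config)
        for bg in ("CT21", "VT26"):
            rec = pooled_ratio(ds, "Idh", "activity_idh", bg, "starvation")
            assert rec.ratio == pytest.approx(0.459, rel=1e-10)

    def test_missing_genotype_flagged(self, default_dataset):
        frame = default_dataset.frame
        frame = frame[
            ~(
                (frame["gene_series"] == "G6pd")
                & (frame["background"] == "CT21")
                & (frame["condition"] == "control")
                & (frame["genotype_class"] == "full")
            )
        ]
        ds = Dataset(frame=frame, design=default_dataset.design)
        rec = pooled_ratio(ds, "G6pd", "activity_men", "CT21", "control")
        assert not rec.defined and math.isnan(rec.ratio)


class TestRatioAnova:
    def test_all_equal_ratios(self):
        recs = _records({c: [0.7] * 4 for c in ("control", "oxidative")})
        res = ratio_anova(recs)
        assert res.F == 0.0 and res.p_value == 1.0

    def test_complete_default_design_df(self, default_dataset):
        _, anova, _ = compare_conditions(default_dataset, "Men", "activity_idh")
        assert anova.df_num == 3
        assert anova.df_den == 24
        assert "residual df" in anova.note

    def test_matches_hand_coded_oracle(self):
        rng = np.random.default_rng(3)
        a = 0.5 + 0.05 * rng.standard_normal(4)
        b = 0.8 + 0.05 * rng.standard_normal(4)
        res = ratio_anova(_records({"control": a, "starvation": b}))
        F, p = one_way_anova_oracle([a, b])
        assert res.F == pytest.approx(F, rel=1e-8)
        assert res.p_value == pytest.approx(p, rel=1e-8)
        # scipy as a second, independent cross-check
        F2, p2 = stats.f_oneway(a, b)
        assert res.F == pytest.approx(F2, rel=1e-8)

    def test_thin_condition_named(self):
        recs = _records({"control": [0.5, 0.6, 0.7], "desiccation": [0.9]})
        with pytest.raises(ValueError, match="desiccation"):
            ratio_anova(recs)

    def test_invariant_to_constant_shift_and_relabeling(self):
        rng = np.random.default_rng(8)
        vals = {c: rng.normal(0.7, 0.05, 5) for c in ("control", "oxidative", "starvation")}
        base = ratio_anova(_records(vals)).F
        shifted = ratio_anova(_records({c: v + 10.0 for c, v in vals.items()})).F
        assert shifted == pytest.approx(base, rel=1e-9)
        rolled = ratio_anova(_records({c: np.roll(v, 2) for c, v in vals.items()})).F
        assert rolled == pytest.approx(base, rel=1e-12)


class TestTukeyHSD:
    def test_identical_groups_no_significance(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = tukey_hsd({c: g for c in "abcd"}, alpha=0.05)
        assert all(p == pytest.approx(1.0, abs=1e-12) for p in res.p_adj)
        assert not any(res.significant)

    def test_separated_group_flags_exactly_its_pairs(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(0, 0.1, 7),
            "b": rng.normal(0, 0.1, 7),
            "c": rng.normal(50, 0.1, 7),
        }
        res = tukey_hsd(groups, alpha=0.05)
        sig = {pair for pair, s in zip(res.pairs, res.significant) if s}
        assert sig == {("a", "c"), ("b", "c")}

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(5)
        groups = {c: rng.normal(i * 0.5, 1.0, 6) for i, c in enumerate("abcd")}
        mine = tukey_hsd(groups)
        ref = stats.tukey_hsd(*groups.values())
        idx = {c: i for i, c in enumerate(groups)}
        for (a, b), p in zip(mine.pairs, mine.p_adj):
            assert p == pytest.approx(ref.pvalue[idx[a], idx[b]], abs=1e-7)

    @settings(max_examples=25)
    @given(
        seed=st.integers(0, 9999),
        n1=st.integers(3, 8),
        n2=st.integers(3, 8),
        delta=st.floats(0.0, 2.0),
    )
    def test_two_groups_reproduce_pooled_t(self, seed, n1, n2, delta):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, n1), rng.normal(delta, 1, n2)
        res = tukey_hsd({"a": a, "b": b}, alpha=0.05)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        # q = |t| * sqrt(2): the 2-group studentized range is the pooled t
        assert res.q_stat[0] == pytest.approx(abs(t) * math.sqrt(2), rel=1e-10)
        assert res.p_adj[0] == pytest.approx(p, abs=1e-9)
        assert res.significant[0] == (p < 0.05)

    def test_zero_variance_cases(self):
        res = tukey_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.p_adj == [0.0] and res.significant == [True]
        res = tukey_hsd({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.p_adj == [1.0] and not any(res.significant)

    def test_published_critical_value(self):
        # classical table entry q(0.05; k=4, df=24) = 3.901
        assert srange_ppf(0.95, 4, 24) == pytest.approx(3.901, abs=2e-3)
        assert srange_sf(3.901, 4, 24) == pytest.approx(0.05, abs=1e-4)


class TestCompareConditions:
    def test_deterministic(self, default_dataset):
        a = compare_conditions(default_dataset, "G6pd", "activity_men")
        b = compare_conditions(default_dataset, "G6pd", "activity_men")
        assert a[1].F == b[1].F
        assert a[2].p_adj == b[2].p_adj

    def test_absent_gene_named(self, default_dataset):
        men_only = Dataset(
            frame=default_dataset.subset(gene_series="Men"),
            design=default_dataset.design,
        )
        with pytest.raises(ValueError, match="G6pd"):
            compare_conditions(men_only, "G6pd", "activity_men")

    def test_oxidative_dominant_response_detected(self):
        # strong compensation only under oxidative stress: every oxidative
        # pair significant, no other pair, in the low-noise limit
        cfg = GeneratorConfig(seed=2, sd_background=0.02, sd_bottle=0.0)
        cfg.sd_residual = {k: 0.02 for k in cfg.sd_residual}
        cfg.set_elasticity("G6pd", "activity_men", -0.3)
        cfg.set_elasticity("G6pd", "activity_men", -1.2, conditions=("oxidative",))
        ds = generate_dataset(cfg)
        _, anova, tukey = compare_conditions(ds, "G6pd", "activity_men")
        assert anova.p_value < 1e-6
        for pair, sig in zip(tukey.pairs, tukey.significant):
            assert sig == ("oxidative" in pair)
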