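"""Per-background slopes, gated elasticity estimates, and the full matrix."""

import math

import numpy as np
import pandas as pd
import pytest

from nadphnet import (
    Dataset,
    calibrated_default_config,
    elasticity_matrix,
    estimate_elasticity,
    generate_dataset,
    per_background_slope,
)
from nadphnet.design import ExperimentalDesign
from nadphnet.elasticity import UndefinedSlopeError
from nadphnet.simulate import GeneratorConfig


def _cell_frame(e1_vals, e2_vals, genotypes=None):
    n = len(e1_vals)
    genotypes = genotypes or ["full"] * (n // 2) + ["reduced"] * (n - n // 2)
    return pd.DataFrame(
        {"triglyceride": e1_vals, "carbohydrate_mg_per_L": e2_vals,
         "genotype_class": genotypes}
    )


class TestPerBackgroundSlope:
    def test_identity_slope(self):
        vals = np.exp([0.1, 0.5, 1.0, 1.4])
        frame = _cell_frame(vals, vals)
        assert per_background_slope(
            frame, "triglyceride", "carbohydrate_mg_per_L"
        ) == pytest.approx(1.0, rel=1e-12)

    def test_constant_response_slope_zero(self):
        frame = _cell_frame(np.exp([0.0, 1.0, 2.0, 3.0]), np.ones(4) * 5.0)
        assert per_background_slope(
            frame, "triglyceride", "carbohydrate_mg_per_L"
        ) == pytest.approx(0.0, abs=1e-14)

    def test_collinear_points_closed_form(self):
        # (ln e1, ln e2) on the line y = -0.5 x
        frame = _cell_frame(np.exp([0.0, 1.0, 2.0, 3.0]), np.exp([0.0, -0.5, -1.0, -1.5]))
        assert per_background_slope(
            frame, "triglyceride", "carbohydrate_mg_per_L"
        ) == pytest.approx(-0.5, rel=1e-12)

    def test_slope_invariant_to_activity_unit_conversion(self):
        # activity columns are rescaled to nmol before logging; a log-log
        # slope is unaffected by any multiplicative unit change
        rng = np.random.default_rng(0)
        e1 = np.exp(rng.normal(size=8))
        e2 = np.exp(0.7 * np.log(e1) + rng.normal(scale=0.1, size=8))
        geno = ["full"] * 4 + ["reduced"] * 4
        a = pd.DataFrame({"activity_men": e1, "activity_idh": e2, "genotype_class": geno})
        b = pd.DataFrame(
            {"triglyceride": e1, "carbohydrate_mg_per_L": e2, "genotype_class": geno}
        )
        s1 = per_background_slope(a, "activity_men", "activity_idh")
        s2 = per_background_slope(b, "triglyceride", "carbohydrate_mg_per_L")
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_secant_method_two_group_means(self):
        frame = _cell_frame(
            np.array([1.0, 1.0, math.e, math.e]),
            np.array([2.0, 4.0, 1.0, 2.0]),
            genotypes=["full", "full", "reduced", "reduced"],
        )
        # secant = (mean ln e2 | reduced - mean ln e2 | full) / (1 - 0)
        expected = (math.log(1) + math.log(2)) / 2 - (math.log(2) + math.log(4)) / 2
        slope = per_background_slope(
            frame, "triglyceride", "carbohydrate_mg_per_L", method="secant"
        )
        assert slope == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_rows_excluded_then_error(self):
        frame = _cell_frame(
            np.array([1.0, 2.0, 0.0, 3.0]), np.array([1.0, 2.0, 3.0, 0.0])
        )
        with pytest.raises(UndefinedSlopeError):
            per_background_slope(frame, "triglyceride", "carbohydrate_mg_per_L")

    def test_zero_variance_e1(self):
        frame = _cell_frame(np.ones(6), np.exp(np.arange(6.0)))
        with pytest.raises(UndefinedSlopeError):
            per_background_slope(frame, "triglyceride", "carbohydrate_mg_per_L")


@pytest.fixture(scope="module")
def recovery_dataset():
    cfg = GeneratorConfig(seed=7)
    cfg.sd_residual = {k: 0.05 for k in cfg.sd_residual}
    cfg.set_elasticity("G6pd", "activity_men", -0.8, conditions=("oxidative",))
    design = ExperimentalDesign(samples_per_bottle_per_condition=8)
    return generate_dataset(cfg, design)


class TestEstimateElasticity:
    def test_parameter_recovery(self, recovery_dataset):
        est = estimate_elasticity(recovery_dataset, "G6pd", "activity_men", "oxidative")
        assert est.gated
        assert abs(est.epsilon - (-0.8)) < 3 * est.se
        assert est.n_backgrounds == 7
        assert est.epsilon == pytest.approx(np.mean(list(est.slopes.values())))
        assert est.se == pytest.approx(
            np.std(list(est.slopes.values()), ddof=1) / math.sqrt(7)
        )

    def test_null_cell_usually_ungated_and_displayed_as_ns(self, recovery_dataset):
        est = estimate_elasticity(recovery_dataset, "G6pd", "triglyceride", "control")
        if not est.gated:
            assert math.isnan(est.display_epsilon)
        gated_est = estimate_elasticity(
            recovery_dataset, "G6pd", "activity_men", "oxidative"
        )
        assert gated_est.display_epsilon == gated_est.epsilon

    def test_background_relabeling_leaves_epsilon_unchanged(self, recovery_dataset):
        frame = recovery_dataset.frame.copy()
        perm = {"CT21": "VT26", "VT26": "CT21"}
        frame["background"] = frame["background"].map(lambda b: perm.get(b, b))
        frame["sample_id"] = frame["sample_id"] + "-r"
        permuted = Dataset(frame=frame, design=recovery_dataset.design)
        a = estimate_elasticity(recovery_dataset, "G6pd", "activity_men", "oxidative")
        b = estimate_elasticity(permuted, "G6pd", "activity_men", "oxidative")
        assert b.epsilon == pytest.approx(a.epsilon, rel=1e-12)
        assert b.se == pytest.approx(a.se, rel=1e-12)
        assert b.slopes["CT21"] == pytest.approx(a.slopes["VT26"], rel=1e-12)

    def test_missing_genotype_class_rejected(self, recovery_dataset):
        frame = recovery_dataset.frame
        frame = frame[
            ~((frame["gene_series"] == "Idh") & (frame["genotype_class"] == "reduced"))
        ]
        ds = Dataset(frame=frame, design=recovery_dataset.design)
        with pytest.raises(ValueError, match="reduced"):
            estimate_elasticity(ds, "Idh", "activity_men", "control")


class TestElasticityMatrix:
    def test_full_matrix_counts(self, default_dataset):
        estimates = elasticity_matrix(default_dataset)
        assert len(estimates) == 48
        assert all(e.available for e in estimates)
        # each perturbed gene excludes its own enzyme from the responses
        for e in estimates:
            assert not e.response.endswith(e.perturbed.lower())

    def test_restricted_dataset_marks_unavailable(self, default_dataset):
        control_only = Dataset(
            frame=default_dataset.subset(condition="control"),
            design=default_dataset.design,
        )
        estimates = elasticity_matrix(control_only)
        available = [e for e in estimates if e.available]
        assert len(available) == 12
        assert len(estimates) - len(available) == 36

    def test_compensatory_g6pd_men_signs(self, default_dataset):
        for e in elasticity_matrix(default_dataset):
            if e.perturbed == "G6pd" and e.response == "activity_men" and e.gated:
                assert e.epsilon < 0
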