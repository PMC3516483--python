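"""Simulation studies that validate the estimator pipeline on known truth.

Every study generates data from :mod:`nadphnet.simulate` with a known
configuration, runs the corresponding analysis stage, and summarises how
well the ground truth is recovered.  These are the package's own method
checks — recovery bias and interval coverage for the elasticity estimator,
type-I-error calibration of the ANCOVA gate and of Tukey's HSD, pooled-
ratio fidelity, and sign recovery of the full interaction matrix.
"""

from __future__ import annotations

import math

import numpy as np

from .conditions import tukey_hsd
from .design import ACTIVITY_COLUMNS, CONDITIONS, GENES, ExperimentalDesign
from .elasticity import elasticity_matrix, fit_ancova, matrix_responses
from .simulate import (
    GeneratorConfig,
    MEASURED_REDUCTION_RATIOS,
    calibrated_default_config,
    generate_dataset,
)

_Z95 = 1.96


def _rep_seed(base_seed: int, i: int) -> int:
    return (1_000_003 * (base_seed + 1) + i) % (2**31)


def recovery_config(seed: int = 0) -> tuple[GeneratorConfig, dict]:
    """A generator configuration with known elasticities in every matrix cell.

    The four truth values (-0.8, -0.3, 0, +0.3) are assigned cyclically
    across the 48 (gene, response, condition) cells; residual SD is 0.1 on
    the log scale for every variable.
    """
    cfg = GeneratorConfig(seed=seed)
    cfg.sd_residual = {v: 0.1 for v in cfg.sd_residual}
    values = (-0.8, -0.3, 0.0, 0.3)
    truth: dict[tuple[str, str, str], float] = {}
    i = 0
    for gene in GENES:
        for response in matrix_responses(gene):
            for cond in CONDITIONS:
                eps = values[i % len(values)]
                i += 1
                cfg.true_elasticity[f"{gene}:{response}:{cond}"] = eps
                truth[(gene, response, cond)] = eps
    return cfg, truth


def elasticity_recovery_study(n_reps: int = 200, base_seed: int = 0) -> dict:
    """Bias and 95%-interval coverage of the elasticity estimator.

    Generates ``n_reps`` full default-design datasets from
    :func:`recovery_config`, estimates the complete matrix each time, and
    reports the worst per-cell absolute bias of the mean estimate and the
    pooled empirical coverage of epsilon +/- 1.96 se.
    """
    base_cfg, truth = recovery_config()
    est_sum: dict[tuple, float] = {k: 0.0 for k in truth}
    cover: int = 0
    n_intervals = 0
    for i in range(n_reps):
        cfg = base_cfg.with_seed(_rep_seed(base_seed, i))
        estimates = elasticity_matrix(generate_dataset(cfg))
        for e in estimates:
            key = (e.perturbed, e.response, e.condition)
            est_sum[key] += e.epsilon
            n_intervals += 1
            if abs(e.epsilon - truth[key]) <= _Z95 * e.se:
                cover += 1
    biases = {k: abs(est_sum[k] / n_reps - truth[k]) for k in truth}
    return {
        "n_reps": n_reps,
        "max_abs_bias": max(biases.values()),
        "mean_abs_bias": float(np.mean(list(biases.values()))),
        "coverage": cover / n_intervals,
        "n_intervals": n_intervals,
    }


def null_gate_config(seed: int = 0) -> GeneratorConfig:
    """The all-null configuration for gate calibration: every elasticity is
    zero and the background/bottle variance components are off, so the
    response columns are iid and the gate's nominal level is testable.

    (With background heterogeneity on, the pooled gate is deliberately
    conservative: the balanced genotype contrast cancels background effects
    in the numerator while the error mean square retains them.)
    """
    return GeneratorConfig(seed=seed, sd_background=0.0, sd_bottle=0.0)


def gate_calibration_study(
    n_cells: int = 10_000, base_seed: int = 0, alpha: float = 0.05
) -> dict:
    """Empirical false-positive rate of the ANCOVA genotype gate.

    Each generated dataset contributes 48 null cells (gene x response x
    condition); datasets are generated until ``n_cells`` gates have run.
    """
    fired = 0
    total = 0
    i = 0
    while total < n_cells:
        cfg = null_gate_config(seed=_rep_seed(base_seed, i))
        i += 1
        dataset = generate_dataset(cfg)
        for gene in GENES:
            for cond in CONDITIONS:
                sub = dataset.subset(gene_series=gene, condition=cond)
                for response in matrix_responses(gene):
                    if total >= n_cells:
                        break
                    res = fit_ancova(
                        sub, response, "genotype_class",
                        ["protein_mg_per_L", "weight_mg"],
                    )
                    fired += res.p_value < alpha
                    total += 1
    return {"rate": fired / total, "n_cells": total, "alpha": alpha}


def tukey_fwer_study(
    n_sims: int = 10_000,
    base_seed: int = 0,
    k: int = 4,
    n_per_group: int = 7,
    alpha: float = 0.05,
) -> dict:
    """Familywise error rate of Tukey HSD under the complete null.

    Mirrors the cross-condition comparison's shape: ``k`` condition groups
    of ``n_per_group`` background ratios, all drawn from one normal
    distribution.
    """
    rng = np.random.default_rng(_rep_seed(base_seed, 0))
    any_sig = 0
    names = [f"g{j}" for j in range(k)]
    for _ in range(n_sims):
        draws = rng.standard_normal((k, n_per_group))
        res = tukey_hsd(dict(zip(names, draws)), alpha=alpha)
        any_sig += any(res.significant)
    return {"fwer": any_sig / n_sims, "n_sims": n_sims, "alpha": alpha}


def ratio_fidelity_study(n_reps: int = 100, base_seed: int = 0) -> dict:
    """Mean absolute deviation of the pooled reduced/full activity ratio
    from the configured reduction ratio, per gene, over seeded replicates."""
    devs: dict[str, list[float]] = {g: [] for g in MEASURED_REDUCTION_RATIOS}
    ratios: dict[str, list[float]] = {g: [] for g in MEASURED_REDUCTION_RATIOS}
    for i in range(n_reps):
        cfg = calibrated_default_config(seed=_rep_seed(base_seed, i))
        frame = generate_dataset(cfg).frame
        for gene, r in MEASURED_REDUCTION_RATIOS.items():
            col = ACTIVITY_COLUMNS[gene]
            series = frame[frame["gene_series"] == gene]
            ratio = (
                series.loc[series["genotype_class"] == "reduced", col].mean()
                / series.loc[series["genotype_class"] == "full", col].mean()
            )
            ratios[gene].append(float(ratio))
            devs[gene].append(abs(ratio - r))
    n_per_genotype = ExperimentalDesign().n_samples // (2 * len(GENES))
    return {
        "n_reps": n_reps,
        "mean_ratio": {g: float(np.mean(v)) for g, v in ratios.items()},
        "mad": {g: float(np.mean(v)) for g, v in devs.items()},
        "mc_bound": 3 * 0.08 / math.sqrt(n_per_genotype),
    }


def sign_recovery_config(seed: int = 0) -> tuple[GeneratorConfig, ExperimentalDesign]:
    """Default sign-pattern configuration in its low-noise, large-n regime:
    residual SDs halved and eight samples per bottle per condition."""
    cfg = calibrated_default_config(seed=seed)
    cfg.sd_residual = {k: v / 2 for k, v in cfg.sd_residual.items()}
    return cfg, ExperimentalDesign(samples_per_bottle_per_condition=8)


def sign_recovery_study(n_reps: int = 50, base_seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of replicates whose gated matrix cells all carry the true sign.

    Only cells with a nonzero true elasticity bear a sign; gated zero-truth
    cells are gate type-I events and are not counted against the replicate.
    """
    ok = 0
    for i in range(n_reps):
        cfg, design = sign_recovery_config(seed=_rep_seed(base_seed, i))
        estimates = elasticity_matrix(generate_dataset(cfg, design), alpha=alpha)
        good = True
        for e in estimates:
            true_eps = cfg.elasticity(e.perturbed, e.response, e.condition)
            if e.gated and true_eps != 0.0 and math.copysign(1, e.epsilon) != math.copysign(1, true_eps):
                good = False
                break
        ok += good
    return {"fraction": ok / n_reps, "n_reps": n_reps}
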