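"""Covariate-adjusted genotype tests and gated elasticity coefficients.

The central statistic is the elasticity coefficient: for a gene series with
engineered full- and reduced-activity genotypes, the OLS slope of ln E2
versus ln E1 is computed within each third-chromosome background (E1 = the
perturbed enzyme's activity, E2 = a responding enzyme or metabolite), and
the elasticity is the mean of the per-background slopes with a standard
error across backgrounds.  An ANCOVA on the response (genotype class as the
factor, soluble protein and body weight as covariates) gates whether the
coefficient is reported, mirroring the "NS" cells of an interaction matrix.

No correction for multiple testing is applied across matrix cells; each
cell's gate is a single nominal-alpha test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .design import (
    ACTIVITY_COLUMNS,
    MEASURED_VARIABLES,
    TABLE_TO_NMOL,
    Dataset,
)

__all__ = [
    "LinearTestResult",
    "ElasticityEstimate",
    "fit_ancova",
    "per_background_slope",
    "estimate_elasticity",
    "elasticity_matrix",
    "DegenerateModelError",
    "UndefinedSlopeError",
]

DEFAULT_COVARIATES: tuple[str, ...] = ("protein_mg_per_L", "weight_mg")
_TINY_REL = 1e-12


class DegenerateModelError(ValueError):
    """The linear model's design matrix is rank-deficient in the tested factor."""


class UndefinedSlopeError(ValueError):
    """A per-background slope cannot be computed (no variance in ln E1)."""


@dataclass
class LinearTestResult:
    """F test of one factor from a least-squares linear model."""

    factor: str
    F: float
    df_num: int
    df_den: int
    p_value: float
    adjusted_means: dict[str, float] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    n: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


def fit_ancova(
    frame: pd.DataFrame,
    response: str,
    factor: str,
    covariates: list[str] | tuple[str, ...] = (),
) -> LinearTestResult:
    """Marginal F test of ``factor`` after adjusting for ``covariates``.

    Fits ``response ~ covariates + factor`` by least squares and tests the
    factor on the variation remaining after the covariates (full-versus-
    reduced model F).  Adjusted level means are model predictions at the
    covariate grand means.  Zero-variance covariates carry no information
    and are dropped; a covariate collinear with the factor makes the test
    undefined and raises :class:`DegenerateModelError`.
    """
    y = frame[response].to_numpy(dtype=float)
    n = y.size
    levels = list(pd.unique(frame[factor]))
    if len(levels) < 2:
        raise DegenerateModelError(
            f"factor {factor!r} has {len(levels)} level(s); need at least 2"
        )
    cov_used: list[str] = []
    cov_cols: list[np.ndarray] = []
    for cov in covariates:
        col = frame[cov].to_numpy(dtype=float)
        if not np.isfinite(col).all():
            raise ValueError(f"covariate {cov!r} contains non-finite values")
        if np.ptp(col) > 0:
            cov_used.append(cov)
            cov_cols.append(col)
    x_reduced = np.column_stack([np.ones(n)] + cov_cols)
    dummies = [
        (frame[factor] == lev).to_numpy(dtype=float) for lev in levels[1:]
    ]
    x_full = np.column_stack([x_reduced] + dummies)

    rank_reduced = np.linalg.matrix_rank(x_reduced)
    rank_full = np.linalg.matrix_rank(x_full)
    df_num = rank_full - rank_reduced
    if df_num < len(levels) - 1:
        raise DegenerateModelError(
            f"factor {factor!r} is collinear with the covariates {cov_used}"
        )
    df_den = n - rank_full
    if df_den < 1:
        raise DegenerateModelError("no residual degrees of freedom")

    beta_full, sse_full = _lstsq_sse(x_full, y)
    _, sse_reduced = _lstsq_sse(x_reduced, y)

    sst = float(np.sum((y - y.mean()) ** 2))
    tol = _TINY_REL * max(1.0, sst)
    num = max(sse_reduced - sse_full, 0.0)
    if sse_full <= tol:
        if num <= tol:
            F, p = 0.0, 1.0
        else:
            F, p = math.inf, 0.0
    else:
        F = (num / df_num) / (sse_full / df_den)
        p = float(f_dist.sf(F, df_num, df_den))

    cov_means = [col.mean() for col in cov_cols]
    adjusted = {}
    for i, lev in enumerate(levels):
        row = np.zeros(x_full.shape[1])
        row[0] = 1.0
        row[1 : 1 + len(cov_means)] = cov_means
        if i > 0:
            row[len(cov_means) + i] = 1.0
        adjusted[lev] = float(row @ beta_full)

    return LinearTestResult(
        factor=factor,
        F=float(F),
        df_num=int(df_num),
        df_den=int(df_den),
        p_value=p,
        adjusted_means=adjusted,
        covariates=cov_used,
        n=n,
    )


def _lstsq_sse(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def _log_values(frame: pd.DataFrame, variable: str) -> np.ndarray:
    """Natural log of a variable, activities first converted to nmol/min/ug."""
    vals = frame[variable].to_numpy(dtype=float)
    if variable in ACTIVITY_COLUMNS.values():
        vals = vals * TABLE_TO_NMOL
    return np.log(vals)


def per_background_slope(
    frame: pd.DataFrame,
    e1: str,
    e2: str,
    method: str = "pooled",
) -> float:
    """OLS slope of ln E2 on ln E1 over one (gene, background, condition) cell.

    ``frame`` holds both genotype groups of the cell; rows with a
    non-positive value of either variable are excluded before logging.
    ``method='pooled'`` regresses the sample-level points of both genotypes
    together; ``method='secant'`` uses the line through the two genotype
    mean points instead.
    """
    if method not in ("pooled", "secant"):
        raise ValueError(f"unknown slope method {method!r}")
    positive = (frame[e1] > 0) & (frame[e2] > 0)
    usable = frame.loc[positive]
    counts = usable.groupby("genotype_class").size()
    if len(counts) < 2 or (counts < 2).any():
        raise UndefinedSlopeError(
            "each genotype group needs >= 2 usable samples with positive "
            f"{e1} and {e2}; got {counts.to_dict()}"
        )
    x = _log_values(usable, e1)
    y = _log_values(usable, e2)
    if method == "secant":
        geno = usable["genotype_class"].to_numpy()
        mx = {g: x[geno == g].mean() for g in ("full", "reduced")}
        my = {g: y[geno == g].mean() for g in ("full", "reduced")}
        dx = mx["reduced"] - mx["full"]
        if dx == 0:
            raise UndefinedSlopeError("genotype means of ln E1 coincide")
        return float((my["reduced"] - my["full"]) / dx)
    ssx = float(np.sum((x - x.mean()) ** 2))
    if ssx <= 0:
        raise UndefinedSlopeError(f"ln {e1} has zero variance in this cell")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / ssx)


@dataclass
class ElasticityEstimate:
    """One cell of the interaction matrix: epsilon = mean per-background slope."""

    perturbed: str
    response: str
    condition: str
    slopes: dict[str, float]
    epsilon: float
    se: float
    n_backgrounds: int
    gated: bool
    gate_p: float
    gate_F: float = math.nan
    available: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def display_epsilon(self) -> float:
        """Epsilon as reported: NaN (an "NS" cell) unless the gate fired."""
        return self.epsilon if self.gated else math.nan


def estimate_elasticity(
    dataset: Dataset,
    perturbed: str,
    response: str,
    condition: str,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    slope_method: str = "pooled",
) -> ElasticityEstimate:
    """Gated elasticity of ``response`` to the perturbed gene under one condition.

    The gate is the covariate-adjusted genotype test on the response over
    the condition subset (backgrounds pooled).  Per-background slopes and
    their mean +- SE are computed regardless of the gate so ungated values
    remain inspectable; ``display_epsilon`` enforces the gate.
    """
    e1 = ACTIVITY_COLUMNS[perturbed]
    sub = dataset.subset(gene_series=perturbed, condition=condition)
    present = set(sub["genotype_class"])
    if not {"full", "reduced"} <= present:
        raise ValueError(
            f"series {perturbed!r} under {condition!r} lacks genotype classes "
            f"{sorted({'full', 'reduced'} - present)}"
        )
    gate = fit_ancova(sub, response=response, factor="genotype_class",
                      covariates=covariates)

    slopes: dict[str, float] = {}
    warnings: list[str] = []
    for bg in dataset.design.backgrounds:
        cell = sub.loc[sub["background"] == bg]
        try:
            slopes[bg] = per_background_slope(cell, e1, response, method=slope_method)
        except UndefinedSlopeError as exc:
            warnings.append(f"background {bg}: {exc}")
    n_bg = len(slopes)
    if n_bg == 0:
        epsilon, se = math.nan, math.nan
        warnings.append("no usable backgrounds")
    else:
        vals = np.array(list(slopes.values()))
        epsilon = float(vals.mean())
        if n_bg >= 2:
            se = float(vals.std(ddof=1) / math.sqrt(n_bg))
        else:
            se = math.nan
            warnings.append("single usable background: se undefined")

    return ElasticityEstimate(
        perturbed=perturbed,
        response=response,
        condition=condition,
        slopes=slopes,
        epsilon=epsilon,
        se=se,
        n_backgrounds=n_bg,
        gated=bool(gate.p_value < alpha),
        gate_p=gate.p_value,
        gate_F=gate.F,
        warnings=warnings,
    )


def matrix_responses(perturbed: str) -> list[str]:
    """The four responses of a perturbed gene: the two other enzymes plus
    triglyceride and carbohydrate."""
    own = ACTIVITY_COLUMNS[perturbed]
    return [v for v in MEASURED_VARIABLES if v != own]


def elasticity_matrix(
    dataset: Dataset,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    slope_method: str = "pooled",
) -> list[ElasticityEstimate]:
    """All (perturbed gene) x (4 responses) x (conditions) elasticity cells.

    Cells whose series/condition subset is missing or degenerate are
    returned as unavailable rather than aborting the matrix.
    """
    estimates: list[ElasticityEstimate] = []
    for gene in dataset.design.genes:
        for response in matrix_responses(gene):
            for condition in dataset.design.conditions:
                try:
                    est = estimate_elasticity(
                        dataset, gene, response, condition,
                        alpha=alpha, covariates=covariates,
                        slope_method=slope_method,
                    )
                except (ValueError, DegenerateModelError) as exc:
                    est = ElasticityEstimate(
                        perturbed=gene, response=response, condition=condition,
                        slopes={}, epsilon=math.nan, se=math.nan,
                        n_backgrounds=0, gated=False, gate_p=math.nan,
                        available=False, warnings=[str(exc)],
                    )
                estimates.append(est)
    return estimates
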