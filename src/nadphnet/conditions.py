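"""Do stressors differ in their impact on the network?

For one (perturbed gene, response) pair, the reduced/full genotype ratio is
pooled within each (background, condition) cell — averaging all samples of
a genotype before taking the ratio, which deliberately collapses
within-genotype replication and makes the comparison conservative.  The
per-background ratios are then compared across conditions with a one-way
ANOVA and all-pairwise Tukey HSD (Tukey-Kramer for unequal group sizes).

With the complete 4-condition x 7-background layout the ANOVA has 3 and 24
degrees of freedom; published analyses of this design sometimes print a
denominator df of 27, which corresponds to total rather than residual df —
the model's own residual df is reported here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._srange import srange_sf
from .design import Dataset, MEASURED_VARIABLES
from .elasticity import LinearTestResult, fit_ancova

__all__ = [
    "RatioRecord",
    "TukeyResult",
    "pooled_ratio",
    "ratio_anova",
    "tukey_hsd",
    "compare_conditions",
]


@dataclass
class RatioRecord:
    """Pooled reduced/full response ratio for one (background, condition) cell."""

    gene: str
    response: str
    background: str
    condition: str
    ratio: float
    n_reduced: int = 0
    n_full: int = 0
    defined: bool = True


def pooled_ratio(
    dataset: Dataset,
    gene: str,
    response: str,
    background: str,
    condition: str,
) -> RatioRecord:
    """Ratio of genotype-pooled arithmetic means (bottles and samples pooled).

    Computed on the measurement scale, not the log scale.  A zero or absent
    full-genotype mean leaves the ratio undefined (flagged, NaN).
    """
    if response not in MEASURED_VARIABLES:
        raise ValueError(f"unknown response {response!r}")
    cell = dataset.subset(gene_series=gene, background=background, condition=condition)
    reduced = cell.loc[cell["genotype_class"] == "reduced", response]
    full = cell.loc[cell["genotype_class"] == "full", response]
    if len(reduced) == 0 or len(full) == 0:
        return RatioRecord(gene, response, background, condition, math.nan,
                           len(reduced), len(full), defined=False)
    mean_full = float(full.mean())
    if mean_full == 0:
        return RatioRecord(gene, response, background, condition, math.nan,
                           len(reduced), len(full), defined=False)
    return RatioRecord(
        gene, response, background, condition,
        float(reduced.mean()) / mean_full, len(reduced), len(full),
    )


def ratio_anova(ratios: list[RatioRecord]) -> LinearTestResult:
    """One-way ANOVA of the pooled ratios on condition.

    Backgrounds are the replicates within each condition; every condition
    must contribute at least two defined ratios.
    """
    usable = [r for r in ratios if r.defined and math.isfinite(r.ratio)]
    frame = pd.DataFrame(
        {"ratio": [r.ratio for r in usable], "condition": [r.condition for r in usable]}
    )
    if frame.empty or frame["condition"].nunique() < 2:
        raise ValueError("ratio_anova needs defined ratios from >= 2 conditions")
    counts = frame.groupby("condition").size()
    thin = sorted(counts.index[counts < 2])
    if thin:
        raise ValueError(f"condition(s) with fewer than 2 ratios: {thin}")
    result = fit_ancova(frame, response="ratio", factor="condition", covariates=())
    result.note = (
        "one-way layout: df_den is the model's residual df "
        "(conditions x backgrounds design)"
    )
    return result


@dataclass
class TukeyResult:
    """All-pairwise Tukey HSD (Tukey-Kramer) comparisons."""

    pairs: list[tuple[str, str]]
    q_stat: list[float]
    p_adj: list[float]
    significant: list[bool]
    alpha: float
    means: dict[str, float] = field(default_factory=dict)
    df: int = 0
    k: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_i": [p[0] for p in self.pairs],
                "level_j": [p[1] for p in self.pairs],
                "q_stat": self.q_stat,
                "p_adj": self.p_adj,
                "significant": self.significant,
            }
        )


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """Tukey's honestly-significant-difference test over named groups.

    Pairwise studentized-range statistics use the pooled within-group
    variance; unequal group sizes use the Tukey-Kramer scaling
    sqrt(s2/2 * (1/n_i + 1/n_j)).  Adjusted p-values come from the upper
    tail of the studentized-range distribution with k groups and the pooled
    error df, evaluated by numerical integration.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("tukey_hsd needs at least 2 groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    sizes = {g: arr.size for g, arr in arrays.items()}
    if any(n < 2 for n in sizes.values()):
        raise ValueError("every group needs at least 2 values")
    k = len(names)
    df = sum(sizes.values()) - k
    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    sse = sum(float(np.sum((arr - means[g]) ** 2)) for g, arr in arrays.items())
    s2 = sse / df

    pairs = list(combinations(names, 2))
    diffs = np.array([abs(means[a] - means[b]) for a, b in pairs])
    if s2 <= 0:
        q = np.where(diffs > 0, math.inf, 0.0)
        p = np.where(diffs > 0, 0.0, 1.0)
    else:
        scale = np.array(
            [math.sqrt(0.5 * s2 * (1.0 / sizes[a] + 1.0 / sizes[b])) for a, b in pairs]
        )
        q = diffs / scale
        p = srange_sf(q, k, df)
    return TukeyResult(
        pairs=pairs,
        q_stat=[float(v) for v in q],
        p_adj=[float(v) for v in np.atleast_1d(p)],
        significant=[bool(v < alpha) for v in np.atleast_1d(p)],
        alpha=alpha,
        means=means,
        df=df,
        k=k,
    )


def compare_conditions(
    dataset: Dataset,
    gene: str,
    response: str,
    alpha: float = 0.05,
) -> tuple[list[RatioRecord], LinearTestResult, TukeyResult]:
    """Pooled ratios -> cross-condition ANOVA -> Tukey HSD, for one response.

    Deterministic given the dataset: no internal randomness.
    """
    if gene not in set(dataset.frame["gene_series"]):
        raise ValueError(f"gene series {gene!r} absent from dataset")
    records = [
        pooled_ratio(dataset, gene, response, bg, cond)
        for cond in dataset.design.conditions
        for bg in dataset.design.backgrounds
    ]
    anova = ratio_anova(records)
    groups = {
        cond: np.array(
            [r.ratio for r in records if r.condition == cond and r.defined]
        )
        for cond in dataset.design.conditions
    }
    groups = {c: v for c, v in groups.items() if v.size >= 2}
    tukey = tukey_hsd(groups, alpha=alpha)
    return records, anova, tukey
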