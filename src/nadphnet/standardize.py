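"""Raw assay measurements to analysis-ready quantities.

Covers technical-duplicate averaging, per-ug-protein specific activity in
the assay-report convention, and Fig.-1-style percent change of each
measured variable under stress relative to benign control conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    ACTIVITY_COLUMNS,
    MEASURED_VARIABLES,
    TABLE_TO_NMOL,
    Dataset,
)

__all__ = [
    "average_duplicates",
    "standardize_activity",
    "percent_change_vs_control",
    "raw_rates",
    "PercentChange",
]

#: Homogenate aliquot used per activity assay (10 uL = 1e-5 L); converts
#: soluble protein mg/L to ug protein in the assayed well.
ASSAY_ALIQUOT_L: float = 1e-5
UG_PER_MG: float = 1e3


def protein_ug_in_assay(protein_mg_per_L: float | np.ndarray) -> float | np.ndarray:
    """Micrograms of soluble protein in the standard 10-uL assay aliquot."""
    return np.asarray(protein_mg_per_L, dtype=float) * ASSAY_ALIQUOT_L * UG_PER_MG


def average_duplicates(measurements) -> float:
    """Mean of the available technical replicates of one sample.

    Samples are normally assayed twice and the mean carried forward; a lone
    replicate passes through unchanged, and zero replicates propagate a
    missing-value marker (NaN) so the sample can be excluded downstream.
    """
    values = [v for v in measurements if v is not None]
    if not values:
        return math.nan
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("technical replicates must be finite")
    if arr.size > 2:
        raise ValueError(f"at most 2 technical replicates per sample, got {arr.size}")
    return float(arr.mean())


def standardize_activity(raw_rate_nmol_per_min, protein_ug):
    """Specific activity in the report convention from a raw assay rate.

    Parameters
    ----------
    raw_rate_nmol_per_min
        Total NADP-reduction rate of the assayed aliquot, nmol/min.
    protein_ug
        Soluble protein in the same aliquot, ug; must be positive.

    Returns
    -------
    Specific activity in umol NADP reduced / min / ug protein x 10,000
    (equal to 10 x the nmol/min/ug rate).  Scale-invariant: multiplying
    rate and protein by the same constant leaves the result unchanged.
    """
    raw_rate = np.asarray(raw_rate_nmol_per_min, dtype=float)
    protein = np.asarray(protein_ug, dtype=float)
    if np.any(protein <= 0):
        raise ValueError("protein_ug must be strictly positive")
    if np.any(raw_rate < 0):
        raise ValueError("raw_rate must be non-negative")
    out = (raw_rate / protein) / TABLE_TO_NMOL
    return float(out) if out.ndim == 0 else out


def raw_rates(dataset: Dataset) -> pd.DataFrame:
    """Reconstruct per-aliquot raw assay rates from a standardized table.

    Inverse of :func:`standardize_activity` for each enzyme column; lets the
    standardization stage be exercised end-to-end against generated data.
    Columns: sample_id, protein_ug, raw_rate_{g6pd,idh,men} (nmol/min).
    """
    frame = dataset.frame
    protein_ug = protein_ug_in_assay(frame["protein_mg_per_L"].to_numpy())
    out = pd.DataFrame({"sample_id": frame["sample_id"], "protein_ug": protein_ug})
    for gene, col in ACTIVITY_COLUMNS.items():
        nmol_per_ug = frame[col].to_numpy() * TABLE_TO_NMOL
        out[f"raw_rate_{col.removeprefix('activity_')}"] = nmol_per_ug * protein_ug
    return out


@dataclass
class PercentChange:
    """Per-condition percent change of one variable versus control."""

    variable: str
    percent_change: dict[str, float]  # condition -> 100 * (mean_c - mean_ctl) / mean_ctl
    means: dict[str, float]
    n: dict[str, int]
    adjusted: bool  # True when means are ANCOVA least-squares means

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "condition": list(self.percent_change),
                "mean": [self.means[c] for c in self.percent_change],
                "n": [self.n[c] for c in self.percent_change],
                "percent_change": list(self.percent_change.values()),
                "adjusted": self.adjusted,
            }
        )


def percent_change_vs_control(
    dataset: Dataset,
    variable: str,
    adjusted: bool = False,
    by_background: bool = False,
) -> PercentChange | dict[str, PercentChange]:
    """Percent change of ``variable`` under each stressor relative to control.

    Computed over full-activity (wild-type) genotypes only, pooled across
    gene series and backgrounds, matching how the stress response of the
    unperturbed network is summarised.  With ``adjusted=True`` the condition
    means are covariate-adjusted (ANCOVA least-squares means at the grand
    covariate means) instead of raw means.
    """
    if variable not in MEASURED_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    frame = dataset.subset(genotype_class="full")
    if by_background:
        return {
            bg: _percent_change_one(
                frame.loc[frame["background"] == bg], variable, dataset, adjusted
            )
            for bg in dataset.design.backgrounds
        }
    return _percent_change_one(frame, variable, dataset, adjusted)


def _percent_change_one(
    frame: pd.DataFrame, variable: str, dataset: Dataset, adjusted: bool
) -> PercentChange:
    conditions = dataset.design.conditions
    if "control" not in conditions:
        raise ValueError("dataset design has no control condition")
    if adjusted:
        from .elasticity import fit_ancova

        result = fit_ancova(
            frame, response=variable, factor="condition",
            covariates=["protein_mg_per_L", "weight_mg"],
        )
        means = {c: result.adjusted_means[c] for c in conditions}
    else:
        grouped = frame.groupby("condition")[variable].mean()
        means = {c: float(grouped.get(c, math.nan)) for c in conditions}
    counts = frame.groupby("condition")[variable].size()
    n = {c: int(counts.get(c, 0)) for c in conditions}
    ctl = means["control"]
    pct: dict[str, float] = {}
    for c in conditions:
        if ctl == 0 or math.isnan(ctl):
            pct[c] = math.nan
        else:
            pct[c] = 100.0 * (means[c] - ctl) / ctl
    return PercentChange(variable=variable, percent_change=pct, means=means, n=n,
                         adjusted=adjusted)
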