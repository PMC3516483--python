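"""Rendered outputs and end-to-end pipeline orchestration.

The headline output is the interaction matrix: rows are (perturbed gene ->
response) pairs, columns the four environmental conditions, each cell the
gated elasticity coefficient.  Negative (compensatory) interactions are
drawn in yellow and positive ones in blue, with saturation proportional to
magnitude; cells whose genotype gate did not fire are labelled NS.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap, Normalize

from . import __version__
from .conditions import compare_conditions
from .design import (
    CONDITIONS,
    MEASURED_VARIABLES,
    Dataset,
    validate_design,
    write_samples,
)
from .elasticity import ElasticityEstimate, elasticity_matrix, matrix_responses
from .simulate import GeneratorConfig, calibrated_default_config, generate_dataset
from .standardize import percent_change_vs_control

logger = logging.getLogger("nadphnet")

#: Yellow (negative, compensatory) through white to blue (positive).
INTERACTION_CMAP = LinearSegmentedColormap.from_list(
    "interaction", ["#b8860b", "#ffff66", "#ffffff", "#6699ff", "#003399"]
)

_SHORT = {
    "activity_g6pd": "G6PD",
    "activity_idh": "IDH",
    "activity_men": "MEN",
    "triglyceride": "TRIG",
    "carbohydrate_mg_per_L": "CARB",
}


def matrix_to_frame(estimates: list[ElasticityEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "perturbed": [e.perturbed for e in estimates],
            "response": [e.response for e in estimates],
            "condition": [e.condition for e in estimates],
            "epsilon": [e.epsilon for e in estimates],
            "se": [e.se for e in estimates],
            "n_backgrounds": [e.n_backgrounds for e in estimates],
            "gate_F": [e.gate_F for e in estimates],
            "gate_p": [e.gate_p for e in estimates],
            "gated": [e.gated for e in estimates],
            "available": [e.available for e in estimates],
            "slopes": [json.dumps(e.slopes) for e in estimates],
        }
    )


def render_matrix(
    estimates: list[ElasticityEstimate],
    csv_path: str | Path,
    image_path: str | Path | None = None,
    epsilon_cap: float = 1.0,
) -> pd.DataFrame:
    """Write the interaction matrix as CSV and, optionally, a shaded figure.

    ``epsilon_cap`` clips the colour scale at |epsilon| = cap so a single
    extreme cell cannot wash out the shading of the rest.
    """
    if not estimates:
        raise ValueError("no estimates to render")
    frame = matrix_to_frame(estimates)
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    if image_path is not None:
        _render_heatmap(estimates, Path(image_path), epsilon_cap)
    return frame


def _render_heatmap(
    estimates: list[ElasticityEstimate], image_path: Path, epsilon_cap: float
) -> None:
    rows = sorted(
        {(e.perturbed, e.response) for e in estimates},
        key=lambda pr: (("G6pd", "Idh", "Men").index(pr[0]), pr[1]),
    )
    cols = [c for c in CONDITIONS if any(e.condition == c for e in estimates)]
    by_key = {(e.perturbed, e.response, e.condition): e for e in estimates}
    grid = np.full((len(rows), len(cols)), math.nan)
    labels = np.full((len(rows), len(cols)), "", dtype=object)
    for i, (g, r) in enumerate(rows):
        for j, c in enumerate(cols):
            est = by_key.get((g, r, c))
            if est is None or not est.available:
                labels[i, j] = "n/a"
            elif not est.gated:
                labels[i, j] = "NS"
            else:
                grid[i, j] = est.epsilon
                labels[i, j] = f"{est.epsilon:+.2f}"
    fig, ax = plt.subplots(
        figsize=(1.6 * len(cols) + 3.0, 0.5 * len(rows) + 1.5)
    )
    norm = Normalize(vmin=-epsilon_cap, vmax=epsilon_cap)
    shown = np.clip(grid, -epsilon_cap, epsilon_cap)
    masked = np.ma.masked_invalid(shown)
    im = ax.imshow(masked, cmap=INTERACTION_CMAP, norm=norm, aspect="auto")
    ax.set_xticks(range(len(cols)), cols)
    ax.set_yticks(
        range(len(rows)),
        [f"{g} → {_SHORT.get(r, r)}" for g, r in rows],
    )
    for i in range(len(rows)):
        for j in range(len(cols)):
            ax.text(j, i, labels[i, j], ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="elasticity ε (ln-ln slope)")
    ax.set_title("Gated elasticity coefficients by condition")
    fig.tight_layout()
    image_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(image_path, dpi=150)
    plt.close(fig)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    outdir: str | Path,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
    render_image: bool = True,
    design=None,
) -> dict:
    """simulate -> validate -> percent-change summary -> elasticity matrix ->
    condition comparisons -> rendered outputs.

    Returns the manifest (also written to ``outdir/manifest.json``).  Fully
    deterministic for a fixed (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config if config is not None else calibrated_default_config()
    if seed is not None:
        config = config.with_seed(seed)

    stage = "simulate"
    try:
        dataset = generate_dataset(config, design=design)
        write_samples(dataset, outdir / "samples.csv")
        logger.info("simulate: %d samples", len(dataset))

        stage = "validate"
        report = validate_design(dataset)
        report.to_frame().to_csv(outdir / "design_check.csv", index=False)

        stage = "percent_change"
        pct_frames = [
            percent_change_vs_control(dataset, var).to_frame()
            for var in MEASURED_VARIABLES
        ]
        pct = pd.concat(pct_frames, ignore_index=True)
        pct.to_csv(outdir / "percent_change.csv", index=False, float_format="%.17g")

        stage = "elasticity"
        estimates = elasticity_matrix(dataset, alpha=alpha)
        render_matrix(
            estimates,
            outdir / "elasticity_matrix.csv",
            outdir / "elasticity_matrix.png" if render_image else None,
        )
        logger.info("elasticity: %d matrix cells", len(estimates))

        stage = "conditions"
        comparisons = {}
        for gene in dataset.design.genes:
            for response in matrix_responses(gene):
                records, anova, tukey = compare_conditions(
                    dataset, gene, response, alpha=alpha
                )
                comparisons[f"{gene}:{response}"] = {
                    "ratios": [
                        {
                            "background": r.background,
                            "condition": r.condition,
                            "ratio": r.ratio,
                        }
                        for r in records
                        if r.defined
                    ],
                    "anova": {
                        "F": anova.F,
                        "df_num": anova.df_num,
                        "df_den": anova.df_den,
                        "p_value": anova.p_value,
                    },
                    "tukey": {
                        "pairs": [list(p) for p in tukey.pairs],
                        "p_adj": tukey.p_adj,
                        "significant": tukey.significant,
                    },
                }
        (outdir / "condition_comparisons.json").write_text(
            json.dumps(comparisons, indent=2, sort_keys=True)
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, exc) from exc

    manifest = {
        "package_version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "alpha": alpha,
        "n_samples": len(dataset),
        "n_matrix_cells": len(estimates),
        "n_empty_design_cells": len(report.empty_cells),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
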