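"""Experimental design, sample schema, and the long-format sample table.

The unit of observation is one homogenate of (usually) four male flies,
assayed for the three NADP-reducing enzyme activities (G6PD, IDH, MEN),
triglyceride and carbohydrate concentrations, plus the soluble-protein and
body-weight covariates.  Samples are organised in a factorial cross design:
gene series x third-chromosome background x genotype class x environmental
condition x bottle replicate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENES: tuple[str, ...] = ("G6pd", "Idh", "Men")
CONDITIONS: tuple[str, ...] = ("control", "oxidative", "starvation", "desiccation")
GENOTYPE_CLASSES: tuple[str, ...] = ("full", "reduced")
#: Third-chromosome background lines (isothird lines fixed from wild isofemales).
DEFAULT_BACKGROUNDS: tuple[str, ...] = (
    "CT21", "HFL53", "JFL12", "JFL29", "MD76", "MD80", "VT26",
)

#: Enzyme activity columns, keyed by the gene whose series perturbs them.
ACTIVITY_COLUMNS: dict[str, str] = {
    "G6pd": "activity_g6pd",
    "Idh": "activity_idh",
    "Men": "activity_men",
}
METABOLITE_COLUMNS: tuple[str, ...] = ("triglyceride", "carbohydrate_mg_per_L")
#: All five measured response variables.
MEASURED_VARIABLES: tuple[str, ...] = tuple(ACTIVITY_COLUMNS.values()) + METABOLITE_COLUMNS
COVARIATE_COLUMNS: tuple[str, ...] = ("protein_mg_per_L", "weight_mg")

#: Column order of the long-format sample CSV.
SAMPLE_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "gene_series",
    "genotype_class",
    "background",
    "condition",
    "bottle",
    "n_flies",
    "weight_mg",
    "protein_mg_per_L",
    "activity_g6pd",
    "activity_idh",
    "activity_men",
    "triglyceride",
    "carbohydrate_mg_per_L",
)

_STRING_COLUMNS = ("sample_id", "gene_series", "genotype_class", "background", "condition")
_INT_COLUMNS = ("bottle", "n_flies")
_FLOAT_COLUMNS = tuple(c for c in SAMPLE_COLUMNS if c not in _STRING_COLUMNS + _INT_COLUMNS)

# Activities are stored in the assay-report convention,
# micromol NADP reduced / min / microgram soluble protein x 10,000,
# which equals 10 x (nmol / min / microgram).  The elasticity path logs
# activities on the nmol scale, hence this fixed conversion factor.
TABLE_TO_NMOL: float = 0.1


class SchemaError(ValueError):
    """The sample table's columns do not match the documented schema."""


class DesignValidationError(ValueError):
    """A sample carries a label outside the experimental design's enumerations."""


@dataclass(frozen=True)
class ExperimentalDesign:
    """The factorial layout of the cross experiment.

    Defaults reproduce the full design: 3 gene series x 7 backgrounds x
    2 genotype classes x 4 conditions x 2 bottles x 4 samples = 1,344 rows.
    """

    genes: tuple[str, ...] = GENES
    backgrounds: tuple[str, ...] = DEFAULT_BACKGROUNDS
    conditions: tuple[str, ...] = CONDITIONS
    genotype_classes: tuple[str, ...] = GENOTYPE_CLASSES
    bottles_per_cross: int = 2
    samples_per_bottle_per_condition: int = 4
    flies_per_sample: int = 4

    def __post_init__(self) -> None:
        for name in ("bottles_per_cross", "samples_per_bottle_per_condition", "flies_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be strictly positive")
        if not self.backgrounds:
            raise ValueError("at least one background is required")
        if len(set(self.backgrounds)) != len(self.backgrounds):
            raise ValueError("backgrounds must be unique")
        unknown = set(self.genes) - set(GENES)
        if unknown:
            raise ValueError(f"unknown gene series: {sorted(unknown)}")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        unknown = set(self.genotype_classes) - set(GENOTYPE_CLASSES)
        if unknown:
            raise ValueError(f"unknown genotype classes: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        """Number of rows in a complete dataset under this design."""
        return (
            len(self.genes)
            * len(self.backgrounds)
            * len(self.genotype_classes)
            * len(self.conditions)
            * self.bottles_per_cross
            * self.samples_per_bottle_per_condition
        )

    def cells(self) -> Iterable[tuple[str, str, str, str]]:
        """Iterate (gene, background, genotype, condition) design cells."""
        for g in self.genes:
            for b in self.backgrounds:
                for q in self.genotype_classes:
                    for c in self.conditions:
                        yield g, b, q, c

    def subset(self, **kwargs) -> "ExperimentalDesign":
        return replace(self, **kwargs)


@dataclass
class Dataset:
    """A validated long-format sample table plus its design and provenance."""

    frame: pd.DataFrame
    design: ExperimentalDesign = field(default_factory=ExperimentalDesign)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = _coerce_frame(self.frame)
        _validate_labels(self.frame, self.design)
        if self.frame["sample_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise DesignValidationError(
                f"duplicate sample_id values: {sorted(set(dupes))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, **labels) -> pd.DataFrame:
        """Rows matching the given label columns, e.g. gene_series='Men'."""
        mask = np.ones(len(self.frame), dtype=bool)
        for col, val in labels.items():
            mask &= (self.frame[col] == val).to_numpy()
        return self.frame.loc[mask]

    def equals(self, other: "Dataset") -> bool:
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)


def _coerce_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
    extra = [c for c in frame.columns if c not in SAMPLE_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"sample table schema mismatch: missing columns {missing}, extra columns {extra}"
        )
    frame = frame.loc[:, list(SAMPLE_COLUMNS)].copy()
    for col in _STRING_COLUMNS:
        frame[col] = frame[col].astype(str)
    for col in _INT_COLUMNS:
        frame[col] = _parse_numeric(frame[col], col).astype(np.int64)
    for col in _FLOAT_COLUMNS:
        frame[col] = _parse_numeric(frame[col], col).astype(np.float64)
    return frame


def _parse_numeric(series: pd.Series, col: str) -> pd.Series:
    # astype(float) is correctly rounded (unlike pandas' fast to_numeric
    # parser), which the lossless CSV round-trip contract relies on.
    try:
        return series.astype(np.float64)
    except (ValueError, TypeError):
        out = pd.to_numeric(series, errors="coerce")
        bad = out.isna() & series.notna()
        row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else 0
        raise SchemaError(
            f"unparseable numeric value {series.iloc[row]!r} in column {col!r}, row {row}"
        ) from None


def _validate_labels(frame: pd.DataFrame, design: ExperimentalDesign) -> None:
    checks = {
        "gene_series": design.genes,
        "genotype_class": design.genotype_classes,
        "background": design.backgrounds,
        "condition": design.conditions,
    }
    for col, allowed in checks.items():
        bad = sorted(set(frame[col]) - set(allowed))
        if bad:
            raise DesignValidationError(
                f"column {col!r} contains values outside the design: {bad}"
            )
    if (frame["weight_mg"] <= 0).any():
        raise DesignValidationError("weight_mg must be strictly positive")
    if (frame["protein_mg_per_L"] <= 0).any():
        raise DesignValidationError("protein_mg_per_L must be strictly positive")
    if (frame["n_flies"] < 1).any():
        raise DesignValidationError("n_flies must be >= 1")
    for col in MEASURED_VARIABLES:
        if (frame[col] < 0).any():
            raise DesignValidationError(f"{col} must be non-negative")


def read_samples(path: str | Path, design: ExperimentalDesign | None = None) -> Dataset:
    """Read a long-format sample CSV into a validated :class:`Dataset`.

    Numeric parsing is locale-independent (period decimal separator);
    row order is preserved.
    """
    design = design or ExperimentalDesign()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return Dataset(frame=frame, design=design, provenance={"source": str(path)})


def write_samples(dataset: Dataset, path: str | Path) -> None:
    """Write the sample table as CSV with lossless float round-trip."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.frame.to_csv(path, index=False, float_format="%.17g")


def to_csv_bytes(dataset: Dataset) -> bytes:
    buf = io.StringIO()
    dataset.frame.to_csv(buf, index=False, float_format="%.17g")
    return buf.getvalue().encode()


@dataclass
class CellReport:
    gene: str
    background: str
    genotype_class: str
    condition: str
    observed: int
    expected: int

    @property
    def empty(self) -> bool:
        return self.observed == 0

    @property
    def under_filled(self) -> bool:
        return 0 < self.observed < self.expected


@dataclass
class ValidationReport:
    """Per-design-cell observed vs. expected sample counts (report-only)."""

    cells: list[CellReport]

    @property
    def empty_cells(self) -> list[CellReport]:
        return [c for c in self.cells if c.empty]

    @property
    def under_filled_cells(self) -> list[CellReport]:
        return [c for c in self.cells if c.under_filled]

    @property
    def complete(self) -> bool:
        return not self.empty_cells and not self.under_filled_cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_series": c.gene,
                    "background": c.background,
                    "genotype_class": c.genotype_class,
                    "condition": c.condition,
                    "observed": c.observed,
                    "expected": c.expected,
                }
                for c in self.cells
            ]
        )


def validate_design(dataset: Dataset) -> ValidationReport:
    """Compare observed per-cell sample counts with the design's expectation.

    Non-fatal: real experiments occasionally run short of flies of a
    genotype, so shortfalls are reported, not raised.
    """
    design = dataset.design
    expected = design.bottles_per_cross * design.samples_per_bottle_per_condition
    counts = (
        dataset.frame.groupby(
            ["gene_series", "background", "genotype_class", "condition"], sort=False
        )
        .size()
        .to_dict()
    )
    cells = [
        CellReport(g, b, q, c, int(counts.get((g, b, q, c), 0)), expected)
        for g, b, q, c in design.cells()
    ]
    return ValidationReport(cells=cells)
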