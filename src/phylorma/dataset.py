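"""Specimen-level measurement ingest, fold cleaning, and species means.

The measurement table is delimited text (comma or tab, sniffed) with one
row per dissected specimen: species binomial, total body length (cm,
rostrum tip to fluke notch), vaginal length (cm, ectocervix base to cranial
vulva limit), individual vaginal fold lengths (mm, semicolon-separated) or
a precomputed cumulative fold length (mm), fold count, and maturity state.

Fold cleaning follows the anatomical definition: a vaginal fold is any
folding of the wall at least 0.5 mm long; folds shorter than 1 mm are
rounded up to 1 mm for the cumulative length but excluded from the fold
count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpecimenRecord",
    "TraitTable",
    "load_specimens",
    "clean_folds",
    "species_means",
    "log10_table",
    "nonphylo_residuals",
    "FOLD_MIN_MM",
    "FOLD_ROUND_MM",
]

FOLD_MIN_MM = 0.5     # shorter wall foldings are not counted as folds at all
FOLD_ROUND_MM = 1.0   # folds in [0.5, 1) mm are rounded up to this for sums

_COLUMN_ALIASES = {
    "specimen_id": {"specimen_id", "specimen", "id"},
    "species": {"species", "binomial", "taxon"},
    "body_length_cm": {"body_length_cm", "body_length", "bl_cm", "bl"},
    "vaginal_length_cm": {"vaginal_length_cm", "vaginal_length", "vl_cm", "vl"},
    "fold_lengths_mm": {"fold_lengths_mm", "fold_lengths", "vfl_list_mm"},
    "cumulative_fold_length_mm": {
        "cumulative_fold_length_mm", "cumulative_fold_length", "vfl_mm", "vfl",
    },
    "fold_count": {"fold_count", "n_folds", "folds"},
    "maturity": {"maturity", "maturity_state"},
    "location": {"location", "locality"},
}


@dataclass
class SpecimenRecord:
    """One carcass's raw measurements, with fold-cleaning provenance.

    ``fold_lengths`` holds the raw per-fold measurements in mm (possibly
    including sub-millimeter wall foldings); ``cumulative_fold_length`` and
    ``fold_count`` are the cleaned summaries.  ``cleaned_fold_lengths``
    records the analysis lengths actually summed.
    """

    specimen_id: str
    species: str
    body_length: float            # cm
    vaginal_length: float | None  # cm
    fold_lengths: list[float] | None = None         # raw mm
    cumulative_fold_length: float | None = None     # mm, cleaned
    fold_count: int | None = None
    maturity: str = "unknown"
    location: str = ""
    cleaned_fold_lengths: list[float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.body_length is None or not self.body_length > 0:
            raise ValueError(
                f"specimen {self.specimen_id!r}: body_length must be > 0, "
                f"got {self.body_length}"
            )
        if self.vaginal_length is not None and self.vaginal_length < 0:
            raise ValueError(f"specimen {self.specimen_id!r}: negative vaginal_length")
        if self.fold_lengths is not None and any(f < 0 for f in self.fold_lengths):
            raise ValueError(f"specimen {self.specimen_id!r}: negative fold length")
        if self.maturity not in ("mature", "immature", "unknown"):
            self.maturity = "unknown"
        self._reconcile_folds()

    def _reconcile_folds(self) -> None:
        if self.fold_lengths is not None:
            count, cumulative, analysis = clean_folds(self.fold_lengths)
            if (
                self.cumulative_fold_length is not None
                and abs(self.cumulative_fold_length - cumulative) > 0.5
            ):
                logger.warning(
                    "specimen %r: supplied cumulative fold length %.2f mm differs "
                    "from cleaned sum %.2f mm; the fold list takes precedence",
                    self.specimen_id, self.cumulative_fold_length, cumulative,
                )
            self.cumulative_fold_length = cumulative
            self.cleaned_fold_lengths = analysis
            if self.fold_count is None:
                self.fold_count = count
        if self.fold_count is not None and self.fold_count < 0:
            raise ValueError(f"specimen {self.specimen_id!r}: negative fold_count")
        if self.cumulative_fold_length is not None and self.cumulative_fold_length < 0:
            raise ValueError(
                f"specimen {self.specimen_id!r}: negative cumulative_fold_length"
            )


@dataclass
class TraitTable:
    """Species-keyed trait values with unit and scale metadata.

    ``data`` is a species-indexed DataFrame (one row per species);
    ``units`` maps trait name to unit string, and ``log_scale`` flags traits
    already on the log10 scale.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    log_scale: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("TraitTable requires one row per species")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def trait(self, name: str) -> pd.Series:
        return self.data[name]

    def to_sidecar_json(self) -> str:
        return json.dumps({"units": self.units, "log_scale": self.log_scale}, indent=2)


def clean_folds(raw_lengths) -> tuple[int, float, list[float]]:
    """Apply the fold-definition and rounding rules to raw fold lengths (mm).

    Entries below 0.5 mm are not folds and are dropped entirely; entries in
    [0.5, 1) mm are rounded up to 1 mm for the cumulative sum but excluded
    from the fold count.  Returns ``(fold_count, cumulative_mm,
    analysis_lengths)``.  Idempotent on its own ``analysis_lengths`` output.
    """
    raw = [float(v) for v in raw_lengths]
    if any(v < 0 for v in raw):
        raise ValueError("fold lengths must be nonnegative")
    analysis = [max(v, FOLD_ROUND_MM) for v in raw if v >= FOLD_MIN_MM]
    count = sum(1 for v in raw if v >= FOLD_ROUND_MM)
    return count, float(sum(analysis)), analysis


def _canonical_columns(columns) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        for canonical, aliases in _COLUMN_ALIASES.items():
            if key in aliases:
                mapping[col] = canonical
                break
    return mapping


def _parse_fold_cell(cell) -> list[float] | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    return [float(part) for part in text.split(";") if part.strip()]


def load_specimens(path) -> list[SpecimenRecord]:
    """Read a delimited specimen table (comma or tab, sniffed) into records.

    Mandatory columns: species and body length.  Fold lengths are parsed
    from a semicolon-separated cell; cleaning rules are applied on load.
    Unparseable cells are reported with their row and column.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    rename = _canonical_columns(df.columns)
    df = df.rename(columns=rename)
    for required in ("species", "body_length_cm"):
        if required not in df.columns:
            raise ValueError(
                f"missing mandatory column {required!r} (recognized from aliases "
                f"{sorted(_COLUMN_ALIASES[required])}); found {list(df.columns)}"
            )

    def cell(row, col, caster, rownum):
        value = row.get(col)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        text = str(value).strip()
        if not text:
            return None
        try:
            return caster(text)
        except ValueError as exc:
            raise ValueError(f"row {rownum}, column {col!r}: cannot parse {text!r}") from exc

    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        try:
            records.append(SpecimenRecord(
                specimen_id=str(row.get("specimen_id", f"row{rownum}")).strip(),
                species=str(row["species"]).strip(),
                body_length=cell(row, "body_length_cm", float, rownum),
                vaginal_length=cell(row, "vaginal_length_cm", float, rownum),
                fold_lengths=_parse_fold_cell(row.get("fold_lengths_mm")),
                cumulative_fold_length=cell(row, "cumulative_fold_length_mm", float, rownum),
                fold_count=cell(row, "fold_count", lambda s: int(float(s)), rownum),
                maturity=str(row.get("maturity", "unknown") or "unknown").strip(),
                location=str(row.get("location", "") or "").strip(),
            ))
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
    return records


_TRAIT_ACCESSORS = {
    "body_length": (lambda r: r.body_length, "cm"),
    "vaginal_length": (lambda r: r.vaginal_length, "cm"),
    "cumulative_fold_length": (lambda r: r.cumulative_fold_length, "mm"),
    "fold_count": (lambda r: r.fold_count, "count"),
}


def species_means(records: list[SpecimenRecord], trait: str) -> TraitTable:
    """Arithmetic per-species mean of one cleaned trait.

    Species with no usable (non-missing) value are dropped with a logged
    warning.  Record order is irrelevant.
    """
    if not records:
        raise ValueError("no specimen records supplied")
    if trait not in _TRAIT_ACCESSORS:
        raise ValueError(f"unknown trait {trait!r}; one of {sorted(_TRAIT_ACCESSORS)}")
    accessor, unit = _TRAIT_ACCESSORS[trait]
    values: dict[str, list[float]] = {}
    seen: set[str] = set()
    for rec in records:
        seen.add(rec.species)
        v = accessor(rec)
        if v is not None:
            values.setdefault(rec.species, []).append(float(v))
    dropped = sorted(seen - set(values))
    if dropped:
        logger.warning("species with no usable %s value dropped: %s", trait, dropped)
    # summation over sorted values makes the mean exactly permutation-invariant
    means = pd.Series(
        {sp: float(np.mean(sorted(vs))) for sp, vs in sorted(values.items())},
        name=trait,
    )
    return TraitTable(means.to_frame(), units={trait: unit}, log_scale={trait: False})


def log10_table(table: TraitTable) -> TraitTable:
    """Base-10 log transform of every trait column.

    Raises if any value is nonpositive, naming the species and trait.
    """
    data = table.data.copy()
    for col in data.columns:
        bad = data.index[data[col] <= 0].tolist()
        if bad:
            raise ValueError(f"nonpositive values in trait {col!r} for species {bad}")
        data[col] = np.log10(data[col])
    units = {c: f"log10({u})" for c, u in table.units.items()}
    return TraitTable(data, units=units, log_scale={c: True for c in data.columns})


def nonphylo_residuals(x, y, method: str = "rma") -> np.ndarray:
    """Residuals from an ordinary (non-phylogenetic) line through (x, y).

    The line is fitted from ordinary sample moments — ``method='rma'`` gives
    the standardized-major-axis slope sign(S_xy) sqrt(S_yy / S_xx),
    ``method='ols'`` the least-squares slope S_xy / S_xx — and residuals are
    e_i = y_i - (b0 + b1 x_i).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("residual fit requires n >= 3")
    sxx = np.var(x, ddof=1)
    if sxx <= 0:
        raise ValueError("zero variance in x")
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if method == "rma":
        sign = np.sign(sxy) if sxy != 0 else 1.0
        b1 = sign * np.sqrt(syy / sxx)
    elif method == "ols":
        b1 = sxy / sxx
    else:
        raise ValueError("method must be 'rma' or 'ols'")
    b0 = y.mean() - b1 * x.mean()
    return y - (b0 + b1 * x)
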