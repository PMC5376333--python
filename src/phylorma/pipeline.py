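"""End-to-end study pipeline: three phylogenetic RMA regressions.

Given a rooted tree and a specimen-level measurement table, the pipeline
computes species means of total body length (BL), vaginal length (VL) and
cumulative vaginal fold length (VFL), log10-transforms them, and fits

    1. VL  ~ BL   (phylogenetic RMA, Pagel's lambda estimated),
    2. VFL ~ BL   (ditto),
    3. VFL residuals ~ VL residuals, where the residuals are taken from
       ordinary (non-phylogenetic) fits of each trait on BL, and the
       residual pair is then fitted with a phylogenetic RMA.

Every slope is tested against the isometric expectation for
length-on-length scaling (predicted exponent h = 1).  An optional fourth
fit regresses VFL residuals on fold counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import (
    SpecimenRecord,
    TraitTable,
    load_specimens,
    log10_table,
    nonphylo_residuals,
    species_means,
)
from .phylo_rma import RMAFit, phyl_rma
from .treeio import PhyloTree, read_newick

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "summarize_specimens",
           "write_report", "read_report"]

REPORT_COLUMNS = [
    "fit", "n", "r2_paper", "r2_corr", "beta0", "beta1", "ci_low", "ci_high",
    "h", "lambda_hat", "p_slope", "p_lambda", "t_stat", "df", "lrt_stat",
]


@dataclass
class StudyConfig:
    """All knobs of one pipeline run.

    ``units='mm'`` converts every length trait to millimeters before the
    log10 transform (slopes, correlations, lambda and all tests are
    unaffected by the choice; only intercepts move); ``units='paper'``
    keeps native units (BL and VL in cm, VFL in mm).
    """

    tree_path: str | Path = ""
    specimen_table_path: str | Path = ""
    h: float = 1.0                      # predicted exponent (isometry)
    units: str = "mm"                   # 'mm' | 'paper'
    residual_method: str = "rma"        # 'rma' | 'ols'
    alpha: float = 0.05
    df_policy: str = "n-2"              # 'n-2' | 'n-1'
    r2_ss: str = "ordinary"             # 'ordinary' | 'gls'
    include_fold_count_fit: bool = False
    out_dir: str | Path | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("predicted exponent h must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.units not in ("mm", "paper"):
            raise ValueError("units must be 'mm' or 'paper'")
        if self.residual_method not in ("rma", "ols"):
            raise ValueError("residual_method must be 'rma' or 'ols'")
        if self.df_policy not in ("n-2", "n-1"):
            raise ValueError("df_policy must be 'n-2' or 'n-1'")


@dataclass
class StudyReport:
    """Three fitted regressions plus the species-mean table they used."""

    fits: dict[str, RMAFit]
    species_means: pd.DataFrame          # log10 species means used in fits
    species_counts: dict[str, int]
    summary: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "species_means": self.species_means.reset_index()
                                 .to_dict(orient="list"),
            "species_counts": dict(self.species_counts),
            "summary": self.summary,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        means = pd.DataFrame(d["species_means"]).set_index("species")
        return cls(
            fits={k: RMAFit.from_dict(v) for k, v in d["fits"].items()},
            species_means=means,
            species_counts=dict(d["species_counts"]),
            summary=d["summary"],
            provenance=d["provenance"],
        )

    def table(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            row = {"fit": name}
            row.update({k: getattr(fit, k) for k in REPORT_COLUMNS if k != "fit"})
            rows.append(row)
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _sd(values: np.ndarray) -> float | None:
    return float(np.std(values, ddof=1)) if len(values) > 1 else None


def summarize_specimens(records: list[SpecimenRecord]) -> dict:
    """Specimen-level summary statistics (N, mean, sample SD, min, max).

    Computed for vaginal length (cm), cumulative vaginal fold length (mm)
    and fold count; SD uses the n - 1 divisor and is reported as missing
    for singleton samples.
    """
    if not records:
        raise ValueError("no specimen records")

    def block(values, unit):
        v = np.array([x for x in values if x is not None], dtype=float)
        if len(v) == 0:
            return {"n": 0, "unit": unit}
        return {
            "n": int(len(v)),
            "mean": float(v.mean()),
            "sd": _sd(v),
            "min": float(v.min()),
            "max": float(v.max()),
            "unit": unit,
        }

    return {
        "vaginal_length": block([r.vaginal_length for r in records], "cm"),
        "cumulative_fold_length": block(
            [r.cumulative_fold_length for r in records], "mm"),
        "fold_count": block([r.fold_count for r in records], "count"),
        "n_specimens": len(records),
        "n_species": len({r.species for r in records}),
    }


def _to_unit_policy(table: TraitTable, units: str) -> TraitTable:
    if units == "paper":
        return table
    data = table.data.copy()
    new_units = dict(table.units)
    for col, unit in table.units.items():
        if unit == "cm":
            data[col] = data[col] * 10.0
            new_units[col] = "mm"
    return TraitTable(data, units=new_units, log_scale=dict(table.log_scale))


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_study(
    config: StudyConfig,
    tree: PhyloTree | None = None,
    records: list[SpecimenRecord] | None = None,
) -> StudyReport:
    """Execute the full three-regression study.

    ``tree`` and ``records`` may be passed directly (e.g. from the
    synthetic generator); otherwise they are loaded from the paths in
    ``config``.  Raises with the stage name on any failure.
    """
    stage = "load"
    try:
        if tree is None:
            tree = read_newick(config.tree_path)
        if records is None:
            records = load_specimens(config.specimen_table_path)

        stage = "species_means"
        tables = {
            "BL": species_means(records, "body_length"),
            "VL": species_means(records, "vaginal_length"),
            "VFL": species_means(records, "cumulative_fold_length"),
        }
        merged = pd.concat(
            {k: _to_unit_policy(t, config.units).data.iloc[:, 0]
             for k, t in tables.items()},
            axis=1,
        )
        units = {
            k: ("mm" if (config.units == "mm" or k == "VFL") else "cm")
            for k in merged.columns
        }

        stage = "log10"
        in_tree = merged.index.intersection(tree.tips)
        dropped = sorted(set(merged.index) - set(in_tree))
        if dropped:
            logger.warning("species not in tree dropped: %s", dropped)
        merged = merged.loc[in_tree].dropna()
        nonpos = merged.index[(merged <= 0).any(axis=1)].tolist()
        if nonpos:
            logger.warning(
                "species with a nonpositive trait mean dropped before log10: %s",
                nonpos)
            merged = merged.drop(index=nonpos)
        log_table = log10_table(
            TraitTable(merged, units=units,
                       log_scale={k: False for k in merged.columns})
        )
        log_means = log_table.data
        log_means.index.name = "species"

        stage = "fit:VL_vs_BL"
        df_offset = 2 if config.df_policy == "n-2" else 1
        common = dict(h=config.h, alpha=config.alpha, r2_ss=config.r2_ss)

        def fit(xcol_or_series, ycol_or_series, h=None):
            x = (log_means[xcol_or_series] if isinstance(xcol_or_series, str)
                 else xcol_or_series)
            y = (log_means[ycol_or_series] if isinstance(ycol_or_series, str)
                 else ycol_or_series)
            n = len(set(tree.tips) & set(x.index) & set(y.index))
            kw = dict(common)
            if h is not None:
                kw["h"] = h
            return phyl_rma(tree, x, y, df=n - df_offset, **kw)

        fits = {"VL_vs_BL": fit("BL", "VL"), "VFL_vs_BL": fit("BL", "VFL")}

        stage = "residuals"
        res_vl = nonphylo_residuals(log_means["BL"], log_means["VL"],
                                    method=config.residual_method)
        res_vfl = nonphylo_residuals(log_means["BL"], log_means["VFL"],
                                     method=config.residual_method)
        res_vl = pd.Series(res_vl, index=log_means.index)
        res_vfl = pd.Series(res_vfl, index=log_means.index)

        stage = "fit:VFLres_vs_VLres"
        fits["VFLres_vs_VLres"] = fit(res_vl, res_vfl)

        if config.include_fold_count_fit:
            stage = "fit:VFLres_vs_foldcount"
            counts = species_means(records, "fold_count").data.iloc[:, 0]
            counts = np.log10(counts[counts > 0])
            fits["VFLres_vs_foldcount"] = fit(counts, res_vfl)

        stage = "summarize"
        summary = summarize_specimens(records)
        provenance = {
            "phylorma_version": __version__,
            "config": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in asdict(config).items()},
            "residuals_mean": {
                "VLres": float(res_vl.mean()),
                "VFLres": float(res_vfl.mean()),
            },
            "inputs": {},
        }
        if config.tree_path and Path(config.tree_path).exists():
            provenance["inputs"]["tree_sha256"] = _digest(config.tree_path)
        if (config.specimen_table_path
                and Path(config.specimen_table_path).exists()):
            provenance["inputs"]["specimens_sha256"] = _digest(
                config.specimen_table_path)

        report = StudyReport(
            fits=fits,
            species_means=log_means,
            species_counts={k: f.n for k, f in fits.items()},
            summary=summary,
            provenance=provenance,
        )
        if config.out_dir is not None:
            write_report(report, config.out_dir)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def write_report(report: StudyReport, out_dir, formats=("tsv", "json", "markdown")):
    """Write the study report; returns the list of files written.

    ``report.json`` round-trips losslessly via :meth:`StudyReport.from_dict`;
    ``report.tsv`` holds the three-row fit table; ``report.md`` renders the
    same numbers to three decimals.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    table = report.table()
    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True)
                        + "\n")
        written.append(path)
    if "tsv" in formats:
        path = out_dir / "report.tsv"
        table.to_csv(path, sep="\t", index=False)
        written.append(path)
        means = out_dir / "species_means.tsv"
        report.species_means.to_csv(means, sep="\t")
        written.append(means)
    if "markdown" in formats:
        path = out_dir / "report.md"
        fmt = table.copy()
        for col in fmt.columns:
            if fmt[col].dtype.kind == "f":
                fmt[col] = fmt[col].map(lambda v: f"{v:.3f}")
        lines = ["| " + " | ".join(fmt.columns) + " |",
                 "| " + " | ".join("---" for _ in fmt.columns) + " |"]
        for _, row in fmt.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written


def read_report(path) -> StudyReport:
    """Load a report back from its JSON serialization."""
    return StudyReport.from_dict(json.loads(Path(path).read_text()))
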