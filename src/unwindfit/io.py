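"""File-format plumbing: the intensity CSV dialect and JSON fit reports.

One CSV dialect only, no sniffing: UTF-8, comma separated, decimal point,
header exactly ``dose_gy,donor,replicate,intensity``.  Parse failures
raise :class:`~unwindfit.exceptions.DataValidationError` carrying the
1-based line number of the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import DataValidationError
from .fitting import (
    COLUMNS,
    BootstrapSummary,
    DonorCurve,
    IntensityDataset,
    JointFitResult,
)

__all__ = [
    "read_intensity_csv",
    "write_intensity_csv",
    "fit_report",
    "write_fit_report",
    "read_fit_report",
    "fit_result_from_report",
    "parameter_table",
]

SCHEMA_VERSION = "1"


def read_intensity_csv(path: str | Path) -> IntensityDataset:
    """Read a long-format intensity CSV into a validated dataset.

    Rejects wrong headers, nonnumeric fields and duplicate
    (dose, donor, replicate) rows, reporting the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"{path}: file is empty") from None
    if list(df.columns) != list(COLUMNS):
        raise DataValidationError(
            f"{path}: header must be {','.join(COLUMNS)!r}, "
            f"got {','.join(df.columns)!r}",
            line=1,
        )
    for col in ("dose_gy", "intensity"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataValidationError(
                f"nonnumeric {col} value {df[col].iloc[row]!r}",
                line=row + 2,  # header is line 1
            )
        df[col] = numeric
    dup = df.duplicated(subset=["dose_gy", "donor", "replicate"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise DataValidationError(
            "duplicate (dose, donor, replicate) index "
            f"({df['dose_gy'].iloc[row]}, {df['donor'].iloc[row]}, "
            f"{df['replicate'].iloc[row]})",
            line=row + 2,
        )
    return IntensityDataset(df)


def write_intensity_csv(data: IntensityDataset, path: str | Path) -> None:
    """Write a dataset in the package's CSV dialect."""
    data.frame.to_csv(path, index=False)


def fit_report(
    fit: JointFitResult,
    bootstrap: BootstrapSummary | None = None,
    config: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Assemble the JSON-serialisable fit report.

    Confidence bounds are attached when a bootstrap summary is supplied;
    ``config`` records the resolved run configuration (seed, tolerances,
    input path) so a run is reproducible from its output alone.
    """

    def _ci(name: str):
        if bootstrap is None or name not in bootstrap.per_parameter:
            return None
        _, lo, hi = bootstrap.per_parameter[name]
        return [lo, hi]

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "model": "P(d) = B + (P0 - B) * exp(-beta * d)",
        "background": {"B": fit.B, "ci95": _ci("B")},
        "donors": {
            k: {
                "P0": p.P0,
                "P0_ci95": _ci(f"P0[{k}]"),
                "beta": p.beta,
                "beta_ci95": _ci(f"beta[{k}]"),
            }
            for k, p in fit.per_donor.items()
        },
        "goodness_of_fit": {
            "ss_err": fit.ss_err,
            "ss_tot": fit.ss_tot,
            "r_squared": fit.r_squared,
        },
        "convergence": {
            "converged": fit.converged,
            "n_iterations": fit.n_iterations,
            "message": fit.message,
            "flags": list(fit.flags),
        },
    }
    if bootstrap is not None:
        report["bootstrap"] = {
            "n_samples": bootstrap.n_samples,
            "level": bootstrap.level,
            "seed": bootstrap.seed,
            "n_failed": bootstrap.n_failed,
            "interval_type": "percentile",
        }
    if config is not None:
        report["config"] = config
    return report


def write_fit_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def read_fit_report(path: str | Path) -> dict[str, Any]:
    report = json.loads(Path(path).read_text())
    if report.get("schema_version") != SCHEMA_VERSION:
        raise DataValidationError(
            f"unsupported fit-report schema {report.get('schema_version')!r}"
        )
    return report


def fit_result_from_report(report: dict[str, Any]) -> JointFitResult:
    """Rebuild the fitted parameters from a JSON report (for inversion)."""
    donors = {
        k: DonorCurve(v["P0"], v["beta"]) for k, v in report["donors"].items()
    }
    gof = report.get("goodness_of_fit", {})
    conv = report.get("convergence", {})
    return JointFitResult(
        B=report["background"]["B"],
        per_donor=donors,
        ss_err=gof.get("ss_err", float("nan")),
        ss_tot=gof.get("ss_tot", float("nan")),
        r_squared=gof.get("r_squared", float("nan")),
        converged=conv.get("converged", True),
        n_iterations=conv.get("n_iterations", 0),
        message=conv.get("message", ""),
        flags=tuple(conv.get("flags", ())),
    )


def parameter_table(
    fit: JointFitResult, bootstrap: BootstrapSummary | None = None
) -> pd.DataFrame:
    """Per-donor parameter table (donor, P0, beta and, when available,
    95% CI bounds) mirroring the layout of the reference publication."""
    rows = []
    for k, p in fit.per_donor.items():
        row: dict[str, Any] = {"donor": k, "P0": p.P0, "beta": p.beta}
        if bootstrap is not None:
            _, lo, hi = bootstrap.per_parameter[f"P0[{k}]"]
            row["P0_ci_low"], row["P0_ci_high"] = lo, hi
            _, lo, hi = bootstrap.per_parameter[f"beta[{k}]"]
            row["beta_ci_low"], row["beta_ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)
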