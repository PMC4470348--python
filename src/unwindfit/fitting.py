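"""Joint dose-response estimation for multi-donor unwinding intensity data.

Every donor ``k`` contributes an exponential dose-response curve
``P_k(d) = B + (P0_k - B) exp(-beta_k d)`` with donor-specific zero-dose
intensity ``P0_k`` and decay rate ``beta_k``, while the background ``B`` —
a property of the dye/DNA chemistry, not of the donor — is shared across
all curves.  The joint fit minimises the unweighted sum of squares

    z(B, beta, P0) = sum_k sum_j (P_k(d_j) - Pbar_jk)^2

over the replicate means ``Pbar_jk`` with a Levenberg-Marquardt least-
squares routine.  For balanced replicates this minimiser coincides with
the one obtained from the per-replicate sum of squares (the residual per
cell decomposes into the mean residual plus a parameter-free variance
term), which the test-suite verifies numerically.

Goodness of fit is summarised by ``R^2 = 1 - SS_err / SS_tot`` with
``SS_tot`` the total sum of squares of the replicate means around their
grand mean.  Parameter uncertainty comes from a within-cell bootstrap:
each resample redraws, for every (dose, donor) cell, the same number of
intensities from that cell's replicates with replacement, then refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DataValidationError, DegenerateDataError

__all__ = [
    "DonorCurve",
    "IntensityDataset",
    "JointFitResult",
    "BootstrapSummary",
    "replicate_means",
    "evaluate_objective",
    "fit_joint",
    "r_squared",
    "bootstrap_ci",
]

COLUMNS = ("dose_gy", "donor", "replicate", "intensity")


class DonorCurve(NamedTuple):
    """Per-donor exponential parameters (zero-dose intensity, decay rate)."""

    P0: float
    beta: float


class IntensityDataset:
    """Long-format relative intensities indexed by dose, donor, replicate.

    Wraps a DataFrame with columns ``dose_gy`` (>= 0), ``donor`` (string
    identifier), ``replicate`` (label within a (dose, donor) cell) and
    ``intensity`` (finite, > 0).  Duplicate (dose, donor, replicate) rows
    are rejected.  The index grid need not be complete; missing cells are
    simply absent.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise DataValidationError(f"missing columns: {missing}")
        df = frame.loc[:, list(COLUMNS)].copy()
        df["donor"] = df["donor"].astype(str)
        df["replicate"] = df["replicate"].astype(str)
        df["dose_gy"] = pd.to_numeric(df["dose_gy"], errors="raise")
        df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
        if (df["dose_gy"] < 0).any():
            raise DataValidationError("doses must be >= 0")
        bad = ~np.isfinite(df["intensity"]) | (df["intensity"] <= 0)
        if bad.any():
            raise DataValidationError(
                f"{int(bad.sum())} intensities are nonpositive or non-finite"
            )
        dup = df.duplicated(subset=["dose_gy", "donor", "replicate"])
        if dup.any():
            first = df[dup].iloc[0]
            raise DataValidationError(
                "duplicate (dose, donor, replicate) row: "
                f"({first['dose_gy']}, {first['donor']}, {first['replicate']})"
            )
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        """The validated long-format table (copy)."""
        return self._df.copy()

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self._df["dose_gy"].unique())

    @property
    def donors(self) -> list[str]:
        return sorted(self._df["donor"].unique(), key=_donor_key)

    def replicate_means(self) -> pd.DataFrame:
        """Per-(dose, donor) mean over replicates: doses as rows, donors
        as columns; NaN marks an absent cell."""
        means = (
            self._df.groupby(["dose_gy", "donor"], sort=True)["intensity"]
            .mean()
            .unstack("donor")
        )
        return means.loc[:, self.donors]

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntensityDataset):
            return NotImplemented
        a = self._df.sort_values(list(COLUMNS[:3])).reset_index(drop=True)
        b = other._df.sort_values(list(COLUMNS[:3])).reset_index(drop=True)
        return a.equals(b)


def _donor_key(donor: str):
    # numeric donor labels sort numerically, others lexically
    try:
        return (0, float(donor), donor)
    except ValueError:
        return (1, 0.0, donor)


def replicate_means(data: IntensityDataset) -> pd.DataFrame:
    """Arithmetic mean over replicates for every (dose, donor) cell."""
    means = data.replicate_means()
    if means.isna().all(axis=None):
        raise DataValidationError("dataset has no populated (dose, donor) cells")
    return means


@dataclass(frozen=True)
class JointFitResult:
    """Result of the joint fit: shared background, per-donor curves,
    goodness-of-fit terms and convergence metadata.

    ``flags`` lists soft-constraint violations (the optimisation itself is
    unconstrained, mirroring the Levenberg-Marquardt usage the model was
    developed with): ``B`` outside [0, 1), any ``P0`` above 1 or below
    ``B``, any negative ``beta``.
    """

    B: float
    per_donor: dict[str, DonorCurve]
    ss_err: float
    ss_tot: float
    r_squared: float
    converged: bool
    n_iterations: int
    message: str = ""
    flags: tuple[str, ...] = ()

    def curve(self, donor: str):
        """The fitted :class:`~unwindfit.model.ExpFitParams` for ``donor``."""
        from .model import ExpFitParams

        p = self.per_donor[donor]
        return ExpFitParams(B=self.B, P0=p.P0, beta=p.beta)


def _pack(B: float, donors: list[str], per_donor: Mapping[str, DonorCurve]) -> np.ndarray:
    K = len(donors)
    x = np.empty(1 + 2 * K)
    x[0] = B
    for i, k in enumerate(donors):
        x[1 + i] = per_donor[k].P0
        x[1 + K + i] = per_donor[k].beta
    return x


def _unpack(x: np.ndarray, donors: list[str]) -> tuple[float, dict[str, DonorCurve]]:
    K = len(donors)
    return float(x[0]), {
        k: DonorCurve(float(x[1 + i]), float(x[1 + K + i]))
        for i, k in enumerate(donors)
    }


def evaluate_objective(
    B: float,
    per_donor: Mapping[str, DonorCurve | tuple[float, float]],
    means: pd.DataFrame,
) -> float:
    """The joint sum-of-squares objective on replicate means.

    ``means`` is a (dose x donor) table as returned by
    :func:`replicate_means`; NaN cells are skipped.  Zero iff the model
    reproduces every populated mean exactly.
    """
    doses = means.index.to_numpy(dtype=float)
    total = 0.0
    for k in means.columns:
        P0, beta = per_donor[k]
        model = B + (P0 - B) * np.exp(-beta * doses)
        resid = model - means[k].to_numpy(dtype=float)
        total += float(np.nansum(resid**2))
    return total


def _initial_values(means: pd.DataFrame) -> tuple[float, dict[str, DonorCurve]]:
    """Cheap, scale-aware starting point inside the feasible region.

    B0 is 90% of the smallest observed mean; P0 starts at each donor's
    zero-dose (or lowest-dose) mean; beta from the slope of a log-linear
    regression of (mean - B0) on dose over that donor's cells above B0.
    """
    doses = means.index.to_numpy(dtype=float)
    B0 = 0.9 * float(np.nanmin(means.to_numpy()))
    per_donor: dict[str, DonorCurve] = {}
    for k in means.columns:
        y = means[k].to_numpy(dtype=float)
        ok = np.isfinite(y)
        d_k, y_k = doses[ok], y[ok]
        order = np.argsort(d_k)
        d_k, y_k = d_k[order], y_k[order]
        P0_init = float(y_k[0]) if len(y_k) else 1.0
        above = y_k > B0
        if above.sum() >= 2 and np.ptp(d_k[above]) > 0:
            slope = np.polyfit(d_k[above], np.log(y_k[above] - B0), 1)[0]
            beta_init = max(-float(slope), 1e-6)
        else:
            beta_init = 0.1
        per_donor[k] = DonorCurve(P0_init, beta_init)
    return B0, per_donor


def _residuals_and_jac(x, donors, dose_idx, donor_idx, dose_values, y, w):
    """Weighted residual vector and analytic Jacobian for least_squares."""
    K = len(donors)
    B = x[0]
    P0 = x[1 : 1 + K][donor_idx]
    beta = x[1 + K :][donor_idx]
    d = dose_values[dose_idx]
    e = np.exp(-beta * d)
    resid = (B + (P0 - B) * e - y) * w

    jac = np.zeros((len(y), 1 + 2 * K))
    jac[:, 0] = (1.0 - e) * w
    rows = np.arange(len(y))
    jac[rows, 1 + donor_idx] = e * w
    jac[rows, 1 + K + donor_idx] = -(P0 - B) * d * e * w
    return resid, jac


def fit_joint(
    data: IntensityDataset,
    init: tuple[float, Mapping[str, DonorCurve]] | None = None,
    objective: str = "means",
    ftol: float = 1e-12,
    gtol: float = 1e-10,
    xtol: float = 1e-12,
    max_iter: int = 500,
) -> JointFitResult:
    """Jointly fit shared ``B`` and per-donor ``(P0_k, beta_k)``.

    Parameters
    ----------
    data
        Intensity dataset with at least three distinct doses.
    init
        Optional ``(B, {donor: DonorCurve})`` starting values; by default
        a log-linear warm start is derived from the data.
    objective
        ``"means"`` minimises the sum of squares of replicate means (the
        default); ``"replicates"`` minimises over every individual
        replicate.  For balanced data the two minimisers coincide.

    The optimisation is unconstrained Levenberg-Marquardt (trust-region
    reflective fallback when residuals are fewer than parameters); soft
    bound violations are reported in ``flags``, never clamped.
    Deterministic given ``data`` and ``init``.
    """
    if objective not in ("means", "replicates"):
        raise DataValidationError(f"unknown objective {objective!r}")
    means = replicate_means(data)
    if len(data.doses) < 3:
        raise DataValidationError("need >= 3 distinct doses to identify the model")
    intens = data.frame["intensity"].to_numpy()
    if np.allclose(intens, intens[0], rtol=0, atol=1e-12):
        raise DegenerateDataError(
            "all intensities identical: beta is unidentifiable"
        )

    donors = data.donors
    if init is None:
        B0, start = _initial_values(means)
    else:
        B0, start_map = init
        start = {k: DonorCurve(*start_map[k]) for k in donors}
    x0 = _pack(B0, donors, start)

    if objective == "means":
        stacked = means.stack(future_stack=True).dropna()
        dose_values = means.index.to_numpy(dtype=float)
        dose_pos = {d: i for i, d in enumerate(dose_values)}
        donor_pos = {k: i for i, k in enumerate(donors)}
        dose_idx = np.array([dose_pos[d] for d, _ in stacked.index])
        donor_idx = np.array([donor_pos[k] for _, k in stacked.index])
        y = stacked.to_numpy(dtype=float)
        w = np.ones_like(y)
    else:
        df = data.frame
        dose_values = data.doses
        dose_pos = {d: i for i, d in enumerate(dose_values)}
        donor_pos = {k: i for i, k in enumerate(donors)}
        dose_idx = df["dose_gy"].map(dose_pos).to_numpy()
        donor_idx = df["donor"].map(donor_pos).to_numpy()
        y = df["intensity"].to_numpy(dtype=float)
        w = np.ones_like(y)

    args = (donors, dose_idx, donor_idx, dose_values, y, w)
    method = "lm" if len(y) >= len(x0) else "trf"
    res = least_squares(
        lambda x: _residuals_and_jac(x, *args)[0],
        x0,
        jac=lambda x: _residuals_and_jac(x, *args)[1],
        method=method,
        ftol=ftol,
        gtol=gtol,
        xtol=xtol,
        max_nfev=max_iter * len(x0),
    )

    B, per_donor = _unpack(res.x, donors)
    ss_err = evaluate_objective(B, per_donor, means)
    grand = float(np.nanmean(means.to_numpy()))
    ss_tot = float(np.nansum((means.to_numpy() - grand) ** 2))
    r2 = 1.0 - ss_err / ss_tot if ss_tot > 0 else np.nan

    flags = []
    if not (0.0 <= B < 1.0):
        flags.append("B outside [0, 1)")
    for k, p in per_donor.items():
        if p.P0 > 1.0:
            flags.append(f"P0[{k}] > 1")
        if p.P0 < B:
            flags.append(f"P0[{k}] < B")
        if p.beta < 0.0:
            flags.append(f"beta[{k}] < 0")

    return JointFitResult(
        B=B,
        per_donor=per_donor,
        ss_err=ss_err,
        ss_tot=ss_tot,
        r_squared=r2,
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
        message=str(res.message),
        flags=tuple(flags),
    )


def r_squared(fit: JointFitResult, means: pd.DataFrame) -> float:
    """Coefficient of determination ``1 - SS_err / SS_tot`` of a fit
    against a replicate-mean table.  Raises when the means carry no
    variance (``SS_tot = 0``)."""
    grand = float(np.nanmean(means.to_numpy()))
    ss_tot = float(np.nansum((means.to_numpy() - grand) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("SS_tot = 0: all replicate means identical")
    ss_err = evaluate_objective(fit.B, fit.per_donor, means)
    return 1.0 - ss_err / ss_tot


@dataclass(frozen=True)
class BootstrapSummary:
    """Point estimates with percentile confidence intervals.

    ``per_parameter`` maps ``"B"``, ``"P0[<donor>]"`` and
    ``"beta[<donor>]"`` to ``(point_estimate, ci_low, ci_high)``.  The
    point estimate is the fit on the original data, not the bootstrap
    mean.  ``n_failed`` counts bootstrap replicates whose refit did not
    converge; they are excluded from the percentiles.
    """

    n_samples: int
    level: float
    per_parameter: dict[str, tuple[float, float, float]]
    seed: int | None
    n_failed: int = 0
    draws: pd.DataFrame | None = field(default=None, repr=False, compare=False)


def bootstrap_ci(
    data: IntensityDataset,
    n_samples: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    fit: JointFitResult | None = None,
    keep_draws: bool = False,
) -> BootstrapSummary:
    """Within-cell bootstrap confidence intervals for all fit parameters.

    Each bootstrap replicate redraws, for every (dose, donor) cell, the
    same number of intensities from that cell's observed replicates with
    replacement, and repeats the joint fit (warm-started at the original
    estimate).  Percentile intervals at ``level`` are taken over the
    converged replicates.  Reproducible for a fixed ``seed``.
    """
    if n_samples < 1:
        raise DataValidationError("n_samples must be >= 1")
    if not (0.0 < level < 1.0):
        raise DataValidationError("level must lie in (0, 1)")
    if fit is None:
        fit = fit_joint(data)
    donors = data.donors
    means = replicate_means(data)
    dose_values = means.index.to_numpy(dtype=float)

    # replicate values per populated (dose, donor) cell
    groups = data.frame.groupby(["dose_gy", "donor"], sort=True)["intensity"]
    cells = [
        ((float(d), str(k)), vals.to_numpy(dtype=float))
        for (d, k), vals in groups
    ]
    rng = np.random.default_rng(seed)

    dose_pos = {d: i for i, d in enumerate(dose_values)}
    donor_pos = {k: i for i, k in enumerate(donors)}
    dose_idx = np.array([dose_pos[d] for (d, _), _ in cells])
    donor_idx = np.array([donor_pos[k] for (_, k), _ in cells])

    # resampled cell means for all bootstrap replicates, one cell at a time
    boot_means = np.empty((n_samples, len(cells)))
    for c, (_, vals) in enumerate(cells):
        L = len(vals)
        idx = rng.integers(0, L, size=(n_samples, L))
        boot_means[:, c] = vals[idx].mean(axis=1)

    x_warm = _pack(fit.B, donors, fit.per_donor)
    w = np.ones(len(cells))
    draws = np.empty((n_samples, len(x_warm)))
    failed = np.zeros(n_samples, dtype=bool)
    for b in range(n_samples):
        args = (donors, dose_idx, donor_idx, dose_values, boot_means[b], w)
        res = least_squares(
            lambda x: _residuals_and_jac(x, *args)[0],
            x_warm,
            jac=lambda x: _residuals_and_jac(x, *args)[1],
            method="lm" if len(cells) >= len(x_warm) else "trf",
            ftol=1e-12,
            gtol=1e-10,
            xtol=1e-12,
        )
        draws[b] = res.x
        failed[b] = res.status <= 0
    if failed.any():
        warnings.warn(
            f"{int(failed.sum())} of {n_samples} bootstrap refits did not "
            "converge and were excluded from the percentiles",
            stacklevel=2,
        )
    good = draws[~failed]
    if len(good) == 0:
        raise DegenerateDataError("no bootstrap replicate converged")

    names = (
        ["B"]
        + [f"P0[{k}]" for k in donors]
        + [f"beta[{k}]" for k in donors]
    )
    points = _pack(fit.B, donors, fit.per_donor)
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(good, 100 * alpha, axis=0)
    hi = np.percentile(good, 100 * (1 - alpha), axis=0)
    per_parameter = {
        name: (float(points[i]), float(lo[i]), float(hi[i]))
        for i, name in enumerate(names)
    }
    return BootstrapSummary(
        n_samples=n_samples,
        level=level,
        per_parameter=per_parameter,
        seed=seed,
        n_failed=int(failed.sum()),
        draws=pd.DataFrame(good, columns=names) if keep_draws else None,
    )
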