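"""Closed-form model of alkaline DNA unwinding and fluorescence readout.

The alkaline-unwinding (FADU) assay denatures DNA bidirectionally from
every strand break and chromosome end for a fixed time; a dye then reports
the length of DNA that is still double stranded.  With all chromosomes
concatenated onto the unit interval, a cell with ``m`` internal breaks at
positions ``0 < z_1 <= ... <= z_m < 1`` and relative unwinding distance
``mu`` retains a double-stranded fraction

    L = sum_k max(gap_k - 2*mu, 0)

over the ``m + 1`` gaps between consecutive break points (boundary points
``z_0 = 0`` and ``z_{m+1} = 1`` included).  Overlapping unwinding regions
from neighbouring breaks interfere, which makes the unwound length
sub-additive in the break count.

For breaks placed i.i.d. uniformly, the gaps are distributed like the
minimum-free spacings of a uniform sample, and the conditional expectation
has the closed form ``E(L | m) = (1 - 2*mu)^(m+1)`` (zero once
``2*mu >= 1``).  Treating break number as a baseline count ``D0`` plus a
radiation-induced count ``gamma * d`` proportional to the X-ray dose ``d``
gives the effective-parameter intensity model and its phenomenological
exponential form

    P(d) = B + (P0 - B) * exp(-beta * d),

where ``B`` is the background fluorescence after complete unwinding.  The
module also provides the exact inversions from intensity back to an
equivalent dose and to a total dose-equivalent damage ``D_tot``.

All quantities are dimensionless except dose (Gy) and ``beta``/``gamma``
(Gy^-1).  This module is pure computation; it performs no I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, ModelDomainError

__all__ = [
    "UnwindingConfig",
    "EffectiveParams",
    "ExpFitParams",
    "relative_ds_length",
    "expected_ds_length_conditional",
    "expected_ds_length",
    "intensity_from_effective",
    "exp_form_from_effective",
    "intensity_exp_form",
    "equivalent_dose",
    "dose_equivalent_total",
]


@dataclass(frozen=True)
class UnwindingConfig:
    """Break positions and unwinding distance for a single cell.

    Parameters
    ----------
    breaks
        Internal break positions on the concatenated genome, expressed as
        relative coordinates strictly inside (0, 1), in nondecreasing
        order.  Ties are allowed: a zero-length gap simply contributes
        nothing to the double-stranded length.
    mu
        Relative unwinding distance (fraction of total DNA length) opened
        to each side of every break; must be nonnegative.
    """

    breaks: tuple[float, ...]
    mu: float

    def __init__(self, breaks: Sequence[float], mu: float):
        breaks = tuple(float(b) for b in breaks)
        mu = float(mu)
        for b in breaks:
            if not (0.0 < b < 1.0):
                raise ConfigurationError(
                    f"break position {b!r} outside the open unit interval"
                )
        if any(b2 < b1 for b1, b2 in zip(breaks, breaks[1:])):
            raise ConfigurationError("break positions must be nondecreasing")
        if not (mu >= 0.0):
            raise ConfigurationError(f"unwinding distance mu={mu!r} must be >= 0")
        object.__setattr__(self, "breaks", breaks)
        object.__setattr__(self, "mu", mu)


@dataclass(frozen=True)
class EffectiveParams:
    """Mechanistic parameters of the effective-value intensity model.

    Attributes
    ----------
    d0_eff
        Effective number of breaks at zero dose (> 0).  Includes the
        chromosome-end pseudo-breaks created by concatenating the
        chromosomes, so for human cells it is at least the chromosome
        count; it need not be an integer.
    gamma_eff
        Radiation-induced breaks per unit dose (Gy^-1, >= 0).
    mu_eff
        Effective relative unwinding distance (>= 0).
    B
        Relative background fluorescence after complete unwinding,
        in [0, 1).
    """

    d0_eff: float
    gamma_eff: float
    mu_eff: float
    B: float = 0.0

    def __post_init__(self):
        if not (self.d0_eff > 0 and math.isfinite(self.d0_eff)):
            raise ConfigurationError("d0_eff must be finite and > 0")
        if not (self.gamma_eff >= 0 and math.isfinite(self.gamma_eff)):
            raise ConfigurationError("gamma_eff must be finite and >= 0")
        if not (self.mu_eff >= 0 and math.isfinite(self.mu_eff)):
            raise ConfigurationError("mu_eff must be finite and >= 0")
        if not (0.0 <= self.B < 1.0):
            raise ConfigurationError("background B must lie in [0, 1)")


@dataclass(frozen=True)
class ExpFitParams:
    """Phenomenological parameters of the exponential dose response
    ``P(d) = B + (P0 - B) exp(-beta d)``.

    ``B`` is the shared background in [0, 1), ``P0`` the zero-dose relative
    intensity with ``B <= P0 <= 1``, and ``beta >= 0`` the per-Gy decay
    rate.
    """

    B: float
    P0: float
    beta: float

    def __post_init__(self):
        if not (0.0 <= self.B < 1.0):
            raise ConfigurationError("background B must lie in [0, 1)")
        if not (self.B <= self.P0 <= 1.0):
            raise ConfigurationError("P0 must satisfy B <= P0 <= 1")
        if not (self.beta >= 0.0 and math.isfinite(self.beta)):
            raise ConfigurationError("beta must be finite and >= 0")


def relative_ds_length(config: UnwindingConfig) -> float:
    """Relative double-stranded length remaining after unwinding.

    Evaluates ``sum_k max(gap_k - 2 mu, 0)`` over the gaps between
    consecutive break points, with the interval boundaries 0 and 1 treated
    as additional break points (the chromosome-concatenation convention).

    Returns a fraction in [0, 1]: exactly 1 when ``mu`` is 0 and exactly 0
    once every gap is at most ``2 mu``.
    """
    z = np.concatenate(([0.0], np.asarray(config.breaks, dtype=float), [1.0]))
    gaps = np.diff(z)
    return float(np.maximum(gaps - 2.0 * config.mu, 0.0).sum())


def expected_ds_length_conditional(m: int, mu: float) -> float:
    """Expected double-stranded fraction given exactly ``m`` uniform breaks.

    For ``m`` break points placed i.i.d. uniformly on (0, 1) the spacings
    are exchangeable with density ``m (1 - x)^(m-1)``, and each of the
    ``m + 1`` gaps contributes ``(1 - 2 mu)^(m+1) / (m + 1)`` in
    expectation, giving

        E(L | m) = (1 - 2 mu)^(m + 1)   if 2 mu < 1, else 0.

    ``m`` must be a nonnegative integer (the order-statistics derivation
    does not extend to fractional counts; see :func:`expected_ds_length`
    for the effective-value generalisation).
    """
    if m != int(m) or m < 0:
        raise ConfigurationError(f"break count m={m!r} must be a nonnegative integer")
    if not (mu >= 0.0):
        raise ConfigurationError(f"mu={mu!r} must be >= 0")
    if 2.0 * mu >= 1.0:
        return 0.0
    return float((1.0 - 2.0 * mu) ** (int(m) + 1))


def expected_ds_length(params: EffectiveParams, dose: float) -> float:
    """Expected double-stranded fraction at dose ``d`` (Gy) under the
    effective-value approximation ``(1 - 2 mu_eff)^(D0_eff + gamma_eff d)``.

    The exponent may be non-integer: ``D0_eff`` and ``gamma_eff d`` are
    effective (population-averaged) counts, not per-cell integers.
    """
    if dose < 0:
        raise ModelDomainError(f"dose {dose!r} must be >= 0")
    if params.mu_eff == 0.0:
        return 1.0
    base = 1.0 - 2.0 * params.mu_eff
    if base <= 0.0:
        return 0.0
    return float(base ** (params.d0_eff + params.gamma_eff * dose))


def intensity_from_effective(params: EffectiveParams, dose: float) -> float:
    """Relative fluorescence intensity ``B + (1 - B) E(L)`` at dose ``d``."""
    return params.B + (1.0 - params.B) * expected_ds_length(params, dose)


def exp_form_from_effective(params: EffectiveParams) -> ExpFitParams:
    """Reparameterise the mechanistic model into its exponential form.

    Returns ``P0 = B + (1 - B)(1 - 2 mu_eff)^D0_eff`` and
    ``beta = -gamma_eff ln(1 - 2 mu_eff)``; the exponential form then
    reproduces :func:`intensity_from_effective` exactly at every dose.

    The ``mu_eff = 0`` limit returns ``(P0, beta) = (1, 0)`` (no
    unwinding), preserving continuity.  ``2 mu_eff >= 1`` is rejected:
    the decay rate would be infinite.
    """
    if params.mu_eff == 0.0:
        return ExpFitParams(B=params.B, P0=1.0, beta=0.0)
    base = 1.0 - 2.0 * params.mu_eff
    if base <= 0.0:
        raise ModelDomainError(
            "2*mu_eff >= 1: intensity is flat at background, beta undefined"
        )
    P0 = params.B + (1.0 - params.B) * base ** params.d0_eff
    beta = -params.gamma_eff * math.log(base)
    return ExpFitParams(B=params.B, P0=P0, beta=beta)


def intensity_exp_form(fit: ExpFitParams, dose):
    """Exponential dose response ``P(d) = B + (P0 - B) exp(-beta d)``.

    Accepts a scalar dose or an array of doses (Gy); the return type
    matches.  Monotone nonincreasing in ``d`` with ``P(0) = P0`` and limit
    ``B`` as ``d -> inf``.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ModelDomainError("dose must be >= 0")
    out = fit.B + (fit.P0 - fit.B) * np.exp(-fit.beta * d)
    return float(out) if np.isscalar(dose) or d.ndim == 0 else out


_REL_TOL = 1e-12  # slack for P <= P0 / P <= 1 domain checks


def equivalent_dose(P: float, fit: ExpFitParams) -> float:
    """Dose (Gy) whose model intensity equals ``P``; exact inverse of
    :func:`intensity_exp_form`.

    Requires ``B < P <= P0`` and ``beta > 0``.  Out-of-range intensities
    raise :class:`ModelDomainError` rather than being clamped — a clamped
    value would fabricate a dose.
    """
    if fit.beta == 0.0:
        raise ModelDomainError("beta = 0: intensity is dose-independent")
    if P <= fit.B:
        raise ModelDomainError(f"intensity {P!r} at or below background {fit.B!r}")
    if P > fit.P0 * (1.0 + _REL_TOL) + _REL_TOL:
        raise ModelDomainError(f"intensity {P!r} above zero-dose intensity {fit.P0!r}")
    ratio = min((P - fit.B) / (fit.P0 - fit.B), 1.0)
    return -math.log(ratio) / fit.beta


def dose_equivalent_total(P: float, B: float, beta: float) -> float:
    """Total damage ``D_tot = -(1/beta) ln((P - B)/(1 - B))`` in units of
    the inverse unwinding distance.

    ``D_tot`` expresses baseline plus induced breaks,
    ``(D0_eff + gamma_eff d) * mu_eff``, rescaled so it is computable from
    ``(B, beta)`` alone without separating ``gamma_eff`` from ``mu_eff``.
    It is strictly decreasing in ``P``, zero at ``P = 1``, and satisfies
    ``D_tot(P(d)) = D_tot(P0) + d``.

    Requires ``B < P <= 1`` and ``beta > 0``.
    """
    if beta <= 0.0:
        raise ModelDomainError("beta must be > 0")
    if not (0.0 <= B < 1.0):
        raise ModelDomainError("background B must lie in [0, 1)")
    if P <= B:
        raise ModelDomainError(f"intensity {P!r} at or below background {B!r}")
    if P > 1.0 + _REL_TOL:
        raise ModelDomainError(f"intensity {P!r} above 1")
    ratio = min((P - B) / (1.0 - B), 1.0)
    return -math.log(ratio) / beta
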