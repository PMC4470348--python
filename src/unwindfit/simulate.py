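"""Monte Carlo simulation of a cell population in the unwinding assay.

Serves as the brute-force oracle for the closed forms in
:mod:`unwindfit.model`: each simulated cell draws its own baseline break
count, radiation susceptibility and unwinding distance, places its internal
breaks i.i.d. uniformly on the concatenated genome, and contributes a
fluorescence signal ``F_i = c (B (1 - L_i) + L_i)``.  Normalising the total
fluorescence by its no-unwinding value ``N c`` gives the relative intensity

    I = B + (1 - B) * mean(L_i),

which converges to the effective-parameter closed form as the population
grows (exactly, when the per-cell parameters are point masses).  With
dispersed parameter distributions the simulated intensity deviates from the
closed form evaluated at the mean parameters; the simulator exists
precisely to let that approximation error be measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .exceptions import ConfigurationError
from .model import EffectiveParams, intensity_from_effective  # noqa: F401  (oracle pair)

__all__ = [
    "ParamDist",
    "PopulationSpec",
    "SimulationResult",
    "simulate_population",
    "empirical_conditional_expectation",
]

DistSpec = Union[float, int, Mapping[str, float], "ParamDist"]


@dataclass(frozen=True)
class ParamDist:
    """A per-cell parameter distribution, declared by name and parameters.

    Supported kinds: ``point(value)``, ``normal(mean, sd)`` (truncated at
    zero by clipping), ``lognormal(mean_log, sd_log)``, ``gamma(shape,
    scale)``, ``uniform(low, high)``.  Declarative specs keep simulation
    configs serialisable and runs reproducible.
    """

    kind: str
    params: tuple[float, ...]

    _ARITY = {"point": 1, "normal": 2, "lognormal": 2, "gamma": 2, "uniform": 2}

    @classmethod
    def from_spec(cls, spec: DistSpec) -> "ParamDist":
        """Coerce a bare number (point mass) or a mapping like
        ``{"dist": "normal", "mean": 2, "sd": 0.1}`` into a ParamDist."""
        if isinstance(spec, ParamDist):
            return spec
        if isinstance(spec, (int, float)):
            return cls("point", (float(spec),))
        if isinstance(spec, Mapping):
            d = dict(spec)
            kind = d.pop("dist", None)
            if kind not in cls._ARITY:
                raise ConfigurationError(f"unknown distribution kind {kind!r}")
            order = {
                "point": ("value",),
                "normal": ("mean", "sd"),
                "lognormal": ("mean_log", "sd_log"),
                "gamma": ("shape", "scale"),
                "uniform": ("low", "high"),
            }[kind]
            try:
                params = tuple(float(d.pop(key)) for key in order)
            except KeyError as exc:
                raise ConfigurationError(
                    f"distribution {kind!r} missing parameter {exc.args[0]!r}"
                ) from None
            if d:
                raise ConfigurationError(
                    f"unexpected keys {sorted(d)} for distribution {kind!r}"
                )
            return cls(kind, params)
        raise ConfigurationError(f"cannot interpret distribution spec {spec!r}")

    def __post_init__(self):
        if self.kind not in self._ARITY:
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        if len(self.params) != self._ARITY[self.kind]:
            raise ConfigurationError(
                f"{self.kind!r} takes {self._ARITY[self.kind]} parameters"
            )
        if self.kind == "point" and self.params[0] < 0:
            raise ConfigurationError("point mass must be nonnegative")
        if self.kind == "uniform" and not (0 <= self.params[0] <= self.params[1]):
            raise ConfigurationError("uniform bounds must satisfy 0 <= low <= high")
        if self.kind in ("normal",) and self.params[1] < 0:
            raise ConfigurationError("sd must be >= 0")
        if self.kind == "gamma" and (self.params[0] <= 0 or self.params[1] <= 0):
            raise ConfigurationError("gamma shape and scale must be > 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.params[0])
        if self.kind == "normal":
            # truncate at zero: per-cell counts/distances cannot be negative
            return np.clip(rng.normal(*self.params, size=size), 0.0, None)
        if self.kind == "lognormal":
            return rng.lognormal(*self.params, size=size)
        if self.kind == "gamma":
            return rng.gamma(*self.params, size=size)
        if self.kind == "uniform":
            return rng.uniform(*self.params, size=size)
        raise AssertionError(self.kind)

    @property
    def is_point(self) -> bool:
        return self.kind == "point"


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a simulated cell population.

    ``d0_dist``, ``gamma_dist`` and ``mu_dist`` give the per-cell baseline
    break count, induced breaks per Gy and relative unwinding distance;
    each may be a bare number (point mass) or a named distribution.
    ``break_count_model`` maps ``(D0, gamma, d)`` to a total break count
    (breaks plus chromosome-end pseudo-breaks): ``"round"`` uses the
    deterministic ``round(D0 + gamma d)``, ``"poisson"`` draws
    ``round(D0) + Poisson(gamma d)``.  Either way at least one break point
    is kept, so the genome always has a start.
    """

    n_cells: int
    B: float
    d0_dist: DistSpec
    gamma_dist: DistSpec
    mu_dist: DistSpec
    c: float = 1.0
    break_count_model: str = "round"
    seed: int | None = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if not (0.0 <= self.B < 1.0):
            raise ConfigurationError("background B must lie in [0, 1)")
        if self.c <= 0:
            raise ConfigurationError("fluorescence scale c must be > 0")
        if self.break_count_model not in ("round", "poisson"):
            raise ConfigurationError(
                f"unknown break_count_model {self.break_count_model!r}"
            )
        for name in ("d0_dist", "gamma_dist", "mu_dist"):
            object.__setattr__(
                self, name, ParamDist.from_spec(getattr(self, name))
            )


@dataclass(frozen=True)
class SimulationResult:
    """Mean relative intensity with its Monte Carlo standard error."""

    mean_intensity: float
    se_intensity: float
    per_cell_lengths: np.ndarray | None = None


def _ds_lengths_uniform(rng: np.random.Generator, m: int, mu: np.ndarray) -> np.ndarray:
    """Vectorised double-stranded lengths for ``len(mu)`` cells, each with
    ``m`` i.i.d. uniform internal breaks and its own unwinding distance."""
    n = len(mu)
    if m == 0:
        return np.maximum(1.0 - 2.0 * mu, 0.0)
    z = np.sort(rng.random((n, m)), axis=1)
    gaps = np.diff(z, axis=1, prepend=0.0, append=1.0)
    return np.maximum(gaps - 2.0 * mu[:, None], 0.0).sum(axis=1)


def simulate_population(
    spec: PopulationSpec, dose: float, keep_lengths: bool = False
) -> SimulationResult:
    """Simulate the assay readout of a whole population at one dose.

    Per cell: draw ``(D0, gamma, mu)``, derive the total break count,
    scatter the internal breaks uniformly, evaluate the double-stranded
    length, and average into ``I = B + (1 - B) mean(L)``.  Reproducible
    for a fixed ``spec.seed``.
    """
    if dose < 0:
        raise ConfigurationError("dose must be >= 0")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    d0 = spec.d0_dist.sample(rng, n)
    gamma = spec.gamma_dist.sample(rng, n)
    mu = spec.mu_dist.sample(rng, n)

    if spec.break_count_model == "round":
        total = np.rint(d0 + gamma * dose).astype(np.int64)
    else:
        total = np.rint(d0).astype(np.int64) + rng.poisson(gamma * dose)
    total = np.maximum(total, 1)

    lengths = np.empty(n)
    for m in np.unique(total - 1):  # internal break count per cell
        mask = total - 1 == m
        lengths[mask] = _ds_lengths_uniform(rng, int(m), mu[mask])

    mean_L = float(lengths.mean())
    se_L = float(lengths.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return SimulationResult(
        mean_intensity=spec.B + (1.0 - spec.B) * mean_L,
        se_intensity=(1.0 - spec.B) * se_L,
        per_cell_lengths=lengths if keep_lengths else None,
    )


def empirical_conditional_expectation(
    m: int, mu: float, n_rep: int, seed: int | None = None
) -> tuple[float, float]:
    """Monte Carlo estimate of ``E(L | m)`` with its standard error.

    Averages the double-stranded length over ``n_rep`` independent
    configurations with ``m`` uniform internal breaks; the closed form it
    cross-checks is ``(1 - 2 mu)^(m + 1)``.  Deterministic (zero standard
    error) when ``m = 0``.
    """
    if m < 0 or m != int(m):
        raise ConfigurationError("m must be a nonnegative integer")
    if n_rep < 1:
        raise ConfigurationError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = _ds_lengths_uniform(rng, int(m), np.full(n_rep, float(mu)))
    mean = float(lengths.mean())
    se = float(lengths.std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0
    return mean, se
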