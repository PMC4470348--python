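"""Synthetic intensity datasets with the statistical design of the assay.

The defaults reproduce the design of the calibration experiment the model
was developed on: peripheral blood mononuclear cells from 11 healthy
donors, irradiated at 0, 0.3, 1, 1.9, 3.8, 7.5 and 14.9 Gy, three
independent replicates per (dose, donor) cell, a shared background
``B = 0.122`` and per-donor ``(P0, beta)`` from the published parameter
table.  Intensities follow the exponential dose response with additive
homoscedastic Gaussian noise — the simplest error model consistent with
triplicate fluorescence readouts — and are floored at a small positive
constant so that downstream validation (intensities strictly positive)
always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .fitting import COLUMNS, DonorCurve, IntensityDataset

__all__ = [
    "GeneratorSpec",
    "generate_dataset",
    "DEFAULT_DOSES_GY",
    "DEFAULT_BACKGROUND",
    "DEFAULT_DONOR_PARAMS",
    "DEFAULT_NOISE_SD",
]

#: X-ray dose grid of the reference experiment (Gy), including the
#: unirradiated point.
DEFAULT_DOSES_GY: tuple[float, ...] = (0.0, 0.3, 1.0, 1.9, 3.8, 7.5, 14.9)

#: Shared background fluorescence of the reference fit.
DEFAULT_BACKGROUND: float = 0.122

#: Reference per-donor (P0, beta) parameters for the 11 donors.
DEFAULT_DONOR_PARAMS: dict[str, DonorCurve] = {
    "1": DonorCurve(0.79, 0.18),
    "2": DonorCurve(0.74, 0.24),
    "3": DonorCurve(0.64, 0.21),
    "4": DonorCurve(0.65, 0.21),
    "5": DonorCurve(0.51, 0.20),
    "6": DonorCurve(0.65, 0.20),
    "7": DonorCurve(0.60, 0.30),
    "8": DonorCurve(0.63, 0.25),
    "9": DonorCurve(0.66, 0.31),
    "10": DonorCurve(0.74, 0.28),
    "11": DonorCurve(0.66, 0.18),
}

#: Default replicate noise standard deviation.  The instrument noise is
#: not published; this value makes bootstrap CI widths comparable to the
#: reference table's uncertainties.
DEFAULT_NOISE_SD: float = 0.005

_INTENSITY_FLOOR = 1e-6


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a synthetic triplicate intensity experiment."""

    B: float = DEFAULT_BACKGROUND
    donor_params: Mapping[str, DonorCurve] = field(
        default_factory=lambda: dict(DEFAULT_DONOR_PARAMS)
    )
    doses: tuple[float, ...] = DEFAULT_DOSES_GY
    n_replicates: int = 3
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.B < 1.0):
            raise ConfigurationError("background B must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        doses = tuple(float(d) for d in self.doses)
        if len(set(doses)) != len(doses) or any(d < 0 for d in doses):
            raise ConfigurationError("doses must be distinct and >= 0")
        params = {str(k): DonorCurve(*v) for k, v in self.donor_params.items()}
        if not params:
            raise ConfigurationError("at least one donor is required")
        for k, (P0, beta) in params.items():
            if not (self.B < P0 <= 1.0):
                raise ConfigurationError(f"donor {k}: P0 must satisfy B < P0 <= 1")
            if beta < 0:
                raise ConfigurationError(f"donor {k}: beta must be >= 0")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "donor_params", params)


def generate_dataset(spec: GeneratorSpec) -> IntensityDataset:
    """Draw one synthetic experiment from the generator specification.

    Each replicate intensity is the exponential model value
    ``B + (P0_k - B) exp(-beta_k d_j)`` plus i.i.d. Normal(0, noise_sd^2)
    noise, floored at ``1e-6``.  Identical seeds give identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for donor, (P0, beta) in spec.donor_params.items():
        for d in spec.doses:
            model = spec.B + (P0 - spec.B) * np.exp(-beta * d)
            noise = rng.normal(0.0, spec.noise_sd, size=spec.n_replicates)
            values = np.maximum(model + noise, _INTENSITY_FLOOR)
            for l, v in enumerate(values, start=1):
                rows.append((d, donor, l, float(v)))
    return IntensityDataset(pd.DataFrame(rows, columns=list(COLUMNS)))
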