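"""Synthetic (T, P) -> response datasets with the structure the analysis assumes.

The generator emulates the shape of supercritical-CO2 solubility data: a
full temperature x pressure grid, smooth nonlinear positive response
surfaces, and noise whose spread grows with the mean.  Default surface
signs follow the physics — solvent density falls with temperature and
rises with pressure, solubility rises with both — so monotone-trend checks
have a synthetic analogue with known ground truth.

Density is a polynomial in the standardized features plus additive or
multiplicative noise; solubility is the exponential of a linear-in-terms
log-mean surface times gamma multiplicative noise (mean 1, variance equal
to the dispersion), matching the distributional assumption of the gamma
base learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base_models import expand_polynomial_terms, polynomial_exponents
from .dataset_io import ExperimentalRecord, SolubilityDataset

#: graded-lex coefficients [1, zT, zP, zT^2, zT*zP, zP^2] on standardized (T, P)
DEFAULT_DENSITY_COEFFS = (630.0, -120.0, 150.0, 0.0, 25.0, -40.0)
#: log-mean coefficients [1, zT, zP]
DEFAULT_SOLUBILITY_LOG_COEFFS = (0.9, 0.9, 0.55)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-shaped generator: 4 temperatures x 8 pressures over the
    operating window of the experimental campaign, mild noise."""

    n_temps: int = 4
    n_pressures: int = 8
    t_range: tuple[float, float] = (313.0, 345.0)
    p_range: tuple[float, float] = (95.0, 250.0)
    density_coefficients: tuple[float, ...] = DEFAULT_DENSITY_COEFFS
    solubility_log_coefficients: tuple[float, ...] = DEFAULT_SOLUBILITY_LOG_COEFFS
    noise_model: str = "gaussian"
    dispersion: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_temps < 2 or self.n_pressures < 2:
            raise ValueError("grid sizes must be >= 2")
        if self.noise_model not in ("gaussian", "gamma"):
            raise ValueError("noise_model must be 'gaussian' or 'gamma'")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class GeneratedData:
    dataset: SolubilityDataset
    features: np.ndarray            # (n, 2) raw (T, P)
    density_surface: np.ndarray     # noiseless means, record order
    solubility_surface: np.ndarray


def _degree_for(n_coeffs: int) -> int:
    for degree in range(1, 13):
        if len(polynomial_exponents(degree)) == n_coeffs:
            return degree
    raise ValueError(f"coefficient count {n_coeffs} matches no full expansion")


def _gamma_factor(rng: np.random.Generator, dispersion: float, n: int) -> np.ndarray:
    if dispersion == 0:
        return np.ones(n)
    shape = 1.0 / dispersion
    return rng.gamma(shape, scale=dispersion, size=n)


def generate(spec: GeneratorSpec) -> GeneratedData:
    """Draw one dataset on the full grid; the noiseless surfaces come along
    for recovery tests."""
    t = np.linspace(*spec.t_range, spec.n_temps)
    p = np.linspace(*spec.p_range, spec.n_pressures)
    T, P = np.meshgrid(t, p, indexing="ij")
    X = np.column_stack([T.ravel(), P.ravel()])
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    dens_deg = _degree_for(len(spec.density_coefficients))
    density_mean = expand_polynomial_terms(Z, dens_deg) @ np.asarray(
        spec.density_coefficients, dtype=float
    )
    if np.any(density_mean <= 0):
        raise ValueError("density coefficients produce non-positive means")

    sol_deg = _degree_for(len(spec.solubility_log_coefficients))
    sol_mean = np.exp(
        expand_polynomial_terms(Z, sol_deg)
        @ np.asarray(spec.solubility_log_coefficients, dtype=float)
    )

    rng = np.random.default_rng(spec.seed)
    n = len(X)
    if spec.noise_model == "gaussian":
        density = density_mean + rng.normal(0.0, spec.dispersion, n) * density_mean
        density = np.maximum(density, 0.01 * density_mean)  # enforce positivity
    else:
        density = density_mean * _gamma_factor(rng, spec.dispersion, n)
    solubility = sol_mean * _gamma_factor(rng, spec.dispersion, n)

    records = [
        ExperimentalRecord(
            temperature=float(X[i, 0]),
            pressure=float(X[i, 1]),
            solubility=float(solubility[i]),
            co2_density=float(density[i]),
        )
        for i in range(n)
    ]
    return GeneratedData(
        dataset=SolubilityDataset(records=records),
        features=X,
        density_surface=density_mean,
        solubility_surface=sol_mean,
    )
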