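"""Loading, validation and serialization of solubility datasets.

A dataset is an ordered collection of experimental records, each holding a
temperature (K), a pressure (bar), a drug solubility reading and the CO2
density at those conditions.  The packaged fixture carries the 32-point
phenytoin / supercritical-CO2 dataset used throughout; foreign data in the
same schema load through :func:`load_dataset` with an optional column
mapping.

The CSV dialect is comma-separated with the header ``T_K,P_bar,y,co2_density``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_NAMES = ("temperature", "pressure")
TARGET_NAMES = ("solubility", "co2_density")

#: canonical CSV column for each record field
_CANONICAL_COLUMNS = {
    "temperature": "T_K",
    "pressure": "P_bar",
    "solubility": "y",
    "co2_density": "co2_density",
}

_FIXTURE_NAME = "phenytoin_scco2.csv"


class SchemaError(ValueError):
    """A required column is missing from the source table."""


class ValidationError(ValueError):
    """A cell violates a positivity or numeric invariant."""


@dataclass(frozen=True)
class ExperimentalRecord:
    """One (T, P, y, rho) observation.

    All four quantities are strictly positive: temperature is absolute (K),
    pressure is absolute (bar), solubility must be positive for relative
    deviation metrics and gamma regression, and density is a physical mass
    density (kg/m3 scale).
    """

    temperature: float
    pressure: float
    solubility: float
    co2_density: float

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "solubility", "co2_density"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"{name} must be finite and > 0, got {value!r}"
                )


@dataclass
class SolubilityDataset:
    """Ordered records plus a named target selection.

    ``target_name`` selects which response the pipeline models; switching
    it never mutates the records.
    """

    records: list[ExperimentalRecord]
    target_name: str = "solubility"
    feature_names: tuple[str, str] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.target_name not in TARGET_NAMES:
            raise ValueError(
                f"target_name must be one of {TARGET_NAMES}, got {self.target_name!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def features(self) -> np.ndarray:
        """(n, 2) array of (temperature, pressure) rows, in record order."""
        return np.array(
            [(r.temperature, r.pressure) for r in self.records], dtype=float
        )

    @property
    def targets(self) -> np.ndarray:
        """Selected response column, in record order."""
        return np.array(
            [getattr(r, self.target_name) for r in self.records], dtype=float
        )

    def with_target(self, target_name: str) -> "SolubilityDataset":
        """Same records, different response selection (no copy of records)."""
        return SolubilityDataset(records=self.records, target_name=target_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_K": [r.temperature for r in self.records],
                "P_bar": [r.pressure for r in self.records],
                "y": [r.solubility for r in self.records],
                "co2_density": [r.co2_density for r in self.records],
            }
        )


def _records_from_frame(
    df: pd.DataFrame, columns: Mapping[str, str]
) -> list[ExperimentalRecord]:
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing}; available: {list(df.columns)}"
        )
    records = []
    for i in range(len(df)):
        kwargs = {}
        for fname, col in columns.items():
            raw = df.iloc[i][col]
            value = pd.to_numeric(raw, errors="coerce")
            if pd.isna(value):
                raise ValidationError(
                    f"row {i}, column {col!r}: non-numeric value {raw!r}"
                )
            kwargs[fname] = float(value)
        try:
            records.append(ExperimentalRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def load_dataset(
    source: str | Path | pd.DataFrame,
    schema: Mapping[str, str] | None = None,
    target_name: str = "solubility",
) -> SolubilityDataset:
    """Load a (T, P, y, density) table into a validated dataset.

    Parameters
    ----------
    source
        CSV path or an already-parsed DataFrame.
    schema
        Optional mapping from record field names (``temperature``,
        ``pressure``, ``solubility``, ``co2_density``) to column names in
        the source; defaults to the canonical header.
    target_name
        Which response the returned dataset selects.

    Row order is preserved exactly; every cell is validated (numeric and
    strictly positive).
    """
    columns = dict(_CANONICAL_COLUMNS)
    if schema is not None:
        columns.update(schema)
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    records = _records_from_frame(df, columns)
    return SolubilityDataset(records=records, target_name=target_name)


def write_dataset(ds: SolubilityDataset, path: str | Path) -> None:
    """Write the canonical CSV dialect; round-trips with :func:`load_dataset`.

    Values are serialized with :func:`repr` precision so a load → write →
    load cycle reproduces the records exactly.
    """
    df = ds.to_frame()
    df.to_csv(path, index=False)


def load_phenytoin_dataset(target_name: str = "solubility") -> SolubilityDataset:
    """The packaged 32-record phenytoin / scCO2 dataset (4 temperatures x
    8 pressures, T in 313-345 K, P in 95-250 bar)."""
    with resources.as_file(
        resources.files("solubag.data").joinpath(_FIXTURE_NAME)
    ) as path:
        return load_dataset(path, target_name=target_name)


def correlation_matrix(ds: SolubilityDataset) -> pd.DataFrame:
    """Pearson correlation matrix over (T, P, y, density).

    Symmetric with unit diagonal; raises if any column has zero variance
    (self-correlation is then undefined).
    """
    df = ds.to_frame()
    if len(df) < 2:
        raise ValueError("correlation requires at least 2 records")
    stds = df.std(ddof=1)
    degenerate = stds[stds == 0].index.tolist()
    if degenerate:
        raise ValueError(f"zero-variance column(s): {degenerate}")
    return df.corr(method="pearson")
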