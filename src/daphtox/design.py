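"""Experimental design construction, covariate coding and tabular I/O.

The experiment crosses two urbanization classes (5 *Daphnia magna*
populations each, 5 clonal lineages per population) with a pesticide
treatment (solvent control vs. chlorpyrifos) and a temperature treatment
(20 °C vs. 24 °C), replicated twice: 2 × 5 × 5 × 2 × 2 × 2 = 400
experimental units, or 392 after fully excluding one clone. Each unit is
one jar of 5 (exceptionally 6) neonates scored for survival at 48 h.

All treatment variables enter the model with a signed half-unit coding
(−0.5 / +0.5) so that the intercept represents the average condition and
interaction columns are exact products of the main-effect codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "URBANIZATION_LEVELS",
    "TEMPERATURE_LEVELS",
    "PESTICIDE_LEVELS",
    "ExperimentalUnit",
    "CodedCovariates",
    "DesignSpec",
    "DesignError",
    "ValidationError",
    "build_design",
    "encode_unit",
    "validate_units",
    "read_dataset",
    "write_dataset",
    "units_to_frame",
    "frame_to_units",
]

URBANIZATION_LEVELS = ("rural", "urban")
TEMPERATURE_LEVELS = (20, 24)
PESTICIDE_LEVELS = ("control", "chlorpyrifos")

#: canonical CSV column order
COLUMNS = (
    "population_id",
    "clone_id",
    "urbanization",
    "temperature",
    "pesticide",
    "replicate",
    "n_start",
    "n_surviving",
)

#: signed half-unit codes, exactly as the model equation requires
_CODE = {
    "pesticide": {"control": -0.5, "chlorpyrifos": 0.5},
    "urbanization": {"rural": -0.5, "urban": 0.5},
    "temperature": {20: -0.5, 24: 0.5},
}


class DesignError(ValueError):
    """Raised for an inconsistent design specification."""


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant.

    Carries the offending 1-based data row numbers in ``rows`` when the
    violation is row-local.
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):  # noqa: D107
        super().__init__(message)
        self.rows = tuple(rows)


@dataclass(frozen=True)
class ExperimentalUnit:
    """One replicate jar: the binomial observation unit.

    ``n_surviving`` is ``None`` for a design that has not yet been run
    (or simulated).
    """

    population_id: str
    clone_id: str
    urbanization: str
    temperature: int
    pesticide: str
    replicate: int
    n_start: int = 5
    n_surviving: int | None = None

    def __post_init__(self) -> None:
        if self.urbanization not in URBANIZATION_LEVELS:
            raise ValidationError(
                f"urbanization must be one of {URBANIZATION_LEVELS}, got {self.urbanization!r}"
            )
        if self.temperature not in TEMPERATURE_LEVELS:
            raise ValidationError(
                f"temperature must be one of {TEMPERATURE_LEVELS}, got {self.temperature!r}"
            )
        if self.pesticide not in PESTICIDE_LEVELS:
            raise ValidationError(
                f"pesticide must be one of {PESTICIDE_LEVELS}, got {self.pesticide!r}"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.n_start < 1:
            raise ValidationError(f"n_start must be >= 1, got {self.n_start}")
        if self.n_surviving is not None and not (0 <= self.n_surviving <= self.n_start):
            raise ValidationError(
                f"n_surviving must satisfy 0 <= y <= n_start={self.n_start}, "
                f"got {self.n_surviving}"
            )

    def with_outcome(self, n_surviving: int) -> "ExperimentalUnit":
        return replace(self, n_surviving=int(n_surviving))


@dataclass(frozen=True)
class CodedCovariates:
    """Signed half-unit treatment codes and their interaction products."""

    cpf: float
    urb: float
    temp: float
    cpf_urb: float
    cpf_temp: float
    urb_temp: float
    cpf_urb_temp: float

    def as_row(self) -> tuple[float, ...]:
        """Design-matrix row including the leading intercept column."""
        return (
            1.0,
            self.cpf,
            self.urb,
            self.temp,
            self.cpf_urb,
            self.cpf_temp,
            self.urb_temp,
            self.cpf_urb_temp,
        )


@dataclass(frozen=True)
class DesignSpec:
    """Cardinalities and exclusions of the full-factorial design.

    Defaults reproduce the study layout: 5 populations per urbanization
    class, 5 clones per population, 2 replicates of the 2 × 2 treatment
    crossing. ``oversized_units`` are indices (in deterministic design
    order) of units started with 6 instead of 5 individuals.
    """

    n_populations_per_class: int = 5
    n_clones_per_population: int = 5
    n_replicates: int = 2
    excluded_clones: tuple[str, ...] = ()
    oversized_units: tuple[int, ...] = ()
    n_start: int = 5
    n_start_oversized: int = 6

    @classmethod
    def study(cls, n_oversized: int = 4) -> "DesignSpec":
        """The as-run layout: clone u2.5 excluded, 4 units with 6 neonates.

        The deposited record does not identify which four jars held six
        neonates, so the first ``n_oversized`` units in deterministic
        design order are designated (reproducibility over realism).
        """
        return cls(
            excluded_clones=("u2.5",),
            oversized_units=tuple(range(n_oversized)),
        )

    def population_ids(self) -> list[str]:
        return [
            f"{prefix}{p}"
            for prefix in ("r", "u")
            for p in range(1, self.n_populations_per_class + 1)
        ]

    def clone_ids(self, include_excluded: bool = False) -> list[str]:
        clones = [
            f"{pop}.{c}"
            for pop in self.population_ids()
            for c in range(1, self.n_clones_per_population + 1)
        ]
        if include_excluded:
            return clones
        return [c for c in clones if c not in set(self.excluded_clones)]


def build_design(spec: DesignSpec) -> list[ExperimentalUnit]:
    """Construct the ordered list of experimental units (outcomes absent).

    Deterministic ordering: population, clone, pesticide (control first),
    temperature (20 °C first), replicate. Excluded clones contribute no
    units; oversized unit indices refer to positions in this ordering.
    """
    if min(
        spec.n_populations_per_class, spec.n_clones_per_population, spec.n_replicates
    ) < 1:
        raise DesignError("design cardinalities must all be >= 1")
    all_clones = spec.clone_ids(include_excluded=True)
    if len(set(all_clones)) != len(all_clones):  # pragma: no cover - label scheme
        raise DesignError("duplicate clone label across populations")
    missing = set(spec.excluded_clones) - set(all_clones)
    if missing:
        raise DesignError(f"excluded clone(s) not found in design: {sorted(missing)}")

    excluded = set(spec.excluded_clones)
    units: list[ExperimentalUnit] = []
    for prefix, urbanization in zip(("r", "u"), URBANIZATION_LEVELS):
        for p in range(1, spec.n_populations_per_class + 1):
            pop = f"{prefix}{p}"
            for c in range(1, spec.n_clones_per_population + 1):
                clone = f"{pop}.{c}"
                if clone in excluded:
                    continue
                for pesticide in PESTICIDE_LEVELS:
                    for temperature in TEMPERATURE_LEVELS:
                        for rep in range(1, spec.n_replicates + 1):
                            units.append(
                                ExperimentalUnit(
                                    population_id=pop,
                                    clone_id=clone,
                                    urbanization=urbanization,
                                    temperature=temperature,
                                    pesticide=pesticide,
                                    replicate=rep,
                                )
                            )
    bad = [i for i in spec.oversized_units if not (0 <= i < len(units))]
    if bad:
        raise DesignError(f"oversized unit index out of range: {bad}")
    for i in spec.oversized_units:
        units[i] = replace(units[i], n_start=spec.n_start_oversized)
    if spec.n_start != 5:
        units = [
            u if i in set(spec.oversized_units) else replace(u, n_start=spec.n_start)
            for i, u in enumerate(units)
        ]
    return units


def encode_unit(unit: ExperimentalUnit) -> CodedCovariates:
    """Map a unit's treatment levels to signed half-unit codes.

    control → −0.5, chlorpyrifos → +0.5; rural → −0.5, urban → +0.5;
    20 °C → −0.5, 24 °C → +0.5. Interaction fields are the exact
    arithmetic products of the main-effect codes.
    """
    cpf = _CODE["pesticide"][unit.pesticide]
    urb = _CODE["urbanization"][unit.urbanization]
    temp = _CODE["temperature"][unit.temperature]
    return CodedCovariates(
        cpf=cpf,
        urb=urb,
        temp=temp,
        cpf_urb=cpf * urb,
        cpf_temp=cpf * temp,
        urb_temp=urb * temp,
        cpf_urb_temp=cpf * urb * temp,
    )


def validate_units(
    units: Sequence[ExperimentalUnit],
    n_start_allowed: tuple[int, ...] | None = (5, 6),
) -> None:
    """Check cross-unit invariants; raise :class:`ValidationError` on failure.

    ``n_start_allowed=None`` disables the jar-size bound for general use.
    """
    clone_map: dict[str, tuple[str, str]] = {}
    for i, u in enumerate(units, start=1):
        key = (u.population_id, u.urbanization)
        prev = clone_map.setdefault(u.clone_id, key)
        if prev != key:
            raise ValidationError(
                f"row {i}: clone {u.clone_id!r} maps to {key} but earlier to {prev}; "
                "clone ids must be nested within a single population",
                rows=[i],
            )
        if n_start_allowed is not None and u.n_start not in n_start_allowed:
            raise ValidationError(
                f"row {i}: n_start={u.n_start} outside allowed {n_start_allowed}",
                rows=[i],
            )


def units_to_frame(units: Sequence[ExperimentalUnit]) -> pd.DataFrame:
    df = pd.DataFrame([vars(u) for u in units], columns=list(COLUMNS))
    df["n_surviving"] = df["n_surviving"].astype("Int64")
    return df


def frame_to_units(df: pd.DataFrame) -> list[ExperimentalUnit]:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")
    units = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            y = getattr(row, "n_surviving")
            y = None if pd.isna(y) else _as_int(y, "n_surviving")
            units.append(
                ExperimentalUnit(
                    population_id=str(row.population_id),
                    clone_id=str(row.clone_id),
                    urbanization=str(row.urbanization),
                    temperature=_as_int(row.temperature, "temperature"),
                    pesticide=str(row.pesticide),
                    replicate=_as_int(row.replicate, "replicate"),
                    n_start=_as_int(row.n_start, "n_start"),
                    n_surviving=y,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}", rows=[i]) from exc
    return units


def _as_int(value, name: str) -> int:
    f = float(value)
    if f != int(f):
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    return int(f)


def write_dataset(units: Sequence[ExperimentalUnit], path: str | Path) -> None:
    """Write units as UTF-8 comma-separated text with a header row."""
    units_to_frame(units).to_csv(path, index=False)


def read_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
    n_start_allowed: tuple[int, ...] | None = (5, 6),
) -> list[ExperimentalUnit]:
    """Read and validate a replicate-level CSV dataset.

    ``column_map`` maps this package's canonical column names to the names
    used in the file (for ingesting externally deposited data whose header
    dialect differs); it may be given inline or as a YAML/JSON file path.
    """
    if column_map is not None and not isinstance(column_map, Mapping):
        column_map = _load_column_map(column_map)
    df = pd.read_csv(path)
    if column_map:
        unknown = [k for k in column_map if k not in COLUMNS]
        if unknown:
            raise ValidationError(f"column_map keys not in schema: {unknown}")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if "n_surviving" not in df.columns:
        df = df.assign(n_surviving=pd.NA)
    units = frame_to_units(df)
    validate_units(units, n_start_allowed=n_start_allowed)
    return units


def _load_column_map(path: str | Path) -> dict[str, str]:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return dict(json.loads(text))
    return dict(yaml.safe_load(text))
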