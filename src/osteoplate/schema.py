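"""Femoral parameter schema.

Twenty-eight named morphological parameters partitioned into proximal (9),
shaft (3) and distal (16) regions, plus the overall femur length ``H_f`` as a
standalone entry.  The proximal parameters are the PCA block ``X1..X9`` and
the distal parameters the block ``Y1..Y16``; the shaft block is carried
through unreduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParameterDef",
    "ParameterSchema",
    "FemurParameterSet",
    "CohortMatrix",
    "FEMUR_SCHEMA",
]


@dataclass(frozen=True)
class ParameterDef:
    name: str
    region: str          # "proximal" | "shaft" | "distal" | "global"
    unit: str            # "mm" | "degree" | "ratio"
    mean: float          # reference-cohort mean (100 adult right femurs)
    sd: float            # reference-cohort standard deviation


# Reference cohort: 100 right femurs of healthy Han Chinese adults
# (mean age 47 y); lengths in mm, angles in degrees.
_DEFS = [
    # proximal, order X1..X9
    ParameterDef("H_fh", "proximal", "mm", 47.95, 5.33),    # femoral head vertical height
    ParameterDef("A_fn", "proximal", "degree", 126.18, 6.12),  # collodiaphyseal angle
    ParameterDef("L_fhs", "proximal", "mm", 38.75, 6.25),   # eccentric distance
    ParameterDef("L_fn", "proximal", "mm", 50.80, 6.19),    # neck length
    ParameterDef("D_fh", "proximal", "mm", 43.33, 3.40),    # femoral head diameter
    ParameterDef("D_fn", "proximal", "mm", 33.08, 3.25),    # femoral neck diameter
    ParameterDef("L_t", "proximal", "mm", 65.86, 4.03),     # greater trochanter length
    ParameterDef("H_t1", "proximal", "mm", 10.73, 1.09),    # trochanter bump height
    ParameterDef("H_t2", "proximal", "mm", 17.57, 2.36),    # trochanter interior offset
    # shaft
    ParameterDef("D_fs", "shaft", "mm", 25.94, 2.23),       # shaft coronal diameter
    ParameterDef("H_fs", "shaft", "mm", 269.19, 16.64),     # shaft length
    ParameterDef("A_fs", "shaft", "degree", 173.39, 1.51),  # shaft bending angle
    # distal, order Y1..Y16
    ParameterDef("L_df", "distal", "mm", 75.10, 6.00),
    ParameterDef("L_m", "distal", "mm", 56.03, 3.74),
    ParameterDef("L_l", "distal", "mm", 59.95, 4.00),
    ParameterDef("L_a", "distal", "mm", 32.77, 2.53),
    ParameterDef("L_p", "distal", "mm", 52.06, 4.05),
    ParameterDef("H_m", "distal", "mm", 55.35, 3.71),
    ParameterDef("H_l", "distal", "mm", 59.73, 3.98),
    ParameterDef("A_m", "distal", "degree", 81.33, 1.87),
    ParameterDef("A_l", "distal", "degree", 85.60, 1.97),
    ParameterDef("A_a", "distal", "degree", 8.25, 2.85),
    ParameterDef("A_p", "distal", "degree", 4.13, 1.63),
    ParameterDef("A_s", "distal", "degree", 134.11, 4.19),
    ParameterDef("H_tg", "distal", "mm", 6.04, 0.75),
    ParameterDef("H_ml", "distal", "mm", 4.37, 0.51),
    ParameterDef("C_f", "distal", "ratio", 1.25, 0.09),
    ParameterDef("A_ml", "distal", "degree", 12.98, 2.86),
    # overall femur length (standalone; not part of either PCA block)
    ParameterDef("H_f", "global", "mm", 420.072, 22.968),
]


@dataclass(frozen=True)
class ParameterSchema:
    """Ordered femoral parameter definitions with region partition 9/3/16 (+H_f)."""

    entries: tuple[ParameterDef, ...] = field(default_factory=lambda: tuple(_DEFS))

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        counts = {r: sum(e.region == r for e in self.entries) for r in ("proximal", "shaft", "distal")}
        if counts != {"proximal": 9, "shaft": 3, "distal": 16}:
            raise ValueError(f"regions must partition as 9/3/16, got {counts}")

    def __iter__(self) -> Iterator[ParameterDef]:
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def region_names(self, region: str) -> list[str]:
        return [e.name for e in self.entries if e.region == region]

    def means(self, names: list[str] | None = None) -> np.ndarray:
        d = {e.name: e.mean for e in self.entries}
        return np.array([d[n] for n in (names or self.names)])

    def sds(self, names: list[str] | None = None) -> np.ndarray:
        d = {e.name: e.sd for e in self.entries}
        return np.array([d[n] for n in (names or self.names)])

    def __getitem__(self, name: str) -> ParameterDef:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


FEMUR_SCHEMA = ParameterSchema()


class FemurParameterSet(Mapping[str, float]):
    """Morphological parameter values for one subject, keyed by schema name."""

    def __init__(self, values: Mapping[str, float], schema: ParameterSchema = FEMUR_SCHEMA):
        self.schema = schema
        self._values = {n: float(values[n]) for n in schema.names if n in values}
        missing = set(schema.names) - set(self._values)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        for e in schema:
            if e.unit == "mm" and self._values[e.name] <= 0:
                raise ValueError(f"length parameter {e.name} must be positive")

    @classmethod
    def mean_shape(cls, schema: ParameterSchema = FEMUR_SCHEMA) -> "FemurParameterSet":
        return cls({e.name: e.mean for e in schema}, schema)

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def to_vector(self, names: list[str]) -> np.ndarray:
        return np.array([self._values[n] for n in names])

    def replace(self, **updates: float) -> "FemurParameterSet":
        vals = dict(self._values)
        vals.update(updates)
        return FemurParameterSet(vals, self.schema)


class CohortMatrix:
    """n_subjects x p_parameters value matrix bound to a schema.

    All statistical operations require complete data and n >= 3; length
    parameters must be strictly positive.
    """

    def __init__(
        self,
        values: np.ndarray | pd.DataFrame,
        columns: list[str] | None = None,
        schema: ParameterSchema = FEMUR_SCHEMA,
        subject_ids: list[str] | None = None,
        standardized: bool = False,
        means: np.ndarray | None = None,
        sds: np.ndarray | None = None,
    ):
        if isinstance(values, pd.DataFrame):
            columns = list(values.columns)
            self.values = values.to_numpy(dtype=float)
        else:
            self.values = np.asarray(values, dtype=float)
            if columns is None:
                raise ValueError("columns required when passing a bare array")
        if self.values.ndim != 2:
            raise ValueError("cohort values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cohort contains missing or non-finite values")
        unknown = [c for c in columns if c not in schema.names]
        if unknown:
            raise ValueError(f"columns not in schema: {unknown}")
        self.columns = list(columns)
        self.schema = schema
        self.subject_ids = subject_ids or [f"S{i:04d}" for i in range(self.values.shape[0])]
        self.standardized = standardized
        self.means = means   # set by standardize() for the inverse transform
        self.sds = sds
        if not standardized:
            for j, c in enumerate(self.columns):
                if schema[c].unit == "mm" and np.any(self.values[:, j] <= 0):
                    raise ValueError(f"length parameter {c} must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def select(self, names: list[str]) -> "CohortMatrix":
        idx = [self.columns.index(n) for n in names]
        return CohortMatrix(
            self.values[:, idx], names, self.schema, self.subject_ids,
            self.standardized,
            None if self.means is None else self.means[idx],
            None if self.sds is None else self.sds[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns, index=self.subject_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: ParameterSchema = FEMUR_SCHEMA) -> "CohortMatrix":
        return cls(pd.read_csv(path), schema=schema)
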