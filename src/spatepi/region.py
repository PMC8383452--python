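"""Areal data model: geographic areas, populations, covariates and case counts.

The analysis unit is a privacy-aggregated geographic area (GA) with a planar
centroid in km, a male population aged >= 35, ecological covariates, and one
observed prostate-cancer case count per clinical risk level.  All downstream
vectors and matrices share the fixed area ordering of :class:`StudyRegion`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The four clinical risk levels; every case belongs to exactly one.
RISK_LEVELS: tuple[str, ...] = ("metastatic", "high", "intermediate", "low")

#: Columns of the area-attribute CSV dialect, before the per-level count columns.
ATTRIBUTE_COLUMNS: tuple[str, ...] = (
    "area_id",
    "x_km",
    "y_km",
    "population",
    "phys_density",
    "remoteness",
)


class ValidationError(ValueError):
    """Raised when an input table violates the areal-data contract."""


@dataclass
class StudyRegion:
    """An ordered collection of geographic areas with per-risk-level counts.

    Parameters
    ----------
    areas:
        DataFrame with columns ``area_id, x_km, y_km, population,
        phys_density, remoteness``.  Row order is the canonical area order.
    counts:
        DataFrame indexed like ``areas`` with one non-negative integer column
        per risk level in :data:`RISK_LEVELS`.
    """

    areas: pd.DataFrame
    counts: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = pd.DataFrame(
                {lvl: np.zeros(len(self.areas), dtype=int) for lvl in RISK_LEVELS},
                index=self.areas.index,
            )
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in ATTRIBUTE_COLUMNS if c not in self.areas.columns]
        if missing:
            raise ValidationError(f"missing area columns: {missing}")
        ids = self.areas["area_id"].astype(str)
        dup = ids[ids.duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate area ids: {sorted(dup.unique())}")
        if (self.areas["population"] < 0).any():
            bad = self.areas.loc[self.areas["population"] < 0, "area_id"].tolist()
            raise ValidationError(f"negative population in areas {bad}")
        if (self.areas["phys_density"] < 0).any():
            bad = self.areas.loc[self.areas["phys_density"] < 0, "area_id"].tolist()
            raise ValidationError(f"negative physician density in areas {bad}")
        for lvl in RISK_LEVELS:
            if lvl not in self.counts.columns:
                raise ValidationError(f"missing count column for risk level '{lvl}'")
            col = self.counts[lvl]
            if not np.issubdtype(np.asarray(col).dtype, np.integer):
                as_float = np.asarray(col, dtype=float)
                if not np.all(as_float == np.round(as_float)):
                    raise ValidationError(f"non-integer counts in column '{lvl}'")
                self.counts[lvl] = as_float.astype(int)
            if (self.counts[lvl] < 0).any():
                raise ValidationError(f"negative counts in column '{lvl}'")
        if len(self.counts) != len(self.areas):
            raise ValidationError("counts and areas have different lengths")

    # -- accessors --------------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def area_ids(self) -> np.ndarray:
        return self.areas["area_id"].astype(str).to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of planar centroid coordinates in km."""
        return self.areas[["x_km", "y_km"]].to_numpy(dtype=float)

    @property
    def population(self) -> np.ndarray:
        return self.areas["population"].to_numpy(dtype=int)

    @property
    def phys_density(self) -> np.ndarray:
        return self.areas["phys_density"].to_numpy(dtype=float)

    @property
    def remoteness(self) -> np.ndarray:
        return self.areas["remoteness"].to_numpy(dtype=float)

    def observed(self, risk_level: str) -> np.ndarray:
        if risk_level not in RISK_LEVELS:
            raise ValidationError(
                f"unknown risk level '{risk_level}'; expected one of {RISK_LEVELS}"
            )
        return self.counts[risk_level].to_numpy(dtype=int)

    def populated_mask(self) -> np.ndarray:
        """Boolean mask of areas with population > 0 (SIR/clustering universe)."""
        return self.population > 0

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyRegion":
        df = pd.read_csv(path)
        missing = [c for c in ATTRIBUTE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns in {path}: {missing}")
        count_cols = [c for c in df.columns if c in RISK_LEVELS]
        missing_counts = [c for c in RISK_LEVELS if c not in count_cols]
        if missing_counts:
            raise ValidationError(f"missing count columns in {path}: {missing_counts}")
        areas = df[list(ATTRIBUTE_COLUMNS)].copy()
        counts = df[list(RISK_LEVELS)].copy()
        return cls(areas=areas, counts=counts)

    def to_csv(self, path: str | Path) -> None:
        out = self.areas.copy()
        for lvl in RISK_LEVELS:
            out[lvl] = self.counts[lvl].to_numpy()
        out.to_csv(path, index=False, float_format="%.6f")

    def to_frame(self) -> pd.DataFrame:
        out = self.areas.copy()
        for lvl in RISK_LEVELS:
            out[lvl] = self.counts[lvl].to_numpy()
        return out

    def centroid_geojson(self) -> dict:
        """Point-feature GeoJSON of area centroids (planar km coordinates)."""
        feats = []
        for _, row in self.to_frame().iterrows():
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(row["x_km"]), float(row["y_km"])],
                    },
                    "properties": {
                        "area_id": str(row["area_id"]),
                        "population": int(row["population"]),
                    },
                }
            )
        return {"type": "FeatureCollection", "features": feats}


def build_region(
    area_ids: Sequence[str],
    centroids: np.ndarray,
    population: Sequence[int],
    counts: Mapping[str, Iterable[int]] | None = None,
    phys_density: Sequence[float] | None = None,
    remoteness: Sequence[float] | None = None,
) -> StudyRegion:
    """Convenience constructor from plain arrays (used heavily in tests)."""
    n = len(area_ids)
    centroids = np.asarray(centroids, dtype=float).reshape(n, 2)
    areas = pd.DataFrame(
        {
            "area_id": [str(a) for a in area_ids],
            "x_km": centroids[:, 0],
            "y_km": centroids[:, 1],
            "population": np.asarray(population, dtype=int),
            "phys_density": np.zeros(n) if phys_density is None else np.asarray(phys_density, float),
            "remoteness": np.zeros(n) if remoteness is None else np.asarray(remoteness, float),
        }
    )
    cdf = None
    if counts is not None:
        cdf = pd.DataFrame({lvl: np.asarray(list(counts.get(lvl, np.zeros(n, int))), dtype=int) for lvl in RISK_LEVELS})
    return StudyRegion(areas=areas, counts=cdf)
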