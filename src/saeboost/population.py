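"""Core containers: the individual-level population table and the nested
region hierarchy.

A :class:`PopulationFrame` is a thin schema-aware wrapper around a pandas
DataFrame with one row per individual.  Mandatory columns are ``id``,
``region_nbhd``, ``region_district``, ``region_muni``, ``x_coord_m``,
``y_coord_m``, ``survey_flag`` and ``response``; every remaining column is a
predictive feature.  Missing entries are NaN (continuous) or pandas NA
(categorical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = (
    "id",
    "region_nbhd",
    "region_district",
    "region_muni",
    "x_coord_m",
    "y_coord_m",
    "survey_flag",
    "response",
)

#: Estimation level -> region-code column (``None`` = single national region).
LEVEL_COLUMNS = {
    "neighborhood": "region_nbhd",
    "district": "region_district",
    "municipality": "region_muni",
    "national": None,
}

NATIONAL_CODE = "NL"


def level_codes(frame: pd.DataFrame, level: str) -> pd.Series:
    """Region code per individual at ``level`` (constant for national)."""
    if level not in LEVEL_COLUMNS:
        raise KeyError(
            f"unknown level {level!r}; expected one of {sorted(LEVEL_COLUMNS)}"
        )
    col = LEVEL_COLUMNS[level]
    if col is None:
        return pd.Series(NATIONAL_CODE, index=frame.index, name="region")
    return frame[col]


@dataclass
class RegionHierarchy:
    """Nested partition of individuals into neighborhoods, districts and
    municipalities.

    Parameters
    ----------
    frame
        DataFrame with columns ``region_nbhd``, ``region_district``,
        ``region_muni``, one row per individual.
    tiles
        Optional per-neighborhood bounding boxes (columns ``region_nbhd``,
        ``x0``, ``x1``, ``y0``, ``y1``) used by the synthetic generator to
        place coordinates.
    """

    frame: pd.DataFrame
    tiles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [
            c
            for c in ("region_nbhd", "region_district", "region_muni")
            if c not in self.frame.columns
        ]
        if missing:
            raise ValueError(f"hierarchy frame lacks columns {missing}")

    @property
    def n_individuals(self) -> int:
        return len(self.frame)

    def codes(self, level: str) -> pd.Series:
        return level_codes(self.frame, level)

    def region_sizes(self, level: str) -> pd.Series:
        return self.codes(level).value_counts().sort_index()

    def parent_map(self, child_level: str, parent_level: str) -> pd.Series:
        """Unique parent region code per child region code."""
        child = self.codes(child_level)
        parent = self.codes(parent_level)
        table = pd.DataFrame({"child": child, "parent": parent}).drop_duplicates()
        counts = table.groupby("child")["parent"].nunique()
        bad = counts[counts > 1]
        if len(bad):
            raise ValueError(
                f"regions {list(bad.index)} at level {child_level!r} have "
                f"multiple parents at {parent_level!r}"
            )
        return table.set_index("child")["parent"]

    def validate(self) -> None:
        """Assert the partition and nesting invariants."""
        for level in ("neighborhood", "district", "municipality"):
            codes = self.codes(level)
            if codes.isna().any():
                raise ValueError(f"individuals without a {level} code")
        self.parent_map("neighborhood", "district")
        self.parent_map("district", "municipality")


@dataclass
class PopulationFrame:
    """One record per individual: region codes, coordinates, features,
    survey membership and (for respondents) the observed response."""

    data: pd.DataFrame
    feature_columns: list[str] = field(default_factory=list)
    categorical_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing column {missing[0]}")
        if not self.feature_columns:
            self.feature_columns = [
                c for c in self.data.columns if c not in MANDATORY_COLUMNS
            ]
        if not self.categorical_columns:
            self.categorical_columns = [
                c
                for c in self.feature_columns
                if not pd.api.types.is_numeric_dtype(self.data[c])
            ]
        flags = self.data["survey_flag"]
        if not flags.isin([0, 1]).all():
            raise ValueError("survey_flag values outside {0,1}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def survey_mask(self) -> np.ndarray:
        return self.data["survey_flag"].to_numpy() == 1

    @property
    def n_respondents(self) -> int:
        return int(self.survey_mask.sum())

    @property
    def respondents(self) -> pd.DataFrame:
        return self.data.loc[self.survey_mask]

    @property
    def responses(self) -> np.ndarray:
        """Observed responses of respondents, in row order."""
        return self.data.loc[self.survey_mask, "response"].to_numpy(dtype=float)

    @property
    def hierarchy(self) -> RegionHierarchy:
        return RegionHierarchy(
            self.data[["region_nbhd", "region_district", "region_muni"]]
        )

    def region_codes(self, level: str) -> pd.Series:
        return level_codes(self.data, level)

    def copy(self) -> "PopulationFrame":
        return PopulationFrame(
            self.data.copy(),
            list(self.feature_columns),
            list(self.categorical_columns),
        )

    def validate(self) -> None:
        self.hierarchy.validate()
        resp = self.data["response"]
        surveyed = self.survey_mask
        if resp[surveyed].isna().any():
            raise ValueError("respondent row with empty response")
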