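"""Dummy (treatment) coding of categorical cyclist-behavior covariates.

Every covariate in the lane-occupancy analysis is categorical; an L-level
variable enters the logit as L-1 indicator columns against a designated
reference level, plus a leading intercept column of ones.  The reference
levels are analysis-specific (the per-facility refits use different local
references), so the coding is driven by an explicit :class:`ReferenceMap`
rather than a global convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceMap",
    "DesignMatrix",
    "DEFAULT_REFERENCES",
    "build_design_matrix",
    "subset_columns",
    "reconstruct_categories",
]

INTERCEPT = "intercept"


@dataclass(frozen=True)
class ReferenceMap:
    """Ordered category lists and the reference level for each variable.

    ``levels`` maps variable name -> ordered tuple of category labels;
    ``reference`` maps variable name -> the member treated as baseline.
    Variable order of ``levels`` fixes the design-matrix column order.
    """

    levels: dict[str, tuple[str, ...]]
    reference: dict[str, str]

    def __post_init__(self) -> None:
        for var, cats in self.levels.items():
            if len(set(cats)) != len(cats):
                raise ValueError(f"duplicate categories for variable {var!r}")
            ref = self.reference.get(var)
            if ref is None:
                raise ValueError(f"no reference level declared for variable {var!r}")
            if ref not in cats:
                raise ValueError(
                    f"reference {ref!r} for variable {var!r} is not among its levels {cats}"
                )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.levels)

    def subset(self, variables: list[str] | tuple[str, ...]) -> "ReferenceMap":
        """Restrict to ``variables`` (order as given)."""
        missing = [v for v in variables if v not in self.levels]
        if missing:
            raise KeyError(f"variables not in reference map: {missing}")
        return ReferenceMap(
            levels={v: self.levels[v] for v in variables},
            reference={v: self.reference[v] for v in variables},
        )

    def replace(
        self,
        levels: dict[str, tuple[str, ...]] | None = None,
        reference: dict[str, str] | None = None,
    ) -> "ReferenceMap":
        """Return a copy with some variables' levels/references overridden."""
        new_levels = dict(self.levels)
        new_ref = dict(self.reference)
        if levels:
            new_levels.update(levels)
        if reference:
            new_ref.update(reference)
        return ReferenceMap(levels=new_levels, reference=new_ref)


#: Default coding used for the all-facilities model: reference levels are
#: female, young, conventional bike, greenbelt strip, 4.5 m lane, one vehicle
#: lane, low bike/vehicle volume, no parking, sunny, morning peak, unaccompanied
#: (no manned riding), non-workday.
DEFAULT_REFERENCES = ReferenceMap(
    levels={
        "gender": ("female", "male"),
        "age": ("young", "middle_aged", "old"),
        "bike_type": ("c_bike", "e_bike", "e_scooter", "tricycle"),
        "dividing_strip": ("greenbelt", "barriers", "marking", "pedestrian_bicycle", "mixed"),
        "bike_lane_width": ("4.5", "2.5", "3.5", "1.5"),
        "vehicle_lanes": ("1", "2", "3", "4"),
        "bike_volume": ("low", "medium", "high"),
        "vehicle_volume": ("low", "medium", "high"),
        "on_street_parking": ("no", "yes"),
        "temporary_parking": ("no", "yes"),
        "weather": ("sunny", "cloudy", "rainy"),
        "time_interval": ("morning", "noon", "evening"),
        "manned_riding": ("no", "yes"),
        "workday": ("no", "yes"),
    },
    reference={
        "gender": "female",
        "age": "young",
        "bike_type": "c_bike",
        "dividing_strip": "greenbelt",
        "bike_lane_width": "4.5",
        "vehicle_lanes": "1",
        "bike_volume": "low",
        "vehicle_volume": "low",
        "on_street_parking": "no",
        "temporary_parking": "no",
        "weather": "sunny",
        "time_interval": "morning",
        "manned_riding": "no",
        "workday": "no",
    },
)


@dataclass
class DesignMatrix:
    """n x (k+1) treatment-coded design matrix with column provenance.

    ``X`` holds 0/1 floats with a leading intercept column of ones.  Column
    labels follow ``"<variable>:<level> vs <reference>"``; ``column_info``
    maps each non-intercept label to its ``(variable, level, reference)``.
    """

    X: np.ndarray
    columns: list[str]
    column_info: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape inconsistent with column labels")
        if self.columns[0] != INTERCEPT:
            raise ValueError("first column must be the intercept")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        """Number of non-intercept columns."""
        return self.X.shape[1] - 1

    def variables(self) -> list[str]:
        seen: list[str] = []
        for info in self.column_info.values():
            if info[0] not in seen:
                seen.append(info[0])
        return seen

    def columns_for(self, variable: str) -> list[str]:
        return [c for c, info in self.column_info.items() if info[0] == variable]

    def column_index(self, label: str) -> int:
        try:
            return self.columns.index(label)
        except ValueError:
            raise KeyError(f"unknown design column {label!r}") from None


def _label(variable: str, level: str, reference: str) -> str:
    return f"{variable}:{level} vs {reference}"


def build_design_matrix(covariates: pd.DataFrame, refs: ReferenceMap) -> DesignMatrix:
    """Encode raw categorical covariates into a treatment-coded design matrix.

    Variables are processed in the order of ``refs``; variables missing from
    the data frame are ignored, variables with a single observed level are
    excluded with a warning (their dummy would be constant).  An observed
    category absent from ``refs`` raises with the variable and value named.
    """
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = [INTERCEPT]
    info: dict[str, tuple[str, str, str]] = {}
    for var in refs.variables:
        if var not in covariates.columns:
            continue
        values = covariates[var].astype(str).to_numpy()
        cats = refs.levels[var]
        unseen = set(np.unique(values)) - set(cats)
        if unseen:
            raise ValueError(
                f"variable {var!r} contains categories not in the reference map: {sorted(unseen)}"
            )
        if len(np.unique(values)) < 2:
            warnings.warn(
                f"variable {var!r} has a single observed level and was excluded",
                UserWarning,
                stacklevel=2,
            )
            continue
        ref = refs.reference[var]
        for level in cats:
            if level == ref:
                continue
            labels.append(_label(var, level, ref))
            info[labels[-1]] = (var, level, ref)
            cols.append((values == level).astype(float))
    return DesignMatrix(X=np.column_stack(cols), columns=labels, column_info=info)


def subset_columns(dm: DesignMatrix, keep: list[str] | set[str]) -> DesignMatrix:
    """Restrict to the given non-intercept columns (intercept always kept)."""
    keep_set = set(keep) - {INTERCEPT}
    unknown = keep_set - set(dm.columns)
    if unknown:
        raise KeyError(f"unknown design columns: {sorted(unknown)}")
    labels = [INTERCEPT] + [c for c in dm.columns[1:] if c in keep_set]
    idx = [dm.columns.index(c) for c in labels]
    return DesignMatrix(
        X=dm.X[:, idx],
        columns=labels,
        column_info={c: dm.column_info[c] for c in labels[1:]},
    )


def reconstruct_categories(dm: DesignMatrix, refs: ReferenceMap) -> pd.DataFrame:
    """Invert the coding: recover each encoded variable's category per row."""
    out: dict[str, np.ndarray] = {}
    for var in dm.variables():
        ref = refs.reference[var]
        result = np.full(dm.n, ref, dtype=object)
        for c in dm.columns_for(var):
            _, level, _ = dm.column_info[c]
            result[dm.X[:, dm.column_index(c)] == 1.0] = level
        out[var] = result
    return pd.DataFrame(out)
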