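"""Flat per-cyclist observation container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ObservationSet", "OUTCOME_COLUMN"]

#: Name of the binary outcome column in CSV files (1 = rider occupied the
#: motorized vehicle lane, 0 = normal riding).
OUTCOME_COLUMN = "occupying"


@dataclass
class ObservationSet:
    """One row per observed cyclist: categorical covariates plus, optionally,
    the binary lane-occupancy outcome."""

    covariates: pd.DataFrame
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.y is not None:
            self.y = np.asarray(self.y)
            if len(self.y) != len(self.covariates):
                raise ValueError(
                    f"outcome length {len(self.y)} != covariate rows {len(self.covariates)}"
                )
            bad = ~np.isin(self.y, (0, 1))
            if bad.any():
                rows = np.flatnonzero(bad)[:5].tolist()
                raise ValueError(f"outcome must be 0/1; offending rows: {rows}")
            self.y = self.y.astype(np.int8)

    @property
    def n(self) -> int:
        return len(self.covariates)

    @property
    def variables(self) -> list[str]:
        return list(self.covariates.columns)

    def to_frame(self) -> pd.DataFrame:
        """Single data frame with the outcome (if present) as first column."""
        frame = self.covariates.copy()
        if self.y is not None:
            frame.insert(0, OUTCOME_COLUMN, self.y)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservationSet":
        y = None
        if OUTCOME_COLUMN in frame.columns:
            y = frame[OUTCOME_COLUMN].to_numpy()
            frame = frame.drop(columns=[OUTCOME_COLUMN])
        return cls(covariates=frame.reset_index(drop=True).astype(str), y=y)
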