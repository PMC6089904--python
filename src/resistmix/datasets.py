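"""The grouped dose-response dataset container and its CSV round-trip.

Long format, one row per measurement:

    group,dose_uM,replicate,viability

``group`` labels the assay condition (week post-treatment or mixture
identifier), ``dose_uM`` the drug dose in µM, ``replicate`` the replicate
id and ``viability`` the live fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ("group", "dose_uM", "replicate", "viability")


class DataValidationError(ValueError):
    """Raised when an assay table violates the dataset contract."""


@dataclass(frozen=True)
class DoseResponseDataset:
    """Validated long-format viability table.

    Wraps a :class:`pandas.DataFrame` with columns
    ``group, dose_uM, replicate, viability``.  Group order follows first
    appearance in the table and is preserved through the CSV round-trip.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", _validate(self.frame))

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records) -> "DoseResponseDataset":
        return cls(pd.DataFrame.from_records(records, columns=list(COLUMNS)))

    @classmethod
    def read_csv(cls, path) -> "DoseResponseDataset":
        """Read and validate an assay CSV.

        Offending rows are reported by their line number in the file
        (header = line 1).
        """
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise DataValidationError(f"{path}: empty input file") from None
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise DataValidationError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        for col in ("dose_uM", "viability"):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()]
            if len(bad):
                lines = ", ".join(str(i + 2) for i in bad[:10])
                raise DataValidationError(
                    f"{path}: non-numeric {col} at line(s) {lines}"
                )
            frame[col] = coerced
        out_of_range = frame.index[
            (frame["viability"] < 0) | (frame["viability"] > 1)
        ]
        if len(out_of_range):
            lines = ", ".join(str(i + 2) for i in out_of_range[:10])
            raise DataValidationError(
                f"{path}: viability outside [0, 1] at line(s) {lines}"
            )
        try:
            return cls(frame)
        except DataValidationError as err:
            raise DataValidationError(f"{path}: {err}") from None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- views ---------------------------------------------------------
    @property
    def groups(self) -> tuple:
        return tuple(pd.unique(self.frame["group"]))

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.frame["dose_uM"].unique())

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def subset(self, group) -> "DoseResponseDataset":
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise KeyError(f"unknown group {group!r}")
        return DoseResponseDataset(sub.reset_index(drop=True))

    def arrays(self):
        """(dose, viability, group_codes, groups) as numpy arrays.

        ``group_codes`` indexes into ``groups`` (first-appearance order);
        the flat representation the fitting routines consume.
        """
        groups = self.groups
        index = {g: i for i, g in enumerate(groups)}
        codes = self.frame["group"].map(index).to_numpy(dtype=np.intp)
        dose = self.frame["dose_uM"].to_numpy(dtype=float)
        y = self.frame["viability"].to_numpy(dtype=float)
        return dose, y, codes, groups


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(frame, pd.DataFrame):
        raise DataValidationError("expected a pandas DataFrame")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DataValidationError(f"missing required column(s) {missing}")
    frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)
    if frame.empty:
        raise DataValidationError("dataset contains no records")
    dose = frame["dose_uM"].to_numpy(dtype=float)
    via = frame["viability"].to_numpy(dtype=float)
    if not np.all(np.isfinite(dose)) or np.any(dose < 0):
        raise DataValidationError("doses must be finite and non-negative")
    if not np.all(np.isfinite(via)) or np.any((via < 0) | (via > 1)):
        raise DataValidationError("viability values must lie in [0, 1]")
    return frame
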