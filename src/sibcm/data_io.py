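"""Reading, validation and writing of parcellated BOLD time series.

The universal container is :class:`ParcellatedTimeSeries`: a T x M matrix of
BOLD values (one row per time point, one column per region) together with the
sampling interval (TR, seconds) and region labels.  Files are plain delimited
text (TSV/CSV) with an optional header row of region ids, which keeps inputs
diffable and portable across fMRI toolchains.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The seven canonical resting-state networks plus the unassigned label.
RSN_VOCABULARY = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN", "NONE")


class FormatError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells)."""


class ValidationError(ValueError):
    """Well-formed file with invalid content (NaN/inf, bad sizes)."""


class DegenerateRegionError(ValidationError):
    """A region is constant where variability is required."""


@dataclasses.dataclass(frozen=True)
class ParcellatedTimeSeries:
    """Region-parcellated BOLD signal, empirical or simulated.

    Parameters
    ----------
    values
        T x M array, rows are time points, columns are regions.
    tr_seconds
        Sampling interval in seconds.
    region_ids
        M unique region labels, column order.
    """

    values: np.ndarray
    tr_seconds: float
    region_ids: tuple[str, ...]
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_ids", tuple(map(str, self.region_ids)))
        if values.ndim != 2:
            raise ValidationError(f"expected 2-D matrix, got ndim={values.ndim}")
        t, m = values.shape
        if t < 3:
            raise ValidationError(f"need at least 3 time points, got T={t}")
        if m < 2:
            raise ValidationError(f"need at least 2 regions, got M={m}")
        if len(self.region_ids) != m:
            raise ValidationError(
                f"{len(self.region_ids)} region ids for {m} columns"
            )
        if len(set(self.region_ids)) != m:
            raise ValidationError("region ids are not unique")
        if self.tr_seconds <= 0:
            raise ValidationError(f"tr_seconds must be positive, got {self.tr_seconds}")
        bad = ~np.isfinite(values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at time point {r}, region {self.region_ids[c]!r}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_timepoints * self.tr_seconds

    def with_values(self, values: np.ndarray) -> "ParcellatedTimeSeries":
        return dataclasses.replace(self, values=values)


@dataclasses.dataclass(frozen=True)
class ParcellationMap:
    """Assignment of each region to one resting-state network."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        for region, label in self.assignments.items():
            if label not in RSN_VOCABULARY:
                raise ValidationError(
                    f"RSN label {label!r} for region {region!r} not in "
                    f"{RSN_VOCABULARY}"
                )

    def labels_for(self, region_ids: Sequence[str]) -> list[str]:
        missing = [r for r in region_ids if r not in self.assignments]
        if missing:
            raise ValidationError(f"regions without RSN label: {missing}")
        return [self.assignments[r] for r in region_ids]


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    """Read a delimited numeric table, auto-detecting the delimiter."""
    text = Path(path).read_text()
    sep = delimiter
    if sep is None:
        head = text.splitlines()[0] if text.splitlines() else ""
        sep = "\t" if head.count("\t") >= head.count(",") else ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed table ({exc})") from exc
    return df


def load_timeseries(
    path,
    tr_seconds: float,
    orientation: str = "time-by-region",
    delimiter: str | None = None,
    subject_id: str = "",
    session_id: str = "",
) -> ParcellatedTimeSeries:
    """Load a delimited BOLD matrix.

    ``orientation`` declares the on-disk layout: ``time-by-region`` (default,
    rows are time points) or ``region-by-time`` (transposed on read).  A first
    row that does not parse as numbers is treated as a header of region ids.
    """
    if orientation not in ("time-by-region", "region-by-time"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, delimiter)
    header: list[str] | None = None
    first = df.iloc[0]
    try:
        first.astype(float)
    except (TypeError, ValueError):
        header = [str(v).strip() for v in first]
        df = df.iloc[1:]
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(f"{path}: empty cell at row {r}, column {c}")
    try:
        # numpy's string conversion round-trips repr-printed floats exactly
        values = df.to_numpy(dtype=str).astype(np.float64)
    except ValueError:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at row {r}, column {c}: {df.iat[r, c]!r}"
        ) from None
    if orientation == "region-by-time":
        values = values.T
        # header, if any, labelled rows in the file
    region_ids = header if header is not None else [
        f"R{i:03d}" for i in range(values.shape[1])
    ]
    if header is not None and orientation == "region-by-time":
        raise FormatError(
            f"{path}: header row is ambiguous for region-by-time orientation"
        )
    return ParcellatedTimeSeries(
        values=values, tr_seconds=tr_seconds, region_ids=region_ids,
        subject_id=subject_id, session_id=session_id,
    )


def write_timeseries(ts: ParcellatedTimeSeries, path, delimiter: str = "\t") -> None:
    """Write a series as delimited text with a header row of region ids.

    Values use repr-precision floats so a read-back round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write(delimiter.join(ts.region_ids) + "\n")
        for row in ts.values:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def load_parcellation(path, region_ids: Sequence[str]) -> ParcellationMap:
    """Load a two-column (region_id, RSN label) table covering ``region_ids``."""
    df = _read_table(path, None)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    assignments = {str(r).strip(): str(l).strip() for r, l in df.to_numpy()}
    missing = [r for r in region_ids if r not in assignments]
    if missing:
        raise ValidationError(f"{path}: no RSN label for regions {missing}")
    pm = ParcellationMap({r: assignments[r] for r in region_ids})
    return pm


def standardize(ts: ParcellatedTimeSeries, policy: str = "per-region z-score") -> ParcellatedTimeSeries:
    """Standardize a series.

    ``none`` returns the input unchanged.  ``per-region z-score`` removes each
    region's temporal mean and divides by its (ddof=0) standard deviation,
    which the phase-space association path requires because that statistic is
    amplitude-sensitive while correlation is not.
    """
    if policy == "none":
        return ts
    if policy != "per-region z-score":
        raise ValueError(f"unknown standardization policy {policy!r}")
    mu = ts.values.mean(axis=0)
    sd = ts.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DegenerateRegionError(
            f"constant region under z-score: {ts.region_ids[flat[0]]!r}"
        )
    return ts.with_values((ts.values - mu) / sd)
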