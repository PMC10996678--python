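"""Tab-separated readers and writers for every table the pipeline touches.

All tables are TSV with a one-line header; region order is the canonical
alignment key.  Time-series files carry the TR in a leading comment line
(``#tr_seconds=3.0``) so a file is self-describing, but a TR passed by the
caller wins.  Writers emit floats at full round-trip precision (``%.17g``)
so read(write(x)) is bitwise lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError
from .ignition import IgnitionProfile, ParcelTimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_burden_table",
    "write_burden_table",
    "read_centroids",
    "read_labels",
    "write_profiles",
    "read_manifest",
]

_FLOAT_FMT = "%.17g"


def read_timeseries(path, tr_seconds: float | None = None, subject_id: str | None = None) -> ParcelTimeSeries:
    """Read a region×time TSV into a :class:`ParcelTimeSeries`.

    Layout: optional ``#tr_seconds=<x>`` comment, then a header row
    (``region_id`` followed by timepoint names), then one numeric row per
    region.  Ragged rows raise :class:`FormatError`; non-numeric or missing
    cells raise :class:`DataError` naming the offending row and column.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_tr = None
    while lines and lines[0].startswith("#"):
        key, _, val = lines.pop(0).lstrip("#").partition("=")
        if key.strip() == "tr_seconds":
            header_tr = float(val)
    if not lines:
        raise FormatError(f"{path}: empty table")
    header = lines[0].split("\t")
    ncol = len(header)
    region_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {ncol})"
            )
        region_ids.append(fields[0])
        row = np.empty(ncol - 1)
        for j, cell in enumerate(fields[1:]):
            try:
                row[j] = float(cell)
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric cell at region {fields[0]!r}, "
                    f"column {header[j + 1]!r}: {cell!r}"
                ) from None
        if not np.all(np.isfinite(row)):
            j = int(np.flatnonzero(~np.isfinite(row))[0])
            raise DataError(
                f"{path}: missing value at region {fields[0]!r}, column {header[j + 1]!r}"
            )
        rows.append(row)
    tr = tr_seconds if tr_seconds is not None else header_tr
    if tr is None:
        raise FormatError(f"{path}: no TR in header and none supplied")
    return ParcelTimeSeries(
        subject_id=subject_id or path.stem,
        data=np.vstack(rows),
        tr_seconds=tr,
        region_ids=region_ids,
    )


def write_timeseries(path, series: ParcelTimeSeries) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#tr_seconds={series.tr_seconds!r}\n")
        fh.write("region_id\t" + "\t".join(f"t{j:04d}" for j in range(series.n_timepoints)) + "\n")
        for rid, row in zip(series.region_ids, series.data):
            fh.write(rid + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_burden_table(path, region_ids: list[str] | None = None) -> pd.DataFrame:
    """Read a per-region burden TSV (region_id, abeta_suvr, tau_suvr).

    When ``region_ids`` is given, the table is aligned to that parcellation
    order; regions missing from the table raise :class:`AlignmentError`
    naming them.  SUVR values must be positive.
    """
    table = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    required = {"region_id", "abeta_suvr", "tau_suvr"}
    if not required.issubset(table.columns):
        raise FormatError(f"{path}: burden table needs columns {sorted(required)}")
    if table[["abeta_suvr", "tau_suvr"]].isna().any().any():
        raise DataError(f"{path}: missing SUVR values")
    if (table[["abeta_suvr", "tau_suvr"]] <= 0).any().any():
        raise DataError(f"{path}: SUVR values must be positive")
    if region_ids is not None:
        missing = sorted(set(region_ids) - set(table["region_id"]))
        if missing:
            raise AlignmentError(f"{path}: burden missing for regions {missing[:10]}")
        table = (
            table.set_index("region_id").loc[list(region_ids)].reset_index()
        )
    return table


def write_burden_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_centroids(path) -> pd.DataFrame:
    """Region centroid TSV (region_id, x, y, z in mm), indexed by region id."""
    table = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    if not {"region_id", "x", "y", "z"}.issubset(table.columns):
        raise FormatError(f"{path}: centroid table needs region_id, x, y, z")
    if table.duplicated("region_id").any():
        raise FormatError(f"{path}: duplicate region ids")
    return table.set_index("region_id")


def read_labels(path) -> pd.Series:
    """RSN-label TSV (region_id, rsn) as a Series indexed by region id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"region_id", "rsn"}.issubset(table.columns):
        raise FormatError(f"{path}: label table needs region_id, rsn")
    return table.set_index("region_id")["rsn"]


def write_profiles(path, profiles: list[IgnitionProfile]) -> None:
    """Long TSV of ignition profiles, one row per subject×region."""
    frames = []
    for p in profiles:
        f = p.to_frame()
        f.insert(0, "subject_id", p.subject_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest TSV: subject_id, diagnosis, timeseries, burden paths."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "diagnosis", "timeseries_path"}
    if not required.issubset(table.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    if table["subject_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate subject ids")
    bad = set(table["diagnosis"]) - {"HC", "MCI", "AD"}
    if bad:
        raise FormatError(f"{path}: unknown diagnosis values {sorted(bad)}")
    return table
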