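"""Tabular dataset I/O: paired hematoma/skin rows in plain CSV.

Schema (one row per ROI spectrum, two rows per recording):

    subject_id, sex, age_hours, roi, band_0001, ..., band_NNNN

``sex`` is ``M``/``F``; ``roi`` is ``hematoma`` or ``skin``; ``age_hours`` is
empty for the pre-injection baseline frame. Rows sharing ``(subject_id,
age_hours)`` pair into one :class:`~hemaspec.spectra.Recording`. Values are
written with 17 significant digits so a write/read round trip is lossless.

A flat ``key = value`` sidecar format records provenance (generator or run
configuration) next to the CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DatasetSchemaError
from .grids import WavelengthGrid
from .spectra import PRE_INJECTION, Recording, Spectrum

__all__ = [
    "read_dataset_csv",
    "write_dataset_csv",
    "read_sidecar",
    "write_sidecar",
]

_META_COLS = ["subject_id", "sex", "age_hours", "roi"]


def _band_cols(n_bands: int) -> list[str]:
    return [f"band_{b:04d}" for b in range(1, n_bands + 1)]


def write_dataset_csv(recordings: list[Recording], path: str | Path) -> None:
    """Write recordings as paired hematoma/skin rows; lossless round trip."""
    if not recordings:
        raise DatasetSchemaError("no recordings to write")
    n_bands = recordings[0].grid.n_bands
    rows = []
    for rec in recordings:
        # repr of a Python float is the shortest exactly-round-tripping form
        age = "" if rec.is_pre_injection else repr(float(rec.age_hours))
        for roi, spec in (("hematoma", rec.hematoma), ("skin", rec.skin)):
            rows.append(
                [rec.subject_id, rec.sex, age, roi, *(repr(float(v)) for v in spec.values)]
            )
    frame = pd.DataFrame(rows, columns=_META_COLS + _band_cols(n_bands))
    frame.to_csv(path, index=False)


def read_dataset_csv(
    path: str | Path, grid: WavelengthGrid | None = None
) -> list[Recording]:
    """Read a dataset CSV back into paired recordings.

    Raises
    ------
    DatasetSchemaError
        On a wrong band count, an unpaired ROI row, or a duplicated pair.
    """
    frame = pd.read_csv(
        path,
        dtype={"subject_id": str, "sex": str, "roi": str},
        float_precision="round_trip",
    )
    band_cols = [c for c in frame.columns if c.startswith("band_")]
    n_bands = len(band_cols)
    expected = _META_COLS + _band_cols(n_bands)
    if list(frame.columns) != expected or n_bands == 0:
        raise DatasetSchemaError(
            f"bad column layout: expected {_META_COLS} + band_0001..band_{n_bands:04d}"
        )
    if grid is None:
        grid = WavelengthGrid(n_bands=n_bands)
    elif grid.n_bands != n_bands:
        raise DatasetSchemaError(
            f"CSV has {n_bands} bands but grid expects {grid.n_bands}"
        )

    pairs: dict[tuple[str, float | None], dict[str, Spectrum]] = {}
    meta: dict[tuple[str, float | None], str] = {}
    order: list[tuple[str, float | None]] = []
    for _, row in frame.iterrows():
        if row["roi"] not in ("hematoma", "skin"):
            raise DatasetSchemaError(f"unknown roi label {row['roi']!r}")
        if row["sex"] not in ("M", "F"):
            raise DatasetSchemaError(f"unknown sex label {row['sex']!r}")
        age = PRE_INJECTION if pd.isna(row["age_hours"]) else float(row["age_hours"])
        key = (row["subject_id"], age)
        if key not in pairs:
            pairs[key] = {}
            meta[key] = row["sex"]
            order.append(key)
        if row["roi"] in pairs[key]:
            raise DatasetSchemaError(
                f"duplicated {row['roi']} row for subject {key[0]} at age {key[1]}"
            )
        values = row[band_cols].to_numpy(dtype=float)
        pairs[key][row["roi"]] = Spectrum(values, grid)

    recordings = []
    for key in order:
        if set(pairs[key]) != {"hematoma", "skin"}:
            missing = {"hematoma", "skin"} - set(pairs[key])
            raise DatasetSchemaError(
                f"unpaired rows for subject {key[0]} at age {key[1]}: "
                f"missing {sorted(missing)}"
            )
        recordings.append(
            Recording(key[0], meta[key], key[1], pairs[key]["hematoma"], pairs[key]["skin"])
        )
    return recordings


def write_sidecar(path: str | Path, entries: dict) -> None:
    """Write a flat ``key = value`` provenance sidecar."""
    lines = [f"{k} = {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` sidecar back into a string dict."""
    entries: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DatasetSchemaError(f"malformed sidecar line: {line!r}")
        key, value = line.split("=", 1)
        entries[key.strip()] = value.strip()
    return entries
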