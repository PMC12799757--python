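"""Skin-referenced normalization of hematoma spectra.

Three feature sets are derived from each recording's paired hematoma spectrum
``h`` and adjacent-skin spectrum ``s`` (per band):

======== ==============
method   feature
======== ==============
raw      h
subtract h - s
divide   h / s
======== ==============

Division maps unaffected tissue to 1 and — because both ROIs of a recording
share one illumination gain — cancels that gain exactly, which is why it is
the most robust of the three under varying lighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateReferenceError
from .grids import WavelengthGrid
from .spectra import Recording

__all__ = ["FeatureDataset", "normalize", "METHODS"]

METHODS = ("raw", "subtract", "divide")

#: Calibrated skin reflectance over 400-1000 nm never approaches zero in
#: valid data; a reference band below this signals a broken ROI.
_SKIN_EPS = 1e-6


@dataclass(frozen=True)
class FeatureDataset:
    """Normalized feature matrix with age targets and subject grouping.

    Attributes
    ----------
    X : ndarray, shape (n_samples, n_bands)
        Normalized per-band features.
    y : ndarray, shape (n_samples,)
        Hematoma age in hours.
    subject : ndarray of str
        Subject identifier per sample (the cross-validation group).
    sex : ndarray of str
        ``"M"``/``"F"`` per sample.
    method : str
        One of ``raw``, ``subtract``, ``divide``.
    """

    X: np.ndarray
    y: np.ndarray
    subject: np.ndarray
    sex: np.ndarray
    method: str
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.subject) == len(self.sex) == n):
            raise ValueError("X, y, subject, sex must have equal row counts")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain non-finite values")
        if np.any(self.y < 0):
            raise ValueError("ages must be non-negative")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]


def normalize(recordings: list[Recording], method: str) -> FeatureDataset:
    """Build a :class:`FeatureDataset` from paired recordings.

    Pre-injection baseline recordings carry no age label and are dropped.
    Sample order otherwise follows the input order; subject, sex and age pass
    through unchanged.

    Raises
    ------
    DegenerateReferenceError
        For ``divide`` when any skin reference band is within ``1e-6`` of zero.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    usable = [r for r in recordings if not r.is_pre_injection]
    if not usable:
        raise ValueError("no post-injection recordings to normalize")
    grid = usable[0].grid

    rows = []
    for rec in usable:
        h, s = rec.hematoma.values, rec.skin.values
        if method == "raw":
            rows.append(h)
        elif method == "subtract":
            rows.append(h - s)
        else:
            small = np.abs(s) < _SKIN_EPS
            if small.any():
                band = int(np.argmax(small)) + 1
                raise DegenerateReferenceError(
                    f"skin reference ~0 for subject {rec.subject_id} at "
                    f"{rec.age_hours} h, band {band}"
                )
            rows.append(h / s)

    return FeatureDataset(
        X=np.asarray(rows, dtype=float),
        y=np.asarray([r.age_hours for r in usable], dtype=float),
        subject=np.asarray([r.subject_id for r in usable]),
        sex=np.asarray([r.sex for r in usable]),
        method=method,
        grid=grid,
    )
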