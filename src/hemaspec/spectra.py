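"""Spectra, hyperspectral cubes, ROI masks, and paired recordings.

A *Recording* is one timepoint of one subject: the ROI-averaged hematoma
spectrum together with the paired adjacent-skin spectrum from the same frame.
The adjacent-skin spectrum is the normalization reference for that recording;
because both ROIs come from one frame they share the illumination of that
frame, which is what makes ratio normalization illumination-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, MaskError
from .grids import DEFAULT_GRID, WavelengthGrid

__all__ = [
    "PRE_INJECTION",
    "Spectrum",
    "HyperCube",
    "ROIMask",
    "Recording",
    "calibrate_reflectance",
    "extract_mean_spectrum",
]

#: Sentinel age label for the baseline frame taken before blood injection.
#: Stored alongside the data but excluded from every model dataset.
PRE_INJECTION = None


@dataclass(frozen=True)
class Spectrum:
    """Reflectance per band on a wavelength grid (unitless, finite)."""

    values: np.ndarray
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.shape[0] != self.grid.n_bands:
            raise ValueError(
                f"spectrum length {values.shape} does not match grid "
                f"n_bands={self.grid.n_bands}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("spectrum contains non-finite values")


@dataclass(frozen=True)
class HyperCube:
    """Reflectance cube of shape (rows, cols, n_bands)."""

    data: np.ndarray
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        if data.ndim != 3 or data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube shape {data.shape} incompatible with grid n_bands={self.grid.n_bands}"
            )
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("cube must have at least one pixel")
        if not np.all(np.isfinite(data)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ROIMask:
    """Boolean pixel mask selecting a region of interest."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2:
            raise MaskError(f"mask must be 2-D, got shape {mask.shape}")
        if not mask.any():
            raise MaskError("mask selects no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Recording:
    """One subject-timepoint: paired hematoma and adjacent-skin spectra.

    ``age_hours`` is the time since blood injection, or :data:`PRE_INJECTION`
    for the baseline frame.
    """

    subject_id: str
    sex: str  # "M" or "F"
    age_hours: float | None
    hematoma: Spectrum
    skin: Spectrum
    grid: WavelengthGrid = field(init=False)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.hematoma.grid != self.skin.grid:
            raise ValueError("hematoma and skin spectra must share one grid")
        if self.age_hours is not PRE_INJECTION and self.age_hours < 0:
            raise ValueError(f"age_hours must be >= 0, got {self.age_hours}")
        object.__setattr__(self, "grid", self.hematoma.grid)

    @property
    def is_pre_injection(self) -> bool:
        return self.age_hours is PRE_INJECTION


def calibrate_reflectance(
    raw: HyperCube, white: Spectrum, dark: Spectrum | None = None
) -> HyperCube:
    """Convert raw sensor counts to reflectance against a white reference.

    Per pixel and band: ``R = (raw - dark) / (white - dark)``, where the white
    reference is a tile of known flat reflectance imaged in the same frame and
    the dark frame defaults to zero. Values above 1 (deliberate overexposure)
    are kept, not clipped.

    Raises
    ------
    CalibrationError
        If ``white <= dark`` in any band.
    """
    if dark is None:
        dark = Spectrum(np.zeros(raw.grid.n_bands), raw.grid)
    denom = white.values - dark.values
    if np.any(denom <= 0):
        bad = int(np.argmax(denom <= 0)) + 1
        raise CalibrationError(
            f"white reference <= dark in band {bad}: cannot calibrate"
        )
    data = (raw.data - dark.values) / denom
    return HyperCube(data, raw.grid)


def extract_mean_spectrum(cube: HyperCube, mask: ROIMask) -> Spectrum:
    """Arithmetic per-band mean over the masked pixels of ``cube``."""
    if mask.mask.shape != cube.data.shape[:2]:
        raise MaskError(
            f"mask shape {mask.mask.shape} does not match cube spatial shape "
            f"{cube.data.shape[:2]}"
        )
    # accumulate in float64 even for float32 cubes
    return Spectrum(cube.data[mask.mask].mean(axis=0, dtype=np.float64), cube.grid)
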