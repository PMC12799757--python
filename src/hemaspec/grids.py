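"""Wavelength-grid conventions.

The camera records 204 reflectance bands spanning 400-1000 nm. The exact
band-center table of the instrument is not public, so the package adopts a
linear convention with the endpoints pinned exactly:

    lambda(b) = 400 + (b - 1) * 600 / 203        (b is 1-based)

Under this convention band 165 sits at 884.7 nm (reported in the field as
"885 nm") and bands 23-26 cover 465-474 nm (the "470 nm" bilirubin region),
so 1-based band indices and nominal wavelengths interconvert consistently
with how results are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WavelengthGrid", "band_to_wavelength", "wavelength_to_band", "DEFAULT_GRID"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Linear band-center grid over a closed wavelength interval.

    Parameters
    ----------
    n_bands : int
        Number of spectral bands (>= 2).
    lambda_min, lambda_max : float
        Wavelengths (nm) of the first and last band centers.
    """

    n_bands: int = 204
    lambda_min: float = 400.0
    lambda_max: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError(f"n_bands must be >= 2, got {self.n_bands}")
        if not self.lambda_min < self.lambda_max:
            raise ValueError(
                f"lambda_min ({self.lambda_min}) must be < lambda_max ({self.lambda_max})"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        """Band centers in nm, strictly increasing, length ``n_bands``."""
        return np.linspace(self.lambda_min, self.lambda_max, self.n_bands)

    @property
    def spacing(self) -> float:
        """Distance between adjacent band centers in nm."""
        return (self.lambda_max - self.lambda_min) / (self.n_bands - 1)

    def band_to_wavelength(self, band: int) -> float:
        """Wavelength (nm) of a 1-based band index; endpoints map exactly."""
        if not 1 <= band <= self.n_bands:
            raise IndexError(f"band {band} outside 1..{self.n_bands}")
        if band == self.n_bands:  # avoid float drift at the upper endpoint
            return float(self.lambda_max)
        return float(self.lambda_min + (band - 1) * self.spacing)

    def wavelength_to_band(self, nm: float) -> int:
        """1-based index of the band center nearest ``nm``.

        Ties between two equidistant centers break toward the lower index.
        """
        if not self.lambda_min <= nm <= self.lambda_max:
            raise ValueError(
                f"wavelength {nm} nm outside [{self.lambda_min}, {self.lambda_max}]"
            )
        # np.argmin returns the first (= lower-index) minimiser on exact ties
        return int(np.argmin(np.abs(self.wavelengths - nm))) + 1


DEFAULT_GRID = WavelengthGrid()


def band_to_wavelength(band: int, grid: WavelengthGrid = DEFAULT_GRID) -> float:
    """Wavelength in nm of a 1-based band index on ``grid``."""
    return grid.band_to_wavelength(band)


def wavelength_to_band(nm: float, grid: WavelengthGrid = DEFAULT_GRID) -> int:
    """1-based band index whose center is nearest ``nm`` on ``grid``."""
    return grid.wavelength_to_band(nm)
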