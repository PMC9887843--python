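"""Spectral curves sampled on a wavelength grid (nm)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

STANDARD_GRID = np.arange(400.0, 901.0, 1.0)  # 400–900 nm, 1 nm step


@dataclass
class SpectralCurve:
    """A curve value(λ) on a strictly increasing wavelength grid."""

    wavelength_nm: np.ndarray
    value: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.shape != self.value.shape:
            raise InvalidInputError("wavelength and value must be matching 1-D arrays")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise InvalidInputError("wavelength grid must be strictly increasing")

    def at(self, wavelength) -> np.ndarray:
        """Linear interpolation; out-of-range queries are an error."""
        w = np.asarray(wavelength, dtype=float)
        if w.min() < self.wavelength_nm[0] or w.max() > self.wavelength_nm[-1]:
            raise InvalidInputError(
                f"wavelength outside curve range "
                f"[{self.wavelength_nm[0]}, {self.wavelength_nm[-1]}] nm"
            )
        return np.interp(w, self.wavelength_nm, self.value)

    def resampled(self, grid) -> "SpectralCurve":
        grid = np.asarray(grid, dtype=float)
        return SpectralCurve(grid, self.at(grid), self.name)

    @classmethod
    def flat(cls, value: float, grid=STANDARD_GRID, name: str = "flat") -> "SpectralCurve":
        grid = np.asarray(grid, dtype=float)
        return cls(grid, np.full(grid.shape, float(value)), name)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "SpectralCurve":
        """Read columns ``wavelength_nm``, ``value``."""
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), name or str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelength_nm, "value": self.value}).to_csv(
            path, index=False
        )
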