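"""One-dimensional NMR spectrum container and plain-text I/O.

Spectra live on a uniform ppm grid stored in ascending order (the display
convention in NMR is descending ppm; ascending storage keeps all numeric
code free of sign juggling and is purely an internal choice).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class Spectrum:
    """A 1D spectrum on a uniform ppm grid.

    Parameters
    ----------
    ppm_start : float
        Chemical shift of the first stored point (lowest ppm).
    ppm_step : float
        Grid spacing in ppm; must be positive.
    intensities : numpy.ndarray
        Real intensities, one per grid point; all finite, length >= 2.
    sample_id, batch_id : str
        Free-form identifiers carried through the pipeline.
    """

    ppm_start: float
    ppm_step: float
    intensities: np.ndarray
    sample_id: str = ""
    batch_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ppm_step <= 0:
            raise ValueError("ppm_step must be positive")
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("intensities must be a 1D array of length >= 2")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def ppm(self) -> np.ndarray:
        """The ppm axis (ascending)."""
        return self.ppm_start + self.ppm_step * np.arange(self.intensities.size)

    @property
    def ppm_end(self) -> float:
        return self.ppm_start + self.ppm_step * (self.intensities.size - 1)

    def shifted(self, delta_ppm: float) -> "Spectrum":
        """Return a copy with the ppm axis shifted by ``delta_ppm``."""
        return replace(self, ppm_start=self.ppm_start + delta_ppm,
                       intensities=self.intensities.copy())

    def slice(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (ppm, intensities) restricted to [lo, hi]."""
        ppm = self.ppm
        mask = (ppm >= lo) & (ppm <= hi)
        return ppm[mask], self.intensities[mask]

    @classmethod
    def from_arrays(cls, ppm: np.ndarray, intensities: np.ndarray,
                    sample_id: str = "", batch_id: str = "",
                    rtol: float = 1e-6) -> "Spectrum":
        """Build a Spectrum from explicit (ppm, intensity) arrays.

        The ppm axis must be uniform (within ``rtol`` of the mean step) and
        may be supplied in either ascending or descending order.
        """
        ppm = np.asarray(ppm, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        if ppm.ndim != 1 or ppm.size != intensities.size:
            raise ValueError("ppm and intensities must be 1D of equal length")
        if ppm[0] > ppm[-1]:
            ppm, intensities = ppm[::-1], intensities[::-1]
        steps = np.diff(ppm)
        step = steps.mean()
        if step <= 0 or np.max(np.abs(steps - step)) > rtol * abs(step) + 1e-12:
            raise ValueError("ppm grid is not uniform")
        return cls(ppm_start=float(ppm[0]), ppm_step=float(step),
                   intensities=intensities, sample_id=sample_id, batch_id=batch_id)


def read_spectrum_csv(path, sample_id: str = "", batch_id: str = "") -> Spectrum:
    """Read a two-column (ppm, intensity) CSV file.

    A header row is accepted (any non-numeric first row is skipped).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    ppm = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy()
    inten = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy()
    return Spectrum.from_arrays(ppm, inten, sample_id=sample_id, batch_id=batch_id)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum as a two-column (ppm, intensity) CSV file."""
    pd.DataFrame({"ppm": spectrum.ppm,
                  "intensity": spectrum.intensities}).to_csv(path, index=False)
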