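"""Modified Beer-Lambert conversion of optical-density changes to hemoglobin.

Three measurement wavelengths and two chromophores give an overdetermined
linear system per time sample, solved by ordinary least squares.  The
photon pathlength L is not resolved here: outputs are L-scaled
concentration changes, and L cancels later when channels are Z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError

#: Default wavelengths (nm) of the three-wavelength CW instrument class.
DEFAULT_WAVELENGTHS = (780.0, 805.0, 830.0)

# Literature molar extinction coefficients, 1/(mM*cm), columns HbO2, HbR.
# Device-specific tables should be loaded via read_extinction_table.
DEFAULT_EXTINCTION = np.array(
    [
        [0.736, 1.102],  # 780 nm
        [0.880, 0.762],  # 805 nm (near-isosbestic)
        [0.974, 0.693],  # 830 nm
    ]
)


@dataclass
class ExtinctionSet:
    """Molar extinction coefficients per wavelength for HbO2 and HbR."""

    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS
    coefficients: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.wavelengths_nm), 2):
            raise ConfigError(
                "extinction matrix must be (n_wavelengths, 2), got "
                f"{self.coefficients.shape}"
            )
        if np.linalg.matrix_rank(self.coefficients) < 2:
            raise ConfigError("extinction matrix is rank deficient; system unsolvable")


def od_to_hb(delta_od: np.ndarray, ext: ExtinctionSet | None = None):
    """Convert optical-density changes to L-scaled hemoglobin changes.

    Parameters
    ----------
    delta_od
        (n_wavelengths, n_samples) array of optical-density changes,
        wavelength rows aligned in time.
    ext
        Extinction coefficients; defaults to the shipped literature table.

    Returns
    -------
    (hbo2, hbr, hbt)
        Three (n_samples,) arrays.  hbt = hbo2 + hbr exactly.
    """
    if ext is None:
        ext = ExtinctionSet()
    delta_od = np.asarray(delta_od, dtype=float)
    if delta_od.ndim != 2 or delta_od.shape[0] != len(ext.wavelengths_nm):
        raise ParameterError(
            f"delta_od must be ({len(ext.wavelengths_nm)}, n_samples), got {delta_od.shape}"
        )
    # least-squares per sample: dOD = E @ (L * dC)
    conc = np.linalg.pinv(ext.coefficients) @ delta_od
    hbo2, hbr = conc[0], conc[1]
    return hbo2, hbr, hbo2 + hbr


def hb_to_od(hbo2: np.ndarray, hbr: np.ndarray, ext: ExtinctionSet | None = None) -> np.ndarray:
    """Forward model: L-scaled concentrations back to optical density."""
    if ext is None:
        ext = ExtinctionSet()
    conc = np.vstack([np.asarray(hbo2, float), np.asarray(hbr, float)])
    return ext.coefficients @ conc


def write_extinction_table(ext: ExtinctionSet, path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": ext.wavelengths_nm,
            "hbo2": ext.coefficients[:, 0],
            "hbr": ext.coefficients[:, 1],
        }
    ).to_csv(path, sep="\t", index=False)


def read_extinction_table(path) -> ExtinctionSet:
    frame = pd.read_csv(path, sep="\t")
    for col in ("wavelength_nm", "hbo2", "hbr"):
        if col not in frame.columns:
            raise ConfigError(f"extinction table missing column {col!r}")
    return ExtinctionSet(
        wavelengths_nm=tuple(frame["wavelength_nm"].astype(float)),
        coefficients=frame[["hbo2", "hbr"]].to_numpy(dtype=float),
    )
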