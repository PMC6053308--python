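"""FRET efficiency from fluorescence spectra — the (ratio)A method.

A donor-acceptor fusion in solution is scanned twice on a fluorometer: once
exciting the donor (λDex) and once exciting the acceptor (λAex).  At the
acceptor emission peak (λAem) the donor-excited scan contains sensitized
emission plus directly excited acceptor, while the acceptor-excited scan is
pure acceptor.  With extinction coefficients ε read off absorbance spectra,

    E = [εA(λAex) / εD(λDex)] * [ If(λAem)/Ia(λAem) - εA(λDex)/εA(λAex) ],

which is independent of concentration, path length and detector gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, ParameterError

__all__ = [
    "Spectrum",
    "PairSpectralConfig",
    "SpectralMeasurement",
    "extinction_from_absorbance",
    "ratio_a_efficiency",
    "PAIR_SPECTRA",
]


@dataclass
class Spectrum:
    """A (wavelength, value) table with linear interpolation."""

    wavelength: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.wavelength.ndim != 1 or self.wavelength.shape != self.value.shape:
            raise InvalidInputError("spectrum arrays must be matching 1-D")
        if np.any(np.diff(self.wavelength) <= 0):
            raise InvalidInputError("wavelength grid must be ascending")

    def at(self, wavelength: float) -> float:
        lo, hi = self.wavelength[0], self.wavelength[-1]
        if not lo <= wavelength <= hi:
            raise InvalidInputError(
                f"wavelength {wavelength} nm outside scan range [{lo}, {hi}]")
        return float(np.interp(wavelength, self.wavelength, self.value))

    @classmethod
    def from_csv(cls, path, value_column: str = "intensity") -> "Spectrum":
        import pandas as pd

        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns or value_column not in df.columns:
            raise InvalidInputError(
                f"spectrum CSV needs columns wavelength_nm, {value_column}")
        return cls(df["wavelength_nm"].to_numpy(),
                   df[value_column].to_numpy())

    def to_csv(self, path, value_column: str = "intensity") -> None:
        import pandas as pd

        pd.DataFrame({"wavelength_nm": self.wavelength,
                      value_column: self.value}).to_csv(path, index=False)


@dataclass(frozen=True)
class PairSpectralConfig:
    """Excitation/emission wavelengths and maximal extinction coefficients."""

    donor_ex_nm: float
    acceptor_ex_nm: float
    acceptor_em_nm: float
    donor_max_extinction: float     # M^-1 cm^-1
    acceptor_max_extinction: float  # M^-1 cm^-1


#: published settings: mTFP1-Venus scanned at 458/505 nm with the Venus
#: peak at 530 nm; Clover-mRuby2 at 505/575 nm with the mRuby2 peak at
#: 610 nm.  Maximal extinction coefficients (M^-1 cm^-1): mTFP1 64,000;
#: Venus 93,000; Clover 111,000; mRuby2 113,000.
PAIR_SPECTRA: dict[str, PairSpectralConfig] = {
    "mtfp1-venus": PairSpectralConfig(458.0, 505.0, 530.0, 64000.0, 93000.0),
    "clover-mruby2": PairSpectralConfig(505.0, 575.0, 610.0, 111000.0,
                                        113000.0),
}


@dataclass
class SpectralMeasurement:
    """Scans and absorbance spectra needed for one (ratio)A evaluation."""

    donor_excitation_scan: Spectrum    # emission scan, donor excited
    acceptor_excitation_scan: Spectrum  # emission scan, acceptor excited
    donor_absorbance: Spectrum
    acceptor_absorbance: Spectrum
    config: PairSpectralConfig


def extinction_from_absorbance(absorbance: Spectrum,
                               max_extinction: float) -> Spectrum:
    """Scale an absorbance spectrum so its peak equals ``max_extinction``.

    Absolute absorbance depends on concentration and path length; only the
    shape is needed because the known maximal extinction coefficient fixes
    the scale.  A flat or non-positive spectrum cannot be scaled.
    """
    if not max_extinction > 0:
        raise ParameterError("max_extinction must be positive")
    peak = float(np.max(absorbance.value))
    if peak <= 0 or np.ptp(absorbance.value) == 0:
        raise InvalidInputError("flat or empty absorbance spectrum")
    return Spectrum(absorbance.wavelength,
                    absorbance.value * (max_extinction / peak))


def ratio_a_efficiency(measurement: SpectralMeasurement) -> float:
    """(ratio)A FRET efficiency from one spectral measurement.

    May legitimately be <= 0 for constructs without energy transfer; the
    caller decides how to treat non-positive values.
    """
    cfg = measurement.config
    eps_d = extinction_from_absorbance(measurement.donor_absorbance,
                                       cfg.donor_max_extinction)
    eps_a = extinction_from_absorbance(measurement.acceptor_absorbance,
                                       cfg.acceptor_max_extinction)
    i_f = measurement.donor_excitation_scan.at(cfg.acceptor_em_nm)
    i_a = measurement.acceptor_excitation_scan.at(cfg.acceptor_em_nm)
    if i_a == 0:
        raise InvalidInputError(
            "acceptor-excited intensity at the emission peak is zero")
    eps_a_aex = eps_a.at(cfg.acceptor_ex_nm)
    eps_a_dex = eps_a.at(cfg.donor_ex_nm)
    eps_d_dex = eps_d.at(cfg.donor_ex_nm)
    if eps_d_dex <= 0 or eps_a_aex <= 0:
        raise InvalidInputError("non-positive extinction at an excitation "
                                "wavelength")
    return float((eps_a_aex / eps_d_dex)
                 * (i_f / i_a - eps_a_dex / eps_a_aex))
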