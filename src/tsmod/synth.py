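"""Synthetic data with known ground truth for every analysis input class.

Each generator is a pure function of its spec and seed (byte-identical
reruns) and returns, alongside the data object, a ground-truth record that
the test suite and the acceptance script consume.

What is emulated, and what is not: tabular FRET-length series carry
Gaussian replicate noise; image triplets follow the exact three-cube
algebra with optional Poisson shot noise (no read noise, no fixed-pattern
noise, no optical blur); spectra are smooth Gaussian bands satisfying the
(ratio)A identity at the peaks with the donor emission truncated before the
acceptor peak; gradient-FA images are noise-free geometric phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import LengthPoint, LengthSeries
from .errors import InvalidInputError, ParameterError
from .mechanics import ExtensibleDomain, SensorDesign, unloaded_fret
from .quantify import CorrectionSet, EfficiencyMap, ImageTriplet
from .spectra import (PAIR_SPECTRA, PairSpectralConfig, Spectrum,
                      SpectralMeasurement)

__all__ = [
    "SeriesSpec",
    "ImagingSpec",
    "make_length_series",
    "make_image_triplet",
    "make_bleedthrough_reference",
    "make_spectra",
    "make_gradient_fa_image",
]


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for a synthetic FRET-vs-length series."""

    true_lp: float
    repeat_sequence: str = "GGSGGS"
    n_repeats: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    noise_sd: float = 0.03      # per-replicate efficiency s.d.
    n_replicates: int = 9       # replicates averaged per length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.true_lp <= 0:
            raise ParameterError("true_lp must be positive")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


def make_length_series(spec: SeriesSpec, design_template: SensorDesign
                       ) -> tuple[LengthSeries, dict]:
    """Noisy FRET-length series from the mechanics model at known Lp.

    Each length simulates ``n_replicates`` measurements with Gaussian noise
    ``noise_sd`` and reports their mean with sem = noise_sd/sqrt(n), so
    that quoted uncertainties are consistent with the scatter of the means.
    """
    rng = np.random.default_rng(spec.seed)
    points = []
    truth_curve = {}
    for n_rep in spec.n_repeats:
        domain = ExtensibleDomain(spec.repeat_sequence, int(n_rep),
                                  design_template.domain.extra_residues,
                                  lp=spec.true_lp)
        design = SensorDesign(design_template.pair, domain,
                              design_template.env)
        e_true = unloaded_fret(design)
        truth_curve[int(n_rep)] = e_true
        if spec.noise_sd > 0:
            reps = rng.normal(e_true, spec.noise_sd, size=spec.n_replicates)
            mean = float(reps.mean())
        else:
            mean = e_true
        sem = spec.noise_sd / np.sqrt(spec.n_replicates)
        points.append(LengthPoint(int(n_rep), mean, float(sem)))
    series = LengthSeries("synthetic", spec.repeat_sequence, points)
    truth = {"true_lp_nm": spec.true_lp, "model_curve": truth_curve,
             "seed": spec.seed}
    return series, truth


@dataclass(frozen=True)
class ImagingSpec:
    """Recipe for a synthetic three-cube image triplet."""

    shape: tuple = (128, 128)
    efficiencies: tuple = (0.1, 0.2, 0.3)   # one blob per value
    background_efficiency: float = 0.0
    dbt: float = 0.12
    abt: float = 0.08
    g_factor: float = 2.8
    donor_scale: float = 5000.0
    acceptor_scale: float = 4000.0
    noise: str = "none"                     # "none" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= e < 1.0 for e in self.efficiencies):
            raise ParameterError("efficiencies must lie in [0, 1)")
        if self.noise not in ("none", "poisson"):
            raise InvalidInputError("noise must be 'none' or 'poisson'")


def _blob_field(spec: ImagingSpec, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant efficiency field: elliptical FA-like blobs on a
    uniform background.  Returns (E field, label image)."""
    h, w = spec.shape
    e_field = np.full(spec.shape, spec.background_efficiency)
    labels = np.zeros(spec.shape, dtype=int)
    rows, cols = np.mgrid[0:h, 0:w]
    n = len(spec.efficiencies)
    for i, e in enumerate(spec.efficiencies, start=1):
        cy = (i - 0.5) * h / n
        cx = w * (0.35 + 0.3 * rng.random())
        ry = max(3.0, h / (4 * n))
        rx = ry * (2.0 + rng.random())
        blob = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        e_field[blob] = e
        labels[blob] = i
    return e_field, labels


def make_image_triplet(spec: ImagingSpec
                       ) -> tuple[ImageTriplet, np.ndarray, dict]:
    """Synthetic triplet built with the same algebra the analysis inverts.

    The donor channel reports unquenched donors, Id = D*(1-E); sensitized
    emission is Fc = G*D*E so that Fc/(Fc + G*Id) = E identically; the
    acceptor channel is an independent abundance field; the FRET channel
    adds the bleed-through contributions.  Poisson noise (if requested)
    applies to each channel's expected counts.
    """
    rng = np.random.default_rng(spec.seed)
    e_field, labels = _blob_field(spec, rng)
    donor_abundance = np.full(spec.shape, spec.donor_scale)
    acceptor_abundance = np.full(spec.shape, spec.acceptor_scale)
    i_d = donor_abundance * (1.0 - e_field)
    fc_true = spec.g_factor * donor_abundance * e_field
    i_a = acceptor_abundance.copy()
    i_f = fc_true + spec.dbt * i_d + spec.abt * i_a
    if spec.noise == "poisson":
        i_d = rng.poisson(i_d).astype(float)
        i_a = rng.poisson(i_a).astype(float)
        i_f = rng.poisson(i_f).astype(float)
    triplet = ImageTriplet(i_a, i_f, i_d)
    truth = {
        "efficiency_field": e_field, "fc_true": fc_true,
        "dbt": spec.dbt, "abt": spec.abt, "g_factor": spec.g_factor,
        "seed": spec.seed, "noise": spec.noise,
    }
    return triplet, labels, truth


def make_bleedthrough_reference(spec: ImagingSpec, role: str,
                                ) -> ImageTriplet:
    """Donor-only or acceptor-only reference triplet for the given spec."""
    rng = np.random.default_rng(spec.seed + (1 if role == "donor" else 2))
    base = rng.uniform(0.2, 1.0, size=spec.shape)
    if role == "donor":
        i_d = spec.donor_scale * base
        i_f = spec.dbt * i_d
        i_a = np.zeros(spec.shape)
    elif role == "acceptor":
        i_a = spec.acceptor_scale * base
        i_f = spec.abt * i_a
        i_d = np.zeros(spec.shape)
    else:
        raise InvalidInputError("role must be 'donor' or 'acceptor'")
    if spec.noise == "poisson":
        i_f = rng.poisson(i_f).astype(float)
        if role == "donor":
            i_d = rng.poisson(i_d).astype(float)
        else:
            i_a = rng.poisson(i_a).astype(float)
    return ImageTriplet(i_a, i_f, i_d)


def make_spectra(true_e: float, pair: str | PairSpectralConfig = "clover-mruby2",
                 seed: int = 0, intensity_scale: float = 1.0,
                 ) -> tuple[SpectralMeasurement, dict]:
    """Synthetic fluorometer scans satisfying the (ratio)A identity.

    Absorbance bands are Gaussians peaking at the nominal excitation
    wavelengths; emission bands are Gaussians red-shifted from them, with
    the donor band truncated at 4 sigma so it cannot leak into the acceptor
    emission peak.  The donor-excited scan contains donor emission,
    sensitized acceptor emission proportional to E*eps_D(λDex), and direct
    acceptor excitation proportional to eps_A(λDex).
    """
    if not 0.0 <= true_e < 1.0:
        raise ParameterError("true_e must lie in [0, 1)")
    cfg = PAIR_SPECTRA[pair] if isinstance(pair, str) else pair
    rng = np.random.default_rng(seed)
    wl = np.arange(cfg.donor_ex_nm - 80.0, cfg.acceptor_em_nm + 120.0, 1.0)

    def band(center, sigma, truncate=None):
        v = np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        if truncate is not None:
            v = np.where(wl > truncate, 0.0, v)
        return v

    donor_abs = band(cfg.donor_ex_nm, 18.0)
    acceptor_abs = band(cfg.acceptor_ex_nm, 16.0)
    donor_em = band(cfg.donor_ex_nm + 20.0, 12.0,
                    truncate=cfg.donor_ex_nm + 68.0)
    acceptor_em = band(cfg.acceptor_em_nm, 14.0)

    eps_d_dex = cfg.donor_max_extinction * 1.0            # peak at λDex
    eps_a_aex = cfg.acceptor_max_extinction * 1.0         # peak at λAex
    eps_a_dex = cfg.acceptor_max_extinction * float(
        np.interp(cfg.donor_ex_nm, wl, acceptor_abs))

    concentration = intensity_scale * (0.8 + 0.4 * rng.random())
    # acceptor-excited scan: direct acceptor emission only
    i_acceptor_scan = concentration * eps_a_aex * acceptor_em
    # donor-excited scan: donor emission + sensitized + direct acceptor
    donor_quantum = 0.7
    i_donor_scan = concentration * (
        (1.0 - true_e) * eps_d_dex * donor_quantum * donor_em
        + (true_e * eps_d_dex + eps_a_dex) * acceptor_em)

    meas = SpectralMeasurement(
        donor_excitation_scan=Spectrum(wl, i_donor_scan),
        acceptor_excitation_scan=Spectrum(wl, i_acceptor_scan),
        donor_absorbance=Spectrum(wl, donor_abs * concentration),
        acceptor_absorbance=Spectrum(wl, acceptor_abs * concentration),
        config=cfg,
    )
    truth = {"true_e": true_e, "seed": seed,
             "eps_a_dex_over_aex": eps_a_dex / eps_a_aex}
    return meas, truth


def make_gradient_fa_image(n_fas: int = 8, slope_percent_per_fa: float = 15.0,
                           e_mid: float = 0.18, shape: tuple = (192, 192),
                           seed: int = 0,
                           ) -> tuple[EfficiencyMap, np.ndarray, dict]:
    """Elongated FA phantoms with linear axial efficiency gradients.

    Each FA is a horizontal bar whose efficiency rises linearly from
    ``e_mid - slope/2`` at the distal tip to ``e_mid + slope/2`` (slope in
    percentage points per normalised FA length).  Returns an
    :class:`EfficiencyMap`, the label image and the ground truth.
    """
    if not np.isfinite(slope_percent_per_fa):
        raise ParameterError("slope must be finite")
    rng = np.random.default_rng(seed)
    h, w = shape
    eff = np.full(shape, np.nan)
    labels = np.zeros(shape, dtype=int)
    half = slope_percent_per_fa / 200.0
    for i in range(1, n_fas + 1):
        for _ in range(200):  # redraw until the bar does not touch another FA
            length = int(rng.integers(25, 45))
            width = int(rng.integers(4, 7))
            r0 = int(rng.integers(2, h - width - 2))
            c0 = int(rng.integers(2, w - length - 2))
            patch = labels[r0 - 1:r0 + width + 1, c0 - 1:c0 + length + 1]
            if np.all(patch == 0):
                break
        else:
            raise InvalidInputError("could not place all FAs without overlap; "
                                    "reduce n_fas or enlarge the image")
        axial = np.linspace(e_mid - half, e_mid + half, length)
        for dr in range(width):
            labels[r0 + dr, c0:c0 + length] = i
            eff[r0 + dr, c0:c0 + length] = axial
    valid = ~np.isnan(eff)
    emap = EfficiencyMap(fc=np.where(valid, 1.0, 0.0), efficiency=eff,
                         valid_mask=valid, negative_mask=np.zeros(shape, bool))
    truth = {"slope_percent_per_fa": slope_percent_per_fa, "e_mid": e_mid,
             "n_fas": n_fas, "seed": seed}
    return emap, labels, truth
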