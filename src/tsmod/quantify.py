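"""Quantitative FRET efficiency from three-cube sensitized-emission imaging.

Three images are acquired per field: the acceptor channel ``Ia`` (acceptor
excitation/emission), the FRET channel ``If`` (donor excitation, acceptor
emission) and the donor channel ``Id`` (donor excitation/emission).  The
FRET channel contains, besides true sensitized emission, donor emission
bleeding through the acceptor filter (fraction ``dbt`` of Id) and directly
excited acceptor (fraction ``abt`` of Ia).  The corrected FRET image is

    Fc = If - dbt*Id - abt*Ia

and the pixelwise efficiency

    E = Fc / (Fc + G*Id),

where the G factor converts donor quenching into equivalent sensitized
emission units; it is instrument- and pair-specific and is calibrated from
donor-acceptor fusion constructs of known, constant efficiency.

Focal adhesions are summarised from a label mask (produced externally or by
the naive threshold segmenter here), and axial line scans across
length-normalised FAs yield the slope metric (% efficiency per FA length)
used to compare sensor designs in cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EstimationError, InvalidInputError, ParameterError

__all__ = [
    "ImageTriplet",
    "CorrectionSet",
    "EfficiencyMap",
    "FaRecord",
    "estimate_bleedthrough",
    "corrected_fret",
    "efficiency_map",
    "estimate_g_factor",
    "summarize_fas",
    "line_scan_slope",
    "extract_axial_profiles",
    "records_to_dataframe",
    "threshold_segment",
    "ACCEPTOR_GATES",
]

#: published acceptor-channel intensity gates per FRET pair
ACCEPTOR_GATES = {
    "mtfp1-venus": (1000.0, 40000.0),
    "clover-mruby2": (600.0, 24000.0),
}


@dataclass
class ImageTriplet:
    """Background-subtracted, registered acceptor/FRET/donor images."""

    acceptor: np.ndarray
    fret: np.ndarray
    donor: np.ndarray
    pixel_size: float = 0.108  # um/pixel
    exposure_ms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        if not (self.acceptor.shape == self.fret.shape == self.donor.shape):
            raise InvalidInputError("the three images must share a shape")
        if self.acceptor.ndim != 2:
            raise InvalidInputError("images must be 2-D")
        self.clipped = bool(np.any(self.acceptor < 0) or
                            np.any(self.fret < 0) or np.any(self.donor < 0))
        if self.clipped:
            self.acceptor = np.clip(self.acceptor, 0.0, None)
            self.fret = np.clip(self.fret, 0.0, None)
            self.donor = np.clip(self.donor, 0.0, None)

    @classmethod
    def from_tiffs(cls, acceptor_path, fret_path, donor_path,
                   pixel_size: float = 0.108) -> "ImageTriplet":
        import tifffile

        return cls(tifffile.imread(acceptor_path),
                   tifffile.imread(fret_path),
                   tifffile.imread(donor_path), pixel_size=pixel_size)


@dataclass(frozen=True)
class CorrectionSet:
    """Spectral bleed-through fractions and the G proportionality factor."""

    dbt: float
    abt: float
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dbt < 1.0) or not (0.0 <= self.abt < 1.0):
            raise ParameterError("bleed-through fractions must be in [0, 1)")
        if not self.g_factor > 0:
            raise ParameterError("g_factor must be positive")

    def to_dict(self) -> dict:
        return {"dbt": self.dbt, "abt": self.abt, "g_factor": self.g_factor}

    @classmethod
    def from_dict(cls, d) -> "CorrectionSet":
        return cls(float(d["dbt"]), float(d["abt"]),
                   float(d.get("g_factor", 1.0)))


@dataclass
class EfficiencyMap:
    """Pixelwise corrected FRET and efficiency with a validity mask."""

    fc: np.ndarray
    efficiency: np.ndarray
    valid_mask: np.ndarray
    negative_mask: np.ndarray  # flagged (not clipped) negative Fc pixels


def estimate_bleedthrough(triplets: Sequence[ImageTriplet], role: str,
                          bins: int = 20, min_intensity: float = 0.0
                          ) -> float:
    """Bleed-through fraction from single-fluorophore reference samples.

    ``role='donor'`` uses the ratio If/Id of donor-only samples binned by
    donor intensity; ``role='acceptor'`` uses If/Ia binned by acceptor
    intensity.  Per-bin medians (robust to shot noise) are combined by an
    intensity-weighted average.
    """
    if role not in ("donor", "acceptor"):
        raise InvalidInputError("role must be 'donor' or 'acceptor'")
    if not triplets:
        raise InvalidInputError("need at least one reference triplet")
    refs, frets = [], []
    for t in triplets:
        ref = t.donor if role == "donor" else t.acceptor
        refs.append(ref.ravel())
        frets.append(t.fret.ravel())
    ref = np.concatenate(refs)
    fr = np.concatenate(frets)
    sel = ref > min_intensity
    if not np.any(sel):
        raise EstimationError(f"all {role} reference pixels are empty")
    ref, fr = ref[sel], fr[sel]
    if np.all(fr == 0):
        return 0.0
    # equal-count intensity bins
    order = np.argsort(ref)
    edges = np.array_split(order, max(1, min(bins, len(order))))
    meds, weights = [], []
    for idx in edges:
        if len(idx) == 0:
            continue
        meds.append(np.median(fr[idx] / ref[idx]))
        weights.append(ref[idx].sum())
    coeff = float(np.average(meds, weights=weights))
    if not 0.0 <= coeff < 1.0:
        raise EstimationError(
            f"estimated {role} bleed-through {coeff:.3f} outside [0, 1)")
    return coeff


def corrected_fret(triplet: ImageTriplet,
                   corrections: CorrectionSet) -> np.ndarray:
    """Bleed-through-corrected FRET image Fc = If - dbt*Id - abt*Ia.

    Negative values are retained (they carry noise information) — consumers
    flag them via :class:`EfficiencyMap`.
    """
    return (triplet.fret - corrections.dbt * triplet.donor
            - corrections.abt * triplet.acceptor)


def efficiency_map(triplet: ImageTriplet, corrections: CorrectionSet,
                   gates: tuple[float, float] | None = None) -> EfficiencyMap:
    """Pixelwise E = Fc/(Fc + G*Id), gated on acceptor intensity.

    Pixels whose acceptor intensity falls outside ``gates`` (lo, hi), or
    where the denominator vanishes, are marked invalid rather than raising.
    """
    fc = corrected_fret(triplet, corrections)
    denom = fc + corrections.g_factor * triplet.donor
    valid = denom != 0.0
    if gates is not None:
        lo, hi = gates
        valid &= (triplet.acceptor >= lo) & (triplet.acceptor <= hi)
    eff = np.full(fc.shape, np.nan)
    eff[valid] = fc[valid] / denom[valid]
    return EfficiencyMap(fc, eff, valid, fc < 0.0)


def estimate_g_factor(constructs: Sequence[tuple[ImageTriplet, float]],
                      corrections: CorrectionSet,
                      min_spread: float = 0.02) -> float:
    """G factor from fusion constructs of known constant efficiency.

    For each construct the mean corrected FRET and donor intensities give
    one constraint E_known = Fc/(Fc + G*Id); G is the least-squares solution
    across constructs.  At least two constructs with efficiencies differing
    by ``min_spread`` are required.
    """
    from scipy.optimize import minimize_scalar

    if len(constructs) < 2:
        raise InvalidInputError("need >= 2 constructs of known efficiency")
    known = np.array([e for _, e in constructs])
    if np.ptp(known) < min_spread:
        raise EstimationError(
            "constructs have indistinguishable efficiencies; G is "
            "ill-conditioned")
    fcs, ids = [], []
    for t, _ in constructs:
        fc = corrected_fret(t, corrections)
        sel = t.donor > 0
        fcs.append(fc[sel].mean())
        ids.append(t.donor[sel].mean())
    fcs, ids = np.array(fcs), np.array(ids)
    # per-construct closed form as starting bracket
    g_each = fcs * (1.0 - known) / (known * ids)
    if np.any(g_each <= 0):
        raise EstimationError("non-positive per-construct G; check "
                              "corrections and background subtraction")

    def obj(g):
        pred = fcs / (fcs + g * ids)
        return float(np.sum((pred - known) ** 2))

    lo, hi = 0.25 * g_each.min(), 4.0 * g_each.max()
    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


@dataclass
class FaRecord:
    """Morphology and loading summary of one segmented focal adhesion."""

    label: int
    area_um2: float
    axis_ratio: float
    mean_acceptor: float
    mean_efficiency: float
    centroid: tuple[float, float]
    n_pixels: int
    flag_above_unloaded: bool = False

    def to_dict(self) -> dict:
        return {
            "id": self.label, "area_um2": self.area_um2,
            "axis_ratio": self.axis_ratio,
            "mean_acceptor": self.mean_acceptor,
            "mean_efficiency": self.mean_efficiency,
            "centroid_row": self.centroid[0],
            "centroid_col": self.centroid[1],
            "n_pixels": self.n_pixels,
            "flag_above_unloaded": self.flag_above_unloaded,
        }


def threshold_segment(acceptor: np.ndarray, threshold: float | None = None,
                      min_pixels: int = 4) -> np.ndarray:
    """Naive intensity-threshold FA segmentation (label image).

    A stand-in for dedicated FA segmentation software: Otsu threshold (or a
    fixed one), connected components, small objects dropped.
    """
    from skimage import filters, measure, morphology

    if threshold is None:
        threshold = filters.threshold_otsu(acceptor)
    mask = acceptor > threshold
    mask = morphology.remove_small_objects(mask, max_size=min_pixels - 1)
    return measure.label(mask)


def summarize_fas(emap: EfficiencyMap, labels: np.ndarray,
                  triplet: ImageTriplet, min_area_um2: float = 0.0,
                  min_axis_ratio: float = 1.0,
                  e_unloaded: float | None = None) -> list[FaRecord]:
    """Per-FA statistics from a label mask aligned to the efficiency map.

    Filters follow the conventions used for sensor-gradient analyses:
    ``min_area_um2 = 0.5`` and ``min_axis_ratio = 1.5`` select single,
    elongated FAs.  Pixels failing the map's validity gate never contribute.
    If ``e_unloaded`` is given, FAs whose mean efficiency exceeds it (an
    apparent negative load) are flagged.
    """
    from skimage import measure

    labels = np.asarray(labels)
    if labels.shape != emap.efficiency.shape:
        raise InvalidInputError("label mask must match the efficiency map")
    if labels.max() == 0:
        warnings.warn("empty FA mask; no records produced")
        return []
    px_area = triplet.pixel_size ** 2
    records = []
    for rp in measure.regionprops(labels):
        sel = (labels == rp.label) & emap.valid_mask
        n_px = int(sel.sum())
        if n_px == 0:
            continue
        area = rp.area * px_area
        minor = rp.axis_minor_length
        axis_ratio = rp.axis_major_length / minor if minor > 0 else np.inf
        if area < min_area_um2 or axis_ratio < min_axis_ratio:
            continue
        mean_e = float(emap.efficiency[sel].mean())
        rec = FaRecord(
            label=int(rp.label), area_um2=float(area),
            axis_ratio=float(axis_ratio),
            mean_acceptor=float(triplet.acceptor[sel].mean()),
            mean_efficiency=mean_e, centroid=tuple(rp.centroid),
            n_pixels=n_px,
            flag_above_unloaded=(e_unloaded is not None
                                 and mean_e > e_unloaded))
        records.append(rec)
    return records


def records_to_dataframe(records: Iterable[FaRecord]):
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in records])


def line_scan_slope(profiles: Sequence[np.ndarray], n_samples: int = 50
                    ) -> float:
    """Efficiency slope across length-normalised FA profiles, in %/FA.

    Each profile is an axial efficiency trace starting at the FA tip distal
    to the cell body.  Profiles are resampled onto a common [0, 1]
    normalised-length axis, averaged, and fitted by least squares; the
    returned slope is in percentage points of efficiency per FA length.
    Profiles with fewer than 3 samples are skipped with a warning.
    """
    kept = []
    for p in profiles:
        p = np.asarray(p, dtype=float)
        p = p[np.isfinite(p)]
        if len(p) < 3:
            warnings.warn("profile with < 3 samples skipped")
            continue
        x = np.linspace(0.0, 1.0, len(p))
        xs = np.linspace(0.0, 1.0, n_samples)
        kept.append(np.interp(xs, x, p))
    if not kept:
        raise InvalidInputError("no usable profiles (need >= 3 samples each)")
    mean_profile = np.mean(kept, axis=0)
    xs = np.linspace(0.0, 1.0, n_samples)
    slope = np.polyfit(xs, mean_profile, 1)[0]
    return float(slope * 100.0)


def extract_axial_profiles(emap: EfficiencyMap, labels: np.ndarray,
                           min_length: int = 3) -> list[np.ndarray]:
    """Axial efficiency profiles of labelled FAs along their major axes.

    Pixels are projected onto each region's major axis and averaged in
    integer steps along it, producing one 1-D profile per FA (distal tip
    first, i.e. ascending projected coordinate).
    """
    from skimage import measure

    profiles = []
    for rp in measure.regionprops(np.asarray(labels)):
        coords = rp.coords
        sel = emap.valid_mask[coords[:, 0], coords[:, 1]]
        coords = coords[sel]
        if len(coords) < min_length:
            continue
        centred = coords - coords.mean(axis=0)
        angle = rp.orientation
        # unit vector along the major axis (row, col convention)
        axis = np.array([-np.cos(angle), np.sin(angle)])
        proj = centred @ axis
        order = np.argsort(proj)
        proj = proj[order]
        vals = emap.efficiency[coords[order, 0], coords[order, 1]]
        n_steps = max(int(np.ceil(proj[-1] - proj[0])) + 1, min_length)
        bins = np.linspace(proj[0], proj[-1] + 1e-9, n_steps + 1)
        prof = []
        for i in range(n_steps):
            m = (proj >= bins[i]) & (proj < bins[i + 1])
            if np.any(m):
                prof.append(vals[m].mean())
        if len(prof) >= min_length:
            profiles.append(np.array(prof))
    return profiles
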