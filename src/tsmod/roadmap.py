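"""Sensor performance metrics and design-space sweeps.

Three numbers summarise how useful a tension sensor is in a given force
regime:

* ``delta_fret`` — dynamic range: the drop in FRET efficiency from the
  unloaded state down to the experimentally motivated 5% noise floor;
* ``f_target`` — the midpoint of the functional force range, half the force
  at which the efficiency hits the noise floor;
* ``rz_target`` — the analogous midpoint extension.

Sweeping these metrics over persistence length and chain length for a FRET
pair produces a design roadmap: a look-up table from which a sensor with a
prescribed force or extension sensitivity can be read off directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, ParameterError
from .mechanics import (ExtensibleDomain, FluorophorePair, ForceResponse,
                        PolymerEnvironment, SensorDesign, fret_at_distance,
                        force_response, unloaded_fret)

__all__ = [
    "SensorMetrics",
    "RoadmapGrid",
    "compute_metrics",
    "sensitivity_curve",
    "generate_roadmap",
    "fret_to_force_extension",
    "DEFAULT_NOISE_FLOOR",
]

DEFAULT_NOISE_FLOOR = 0.05
_FORCE_MAX = 50.0  # pN; beyond any physiological single-molecule load


@dataclass
class SensorMetrics:
    """Performance summary of one design at a given noise floor."""

    e_unloaded: float
    noise_floor: float
    delta_fret: float
    f_floor: float      # pN where E = noise_floor (inf if unreachable)
    f_target: float     # f_floor / 2
    rz_floor: float     # nm extension at f_floor
    rz_target: float    # rz_floor / 2
    floor_reachable: bool

    def to_dict(self) -> dict:
        return {
            "e_unloaded": self.e_unloaded,
            "noise_floor": self.noise_floor,
            "delta_fret": self.delta_fret,
            "f_floor_pN": self.f_floor,
            "f_target_pN": self.f_target,
            "rz_floor_nm": self.rz_floor,
            "rz_target_nm": self.rz_target,
            "floor_reachable": self.floor_reachable,
        }


@dataclass
class RoadmapGrid:
    """Metrics over an (Lp, chain length) grid for one FRET pair."""

    pair: FluorophorePair
    lp_grid: np.ndarray
    length_grid: np.ndarray  # residue counts
    metrics: list[list[SensorMetrics]]
    noise_floor: float

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, lp in enumerate(self.lp_grid):
            for j, n in enumerate(self.length_grid):
                m = self.metrics[i][j]
                rows.append({
                    "lp_nm": lp, "n_residues": int(n),
                    "e_unloaded": m.e_unloaded,
                    "delta_fret": m.delta_fret,
                    "f_target_pN": m.f_target,
                    "rz_target_nm": m.rz_target,
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _response_curve(design: SensorDesign, f_max: float = _FORCE_MAX,
                    n_points: int = 241) -> ForceResponse:
    # denser at low force where E(F) bends fastest
    grid = np.concatenate([
        np.linspace(0.0, 2.0, 81)[:-1],
        np.geomspace(2.0, f_max, n_points - 80),
    ])
    return force_response(design, grid)


def compute_metrics(design: SensorDesign,
                    noise_floor: float = DEFAULT_NOISE_FLOOR,
                    response: ForceResponse | None = None) -> SensorMetrics:
    """Dynamic range, target force and target extension of a design.

    The floor crossing E(F) = noise_floor is solved by bisection on the
    monotone efficiency curve.  If the unloaded efficiency is already at or
    below the floor the dynamic range is zero, and if even a fully stretched
    chain stays above the floor (very short, high-R0 designs) the force
    metrics are reported as inf with ``floor_reachable = False``.
    """
    if not 0.0 < noise_floor < 1.0:
        raise ParameterError("noise_floor must lie in (0, 1)")
    e0 = unloaded_fret(design)
    if e0 <= noise_floor:
        return SensorMetrics(e0, noise_floor, 0.0, np.nan, np.nan,
                             np.nan, np.nan, False)
    # the efficiency cannot fall below that of the fully stretched chain
    e_limit = fret_at_distance(
        design.contour_length + 2 * design.pair.r_fluor, design.pair.r0)
    if e_limit >= noise_floor:
        return SensorMetrics(e0, noise_floor, e0 - noise_floor,
                             np.inf, np.inf, np.inf, np.inf, False)
    fr = response if response is not None else _response_curve(design)
    eff, grid, ext = fr.efficiency, fr.force_grid, fr.extension
    if eff[-1] > noise_floor:  # extend search range once
        fr = _response_curve(design, f_max=4 * grid[-1])
        eff, grid, ext = fr.efficiency, fr.force_grid, fr.extension
        if eff[-1] > noise_floor:
            return SensorMetrics(e0, noise_floor, e0 - noise_floor,
                                 np.inf, np.inf, np.inf, np.inf, False)
    # bisection between bracketing grid nodes on the exact model
    k = int(np.searchsorted(-eff, -noise_floor))
    lo, hi = grid[k - 1], grid[k]
    from .mechanics import loaded_fret

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if hi - lo < 1e-6:
            break
        if loaded_fret(design, mid) > noise_floor:
            lo = mid
        else:
            hi = mid
    f_floor = 0.5 * (lo + hi)
    rz_floor = float(np.interp(f_floor, grid, ext))
    return SensorMetrics(e0, noise_floor, e0 - noise_floor, f_floor,
                         f_floor / 2.0, rz_floor, rz_floor / 2.0, True)


def sensitivity_curve(design: SensorDesign, force_grid=None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """|dE/dF| along the force response; returns (force_grid, |dE/dF|)."""
    if force_grid is None:
        fr = _response_curve(design)
    else:
        fr = force_response(design, force_grid)
    dedf = np.abs(np.gradient(fr.efficiency, fr.force_grid))
    return fr.force_grid, dedf


def generate_roadmap(pair: FluorophorePair, lp_grid=None, length_grid=None,
                     noise_floor: float = DEFAULT_NOISE_FLOOR,
                     env: PolymerEnvironment | None = None,
                     repeat_unit: str = "GGSGGS") -> RoadmapGrid:
    """Metrics for every (persistence length, chain length) combination.

    Defaults cover the published range of unstructured-polypeptide
    mechanics: Lp log-spaced over (0.1, 10) nm and lengths 6..96 residues in
    steps of 6.  Values outside those bounds are allowed but warned about.
    """
    import warnings

    if lp_grid is None:
        lp_grid = np.geomspace(0.1, 10.0, 25)
    if length_grid is None:
        length_grid = np.arange(6, 97, 6)
    lp_grid = np.asarray(lp_grid, dtype=float)
    length_grid = np.asarray(length_grid, dtype=int)
    if lp_grid.size == 0 or length_grid.size == 0:
        raise InvalidInputError("roadmap grids must be non-empty")
    if lp_grid.min() < 0.1 or lp_grid.max() > 10.0:
        warnings.warn("lp_grid extends beyond the documented (0.1, 10) nm "
                      "range of reported polypeptide mechanics")
    if length_grid.max() >= 100:
        warnings.warn("length_grid extends beyond the documented < 100 "
                      "residue range")
    env = env or PolymerEnvironment.in_cellulo()
    metrics = []
    for lp in lp_grid:
        row = []
        for n_res in length_grid:
            domain = ExtensibleDomain(repeat_unit, 1,
                                      extra_residues=int(n_res) - len(repeat_unit),
                                      lp=float(lp))
            design = SensorDesign(pair, domain, env)
            row.append(compute_metrics(design, noise_floor))
        metrics.append(row)
    return RoadmapGrid(pair, lp_grid, length_grid, metrics, noise_floor)


@dataclass
class ForceExtensionResult:
    """Per-input force/extension with negative-load flags."""

    efficiency: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    negative: np.ndarray  # True where efficiency exceeded the unloaded value

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "efficiency": self.efficiency, "force_pN": self.force,
            "extension_nm": self.extension, "negative_flag": self.negative,
        })


def fret_to_force_extension(efficiencies, design: SensorDesign,
                            response: ForceResponse | None = None
                            ) -> ForceExtensionResult:
    """Invert the calibration curve: measured E -> (force, extension).

    Efficiencies above the unloaded value have no non-negative force
    solution; they are mapped by linear extrapolation of the curve at F = 0
    and flagged (cellular analyses typically exclude them).
    """
    e = np.asarray(efficiencies, dtype=float)
    if np.any((e <= 0.0) | (e >= 1.0)):
        raise InvalidInputError("efficiencies must lie strictly in (0, 1)")
    from scipy.interpolate import PchipInterpolator

    fr = response if response is not None else _response_curve(design)
    eff, grid, ext = fr.efficiency, fr.force_grid, fr.extension
    # E(F) is strictly decreasing: invert with a monotone spline on the
    # reversed arrays (linear extrapolation beyond the tabulated curve)
    f_of_e = PchipInterpolator(eff[::-1], grid[::-1], extrapolate=False)
    force = f_of_e(e)
    slope0 = (grid[1] - grid[0]) / (eff[1] - eff[0])
    above = e > eff[0]
    force[above] = grid[0] + (e[above] - eff[0]) * slope0
    below = e < eff[-1]
    slope1 = (grid[-1] - grid[-2]) / (eff[-1] - eff[-2])
    force[below] = grid[-1] + (e[below] - eff[-1]) * slope1
    ext_of_f = PchipInterpolator(grid, ext, extrapolate=False)
    extension = np.where((force >= grid[0]) & (force <= grid[-1]),
                         ext_of_f(np.clip(force, grid[0], grid[-1])), np.nan)
    dext0 = (ext[1] - ext[0]) / (grid[1] - grid[0])
    neg = force < grid[0]
    extension[neg] = force[neg] * dext0
    high = force > grid[-1]
    dext1 = (ext[-1] - ext[-2]) / (grid[-1] - grid[-2])
    extension[high] = ext[-1] + (force[high] - grid[-1]) * dext1
    return ForceExtensionResult(e, force, extension, above)
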