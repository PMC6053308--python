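"""Structural spring-network model of force- vs extension-control in FAs.

A focal adhesion is idealised as a stratified stack of molecular layers:
each layer is a parallel bundle of elastic elements (sensors 'S' — the
tagged protein — and linkers 'L' — everything else load-bearing), and the
layers are connected in series between the cytoskeleton and the substrate.
Elements are linear springs; randomness enters only through the seeded
placement of elements across layers.  For regime classification the sensors
occupy their protein's characteristic stratum (layer 0) — adhesions are
nanoscopically stratified, with each protein at a defined height — while
the heterogeneous linkers scatter across layers.

Two bulk inputs are supported, with different load-sharing physics:

* ``extension`` — a rigid displacement clamp (e.g. a defined myosin step or
  an actin polymerisation increment).  Kinematic coupling: all elements in
  a layer share the layer extension, and the layer extensions partition the
  bulk extension in inverse proportion to layer stiffness.
* ``force`` — a bulk force transmitted through the stack.  Force balance
  requires every layer to transmit the full input; within a layer the
  molecular coupling is taken as compliant (fluid-like), so the parallel
  elements share the transmitted force equally rather than in proportion to
  their stiffness.  This reproduces the observation that a pure force input
  always appears force-controlled at the sensor, regardless of composition.

Classification mirrors the three-sensor experiment: the ensemble is run
with a trio of sensor-stiffness multipliers (0.5x, 1x, 2x) — three sensor
variants expressed in otherwise identical structures — and the regime is
read from the coefficient of variation of the per-variant *mean* sensor
force versus mean sensor extension: a force-controlled system hands the
variants the same force distribution, an extension-controlled one the same
extension distribution.  (With a single sensor stiffness a linear spring's
force and extension are exactly proportional, so no single-variant
dispersion statistic could separate the regimes.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, ParameterError

__all__ = [
    "FaNetwork",
    "LoadInput",
    "LoadResult",
    "ControlClassification",
    "build_network",
    "solve_load",
    "ensemble_classify",
    "stiffness_force_relation",
    "DEFAULT_TRIO",
]

DEFAULT_TRIO = (0.5, 1.0, 2.0)
REGIME_MARGIN = 2.0  # cv ratio needed to call a regime


@dataclass(frozen=True)
class Element:
    kind: str      # "S" or "L"
    stiffness: float


@dataclass
class FaNetwork:
    """Two-layer (by default) sensor/linker spring assembly."""

    layers: list[list[Element]]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.layers or any(len(layer) == 0 for layer in self.layers):
            raise InvalidInputError("every layer must contain >= 1 element")
        if any(e.stiffness <= 0 for layer in self.layers for e in layer):
            raise ParameterError("all stiffnesses must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_stiffness(self) -> np.ndarray:
        return np.array([sum(e.stiffness for e in layer)
                         for layer in self.layers])

    def counts(self) -> dict:
        out = {"S": 0, "L": 0}
        for layer in self.layers:
            for e in layer:
                out[e.kind] += 1
        return out


@dataclass(frozen=True)
class LoadInput:
    mode: str        # "force" (pN) or "extension" (nm)
    magnitude: float

    def __post_init__(self) -> None:
        if self.mode not in ("force", "extension"):
            raise InvalidInputError("mode must be 'force' or 'extension'")
        if self.magnitude < 0:
            raise ParameterError("magnitude must be >= 0")


@dataclass
class LoadResult:
    """Per-element loads, checked for balance and compatibility."""

    element_kind: list[str]
    element_layer: np.ndarray
    element_stiffness: np.ndarray
    element_force: np.ndarray
    element_extension: np.ndarray
    layer_extension: np.ndarray
    total_force: float
    total_extension: float

    def sensor_mask(self) -> np.ndarray:
        return np.array([k == "S" for k in self.element_kind])


def build_network(n_sensor: int, n_linker: int, k_sensor: float,
                  k_linker: float, n_layers: int = 2,
                  seed: int | None = None, stratified: bool = False,
                  max_tries: int = 100) -> FaNetwork:
    """Randomly place sensors and linkers among ``n_layers`` layers.

    By default every element is assigned a uniform random layer (seeded).
    With ``stratified=True`` the sensors are pinned to layer 0 — their
    protein's characteristic stratum in the adhesion — and only the linkers
    are scattered; this is the placement used for regime classification.
    Arrangements that leave a layer empty are redrawn, up to ``max_tries``.
    """
    if n_sensor < 0 or n_linker < 0 or n_sensor + n_linker < n_layers:
        raise InvalidInputError(
            "need n_sensor + n_linker >= n_layers with non-negative counts")
    if k_sensor <= 0 or k_linker <= 0:
        raise ParameterError("stiffnesses must be positive")
    if n_layers < 1:
        raise InvalidInputError("need at least one layer")
    rng = np.random.default_rng(seed)
    sensors = [Element("S", k_sensor)] * n_sensor
    linkers = [Element("L", k_linker)] * n_linker
    for _ in range(max_tries):
        layers = [[] for _ in range(n_layers)]
        if stratified and n_sensor:
            for el in sensors:
                layers[0].append(el)
            assignment = rng.integers(0, n_layers, size=n_linker)
            for el, a in zip(linkers, assignment):
                layers[a].append(el)
        else:
            elements = sensors + linkers
            assignment = rng.integers(0, n_layers, size=len(elements))
            for el, a in zip(elements, assignment):
                layers[a].append(el)
        if all(layers):
            return FaNetwork(layers, seed=seed)
    raise InvalidInputError(
        f"could not draw a placement filling all {n_layers} layers")


def solve_load(network: FaNetwork, load: LoadInput) -> LoadResult:
    """Linear-elastic solution of the layered network under a bulk input."""
    k_layer = network.layer_stiffness()
    if np.any(k_layer <= 0):
        raise ParameterError("zero-stiffness layer")
    compliance = float(np.sum(1.0 / k_layer))

    kinds, layer_idx, ks = [], [], []
    for j, layer in enumerate(network.layers):
        for e in layer:
            kinds.append(e.kind)
            layer_idx.append(j)
            ks.append(e.stiffness)
    layer_idx = np.array(layer_idx)
    ks = np.array(ks)

    if load.mode == "extension":
        total_ext = load.magnitude
        f_trans = total_ext / compliance
        layer_ext = f_trans / k_layer
        el_ext = layer_ext[layer_idx]
        el_force = ks * el_ext
        total_force = f_trans
    else:
        total_force = load.magnitude
        counts = np.array([len(layer) for layer in network.layers])
        el_force = (total_force / counts)[layer_idx]
        el_ext = el_force / ks
        # layer extension under compliant sharing: mean element extension
        layer_ext = np.array([el_ext[layer_idx == j].mean()
                              for j in range(network.n_layers)])
        total_ext = float(layer_ext.sum())

    res = LoadResult(kinds, layer_idx, ks, el_force, el_ext, layer_ext,
                     float(total_force), float(total_ext))
    _check_invariants(res, network, load)
    return res


def _check_invariants(res: LoadResult, network: FaNetwork,
                      load: LoadInput) -> None:
    # each layer transmits the full load
    for j in range(network.n_layers):
        sel = res.element_layer == j
        np.testing.assert_allclose(res.element_force[sel].sum(),
                                   res.total_force, rtol=1e-9, atol=1e-12)
    if load.mode == "extension":
        # kinematic compatibility within layers and overall
        for j in range(network.n_layers):
            sel = res.element_layer == j
            assert np.ptp(res.element_extension[sel]) < 1e-12 + \
                1e-9 * abs(res.layer_extension[j])
        np.testing.assert_allclose(res.layer_extension.sum(),
                                   res.total_extension, rtol=1e-9, atol=1e-12)


@dataclass
class ControlClassification:
    """Across-variant dispersion of mean sensor loads."""

    cv_force: float        # CV of mean sensor force across the variant trio
    cv_extension: float    # CV of mean sensor extension across the trio
    regime: str   # "force-controlled" | "extension-controlled" | "mixed"
    n_sensors: int

    @staticmethod
    def from_variant_means(mean_forces, mean_extensions, n_sensors: int,
                           margin: float = REGIME_MARGIN,
                           ) -> "ControlClassification":
        mf = np.asarray(mean_forces, dtype=float)
        mx = np.asarray(mean_extensions, dtype=float)
        cv_f = float(np.std(mf) / np.mean(mf))
        cv_x = float(np.std(mx) / np.mean(mx))
        if cv_f * margin < cv_x:
            regime = "force-controlled"
        elif cv_x * margin < cv_f:
            regime = "extension-controlled"
        else:
            regime = "mixed"
        return ControlClassification(cv_f, cv_x, regime, n_sensors)


def _ensemble_sensor_loads(n_sensor: int, n_linker: int, k_sensor: float,
                           k_linker: float, load: LoadInput,
                           n_realizations: int, rng: np.random.Generator,
                           trio: Sequence[float], n_layers: int = 2,
                           ) -> list[dict]:
    """Per-variant pooled sensor loads over seeded stratified networks.

    Returns one record per sensor-stiffness multiplier in ``trio`` with the
    pooled sensor forces and extensions over ``n_realizations`` placements.
    """
    out = []
    for mult in trio:
        forces, exts = [], []
        for _ in range(n_realizations):
            net = build_network(n_sensor, n_linker, mult * k_sensor,
                                k_linker, n_layers=n_layers, stratified=True,
                                seed=int(rng.integers(2 ** 31)))
            res = solve_load(net, load)
            m = res.sensor_mask()
            forces.append(res.element_force[m])
            exts.append(res.element_extension[m])
        out.append({"multiplier": mult,
                    "forces": np.concatenate(forces),
                    "extensions": np.concatenate(exts)})
    return out


def ensemble_classify(compositions: Iterable[dict], load: LoadInput,
                      n_realizations: int = 200, seed: int = 0,
                      trio: Sequence[float] = DEFAULT_TRIO,
                      margin: float = REGIME_MARGIN,
                      n_layers: int = 2) -> list[dict]:
    """Classify each composition as force- or extension-controlled.

    ``compositions`` holds dicts with keys ``n_sensor``, ``n_linker``,
    ``k_sensor``, ``k_linker``.  For each one, ``n_realizations`` random
    placements are solved for every sensor-stiffness multiplier in ``trio``
    and the pooled sensor loads classified by CV comparison.  Compositions
    without sensors are skipped with a warning.
    """
    import warnings

    if n_realizations < 2:
        raise InvalidInputError("n_realizations must be >= 2")
    rng = np.random.default_rng(seed)
    out = []
    for comp in compositions:
        if comp.get("n_sensor", 0) < 1:
            warnings.warn(f"composition without sensors skipped: {comp}")
            continue
        variants = _ensemble_sensor_loads(
            comp["n_sensor"], comp["n_linker"], comp["k_sensor"],
            comp["k_linker"], load, n_realizations, rng, trio, n_layers)
        n_pooled = sum(len(v["forces"]) for v in variants)
        cls = ControlClassification.from_variant_means(
            [v["forces"].mean() for v in variants],
            [v["extensions"].mean() for v in variants],
            n_pooled, margin)
        out.append({**comp, "cv_force": cls.cv_force,
                    "cv_extension": cls.cv_extension, "regime": cls.regime,
                    "n_sensors_pooled": cls.n_sensors})
    return out


def stiffness_force_relation(sensor_stiffnesses: Sequence[float],
                             load: LoadInput, n_sensor: int, n_linker: int,
                             k_linker: float, n_realizations: int = 200,
                             seed: int = 0, n_layers: int = 2) -> dict:
    """Mean sensor force at each sensor stiffness, with a linear fit.

    In an extension-controlled regime the sensors of a stiffness trio share
    a common extension, so their mean forces are proportional to stiffness;
    the returned slope then estimates that shared extension.  Requires an
    extension-mode input.
    """
    if load.mode != "extension":
        raise InvalidInputError(
            "stiffness-force relation is defined for extension inputs")
    rng = np.random.default_rng(seed)
    means = []
    for k_s in sensor_stiffnesses:
        (variant,) = _ensemble_sensor_loads(
            n_sensor, n_linker, k_s, k_linker, load, n_realizations, rng,
            trio=(1.0,), n_layers=n_layers)
        means.append(float(variant["forces"].mean()))
    ks = np.asarray(sensor_stiffnesses, dtype=float)
    means = np.asarray(means)
    if np.ptp(ks) == 0:  # degenerate design: no slope to estimate
        return {
            "stiffness_pN_per_nm": ks, "mean_force_pN": means,
            "slope_nm": np.nan, "intercept_pN": np.nan,
            "r_squared": np.nan,
        }
    fit = stats.linregress(ks, means)
    return {
        "stiffness_pN_per_nm": ks,
        "mean_force_pN": means,
        "slope_nm": float(fit.slope),
        "intercept_pN": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2),
    }
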