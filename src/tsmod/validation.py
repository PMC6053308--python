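"""Brute-force Monte Carlo sampler for a discretized worm-like chain.

This module is deliberately independent of :mod:`tsmod.mechanics`: it never
evaluates the closed-form radial density.  It samples explicit chains of unit
tangent vectors with nearest-neighbour bending energy

    U/kBT = -kappa * sum_i t_i . t_{i+1} - (F b / kBT) * sum_i t_iz,

i.e. a Kratky-Porod chain of ``n_seg`` bonds of length ``b`` under an
optional axial force.  Unloaded chains are drawn *exactly* (the tangents form
a Markov chain whose transition is a von Mises-Fisher step); loaded chains
are equilibrated by von Mises-Fisher Gibbs sweeps, which sample each tangent
from its exact full conditional and therefore need no step-size tuning.

The bending constant ``kappa`` is chosen so the discrete chain reproduces
the mean squared end-to-end distance of the continuous WLC with the
requested persistence and contour lengths (the standard coarse-graining
that keeps chains of different segment counts mechanically equivalent).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError
from .mechanics import fret_at_distance

__all__ = ["wlc_mc_averages", "sample_end_to_end", "kappa_for_wlc"]


def _mean_cos(kappa: float) -> float:
    """⟨t_i·t_{i+1}⟩ for the vMF bond distribution: Langevin function."""
    if kappa < 1e-8:
        return kappa / 3.0
    return 1.0 / np.tanh(kappa) - 1.0 / kappa


def _discrete_r2(c: float, n: int) -> float:
    """Exact ⟨r²⟩/b² of an n-bond chain with bond correlation c."""
    if c <= 0:
        return float(n)
    return n * (1 + c) / (1 - c) - 2 * c * (1 - c ** n) / (1 - c) ** 2


def kappa_for_wlc(lp: float, lc: float, n_seg: int) -> float:
    """Bending constant of the n_seg-bond chain representing a WLC (lp, lc):
    chosen so the discrete chain's exact ⟨r²⟩ equals the continuous value
    2·lp·lc·[1 - (lp/lc)(1 - exp(-lc/lp))]."""
    if lp <= 0 or lc <= 0 or n_seg < 2:
        raise ParameterError("need lp, lc > 0 and n_seg >= 2")
    b = lc / n_seg
    s = lc / lp
    target = 2 * lp * lc * (1 - (1 - np.exp(-s)) / s) / b ** 2

    def gap(kappa):
        return _discrete_r2(_mean_cos(kappa), n_seg) - target

    return brentq(gap, 1e-8, 1e6, xtol=1e-12)


def _sample_vmf(mu: np.ndarray, kappa: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Vectorised von Mises-Fisher draws on S2 with per-row mean/concentration.

    Uses the inverse-CDF for the polar angle (exact on the sphere) and a
    uniform azimuth, then rotates the z-axis frame onto each ``mu``.
    """
    n = mu.shape[0]
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), (n,)).copy()
    kappa = np.maximum(kappa, 1e-12)
    u = rng.random(n)
    # w = cos(theta) with density prop. to exp(kappa w): inverse CDF, stable form
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.random(n) * 2.0 * np.pi
    s = np.sqrt(np.maximum(0.0, 1.0 - w * w))
    v = np.stack([s * np.cos(phi), s * np.sin(phi), w], axis=1)
    # rotate z onto mu (Rodrigues; handle mu ~ -z)
    mu = mu / np.linalg.norm(mu, axis=1, keepdims=True)
    zc = mu[:, 2]
    flip = zc < -1.0 + 1e-12
    out = np.empty_like(v)
    # general case
    ax = np.stack([-mu[:, 1], mu[:, 0], np.zeros(n)], axis=1)
    norm = np.linalg.norm(ax, axis=1, keepdims=True)
    safe = norm[:, 0] > 1e-12
    k_ax = np.zeros_like(ax)
    k_ax[safe] = ax[safe] / norm[safe]
    cos_a = zc[:, None]
    sin_a = norm
    kxv = np.cross(k_ax, v)
    kdv = np.sum(k_ax * v, axis=1, keepdims=True)
    out = v * cos_a + kxv * sin_a + k_ax * kdv * (1.0 - cos_a)
    aligned = (~safe) & (~flip)
    out[aligned] = v[aligned]
    out[flip] = -v[flip]
    return out


def sample_end_to_end(lp: float, lc: float, n_seg: int, n_chains: int,
                      seed: int, force: float = 0.0,
                      kbt: float = 4.28, n_sweeps: int = 1500,
                      ) -> np.ndarray:
    """Sampled end-to-end distances |r| (nm) of the discretized chain.

    Unloaded chains are exact independent draws; loaded chains start from
    unloaded draws and are relaxed by ``n_sweeps`` Gibbs sweeps under the
    tilted Boltzmann measure.
    """
    rng = np.random.default_rng(seed)
    b = lc / n_seg
    kappa = kappa_for_wlc(lp, lc, n_seg)
    # exact unloaded draw: isotropic first tangent, vMF steps
    t = np.empty((n_chains, n_seg, 3))
    z0 = rng.random(n_chains) * 2.0 - 1.0
    ph0 = rng.random(n_chains) * 2.0 * np.pi
    s0 = np.sqrt(1.0 - z0 ** 2)
    t[:, 0] = np.stack([s0 * np.cos(ph0), s0 * np.sin(ph0), z0], axis=1)
    for i in range(1, n_seg):
        t[:, i] = _sample_vmf(t[:, i - 1], kappa, rng)

    if force > 0.0:
        fb = force * b / kbt
        fvec = np.array([0.0, 0.0, fb])
        for _ in range(n_sweeps):
            for i in range(n_seg):
                mu = fvec[None, :].repeat(n_chains, 0).copy()
                if i > 0:
                    mu += kappa * t[:, i - 1]
                if i < n_seg - 1:
                    mu += kappa * t[:, i + 1]
                conc = np.linalg.norm(mu, axis=1)
                conc = np.maximum(conc, 1e-12)
                t[:, i] = _sample_vmf(mu / conc[:, None], conc, rng)
    elif force < 0.0:
        raise ParameterError("force must be non-negative")

    r_vec = t.sum(axis=1) * b
    return np.linalg.norm(r_vec, axis=1)


def wlc_mc_averages(lp: float, lc: float, n_seg: int, n_chains: int = 20000,
                    seed: int = 0, force: float = 0.0, kbt: float = 4.28,
                    r0: float | None = None, offset: float = 0.0,
                    n_sweeps: int = 1500) -> dict:
    """Monte Carlo ⟨r⟩ (and ⟨E⟩ if ``r0`` given) with standard errors."""
    r = sample_end_to_end(lp, lc, n_seg, n_chains, seed, force, kbt,
                          n_sweeps=n_sweeps)
    out = {
        "mean_r": float(r.mean()),
        "sem_r": float(r.std(ddof=1) / np.sqrt(len(r))),
        "mean_r2": float((r ** 2).mean()),
    }
    if r0 is not None:
        e = fret_at_distance(r + offset, r0)
        out["mean_e"] = float(e.mean())
        out["sem_e"] = float(e.std(ddof=1) / np.sqrt(len(e)))
    return out
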