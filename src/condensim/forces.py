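"""Interaction potentials of the model and total-force assembly.

Four conservative interactions act in the system:

* excluded volume between every pair of chromatin monomers -- a purely
  repulsive Weeks-Chandler-Andersen (WCA) potential, energy-capped at
  ``eps_cut`` for numerical stability;
* harmonic springs along each chain (and across the crossing rewires);
  the springs themselves are *phantom*: they carry no excluded volume, so
  spring-spring and spring-monomer strand passage is allowed, standing in
  for topoisomerase II activity;
* a loop-holding harmonic tying each condensin to its two base-point
  monomers (strength ``F_loop``);
* a finite-range harmonic attraction between every condensin pair closer
  than ``Delta`` (strength ``F_cond``), acting in cis and in trans alike.

Condensins are point particles: they feel no excluded volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .params import SimParams
from .state import SystemState, Topology
from . import _kernels


@dataclass(frozen=True)
class Confinement:
    """Spherical harmonic wall pushing monomers inside ``radius``.

    The inward force on a monomer at distance r > radius from ``center`` is
    ``min(k*(r - radius), f_max)``; the cap keeps the compaction stage stable
    at the model timestep when chains start far outside the shell.
    """

    center: np.ndarray
    radius: float
    k: float = 1000.0
    f_max: float = 20.0


# ---------------------------------------------------------------------------
# scalar pair potentials (reference implementations used directly in tests)
# ---------------------------------------------------------------------------

def wca_energy_force(r: float, params: SimParams) -> Tuple[float, float]:
    """WCA pair energy and radial force magnitude at center distance ``r``.

    The energy is ``4 eps [(sigma/r)^12 - (sigma/r)^6 + 1/4]`` for
    ``r < 2^(1/6) sigma`` and zero beyond.  Below the cap radius ``r_cap``
    (where the energy reaches ``eps_cut``) the energy is clamped at
    ``eps_cut``; in ``cap_mode="flat"`` the force is zero there, in
    ``cap_mode="linear"`` it is held at its ``r_cap`` value.
    A positive force is repulsive.
    """
    if r <= 0:
        raise ValueError(f"invalid geometry: pair distance r = {r} <= 0")
    return _kernels.wca_pair(
        float(r), params.sigma, params.eps, params.eps_cut,
        1 if params.cap_mode == "linear" else 0,
    )


def spring_energy_force(r: float, params: SimParams) -> Tuple[float, float]:
    """Harmonic spring energy ``(eps_spr/2)(r - d_B)^2`` and restoring-force
    magnitude ``eps_spr |r - d_B|``."""
    if r < 0:
        raise ValueError("bond distance must be >= 0")
    dr = r - params.d_B
    return 0.5 * params.eps_spr * dr * dr, params.eps_spr * abs(dr)


def loop_energy_force(
    cond_pos: np.ndarray,
    anchor_pos: np.ndarray,
    F_loop: float,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Loop-holding interaction between one condensin and its two anchors.

    Energy ``(F_loop/2)(r+^2 + r-^2)`` where ``r±`` are the distances from
    the condensin to each anchor.  Returns (energy, forces on the two
    anchors (2, 3), net force on the condensin); action-reaction holds
    pairwise.
    """
    cond_pos = np.asarray(cond_pos, dtype=float)
    anchor_pos = np.asarray(anchor_pos, dtype=float).reshape(2, 3)
    d = anchor_pos - cond_pos[None, :]            # condensin -> anchor
    energy = 0.5 * F_loop * float(np.sum(d * d))
    f_anchor = -F_loop * d                        # anchors pulled toward condensin
    f_cond = -f_anchor.sum(axis=0)
    return energy, f_anchor, f_cond


def attraction_energy_force(
    r: float, F_cond: float, Delta: float
) -> Tuple[float, float]:
    """Inter-condensin attraction at pair distance ``r``.

    Energy ``-F_cond (r - Delta)^2`` for ``r < Delta``, zero at and beyond
    ``Delta``.  The returned force magnitude ``2 F_cond (Delta - r)`` pulls
    the pair together (reported as a positive attractive magnitude).
    """
    if r < 0:
        raise ValueError("pair distance must be >= 0")
    if r >= Delta:
        return 0.0, 0.0
    dr = r - Delta
    return -F_cond * dr * dr, 2.0 * F_cond * (Delta - r)


# ---------------------------------------------------------------------------
# total forces / energy
# ---------------------------------------------------------------------------

def _conf_args(conf: Optional[Confinement]):
    if conf is None:
        return -1.0, 0.0, 0.0, np.zeros(3)
    return float(conf.radius), float(conf.k), float(conf.f_max), \
        np.asarray(conf.center, dtype=float)


def total_forces(
    state: SystemState,
    topology: Topology,
    params: SimParams,
    confinement: Optional[Confinement] = None,
    method: str = "cell",
) -> Tuple[np.ndarray, np.ndarray]:
    """Forces on all monomers and condensins.

    ``method="cell"`` uses the numba cell-list kernel; ``method="brute"``
    is an all-pairs NumPy reference retained for cross-checking.  Both sum
    WCA over all monomer pairs (across chains too), springs over
    ``topology.springs``, loop-holding over anchors, and attraction over
    all condensin pairs within ``Delta``.
    """
    if state.n_mon != params.n_chains * params.N:
        raise ValueError("state/params size mismatch")
    if topology.anchors.shape[0] not in (0, state.n_cond):
        raise ValueError("topology anchors do not match condensin count")
    R, k, fmax, center = _conf_args(confinement)
    if method == "cell":
        f_mon = np.zeros_like(state.mon_pos)
        f_cond = np.zeros_like(state.cond_pos)
        _kernels.forces_kernel(
            state.mon_pos, state.cond_pos, topology.springs, topology.anchors,
            params.sigma, params.eps, params.eps_cut,
            1 if params.cap_mode == "linear" else 0,
            params.eps_spr, params.d_B,
            params.F_loop_abs, params.F_cond_abs, params.Delta,
            R, k, fmax, center,
            f_mon, f_cond,
        )
        return f_mon, f_cond
    if method == "brute":
        return _total_forces_brute(state, topology, params, confinement)
    raise ValueError(f"unknown method {method!r}")


def _total_forces_brute(state, topology, params, confinement):
    """Vectorized all-pairs reference (small systems only)."""
    pos = state.mon_pos
    n = pos.shape[0]
    f_mon = np.zeros_like(pos)
    # WCA over all monomer pairs
    if n > 1:
        d = pos[:, None, :] - pos[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=-1))
        np.fill_diagonal(r, np.inf)
        fr = np.zeros_like(r)
        for i in range(n):
            for j in range(n):
                if i < j and r[i, j] < params.r_cut:
                    _, f = _kernels.wca_pair(
                        r[i, j], params.sigma, params.eps, params.eps_cut,
                        1 if params.cap_mode == "linear" else 0)
                    fr[i, j] = fr[j, i] = f
        with np.errstate(invalid="ignore"):
            unit = d / r[..., None]
        unit = np.nan_to_num(unit)
        f_mon += np.sum(fr[..., None] * unit, axis=1)
    # springs
    for a, b in topology.springs:
        d = pos[a] - pos[b]
        r = float(np.linalg.norm(d))
        if r > 0:
            fvec = -params.eps_spr * (r - params.d_B) * d / r
            f_mon[a] += fvec
            f_mon[b] -= fvec
    # loop-holding + attraction
    f_cond = np.zeros_like(state.cond_pos)
    for j in range(state.n_cond):
        if topology.anchors.shape[0]:
            a1, a2 = topology.anchors[j]
            for a in (a1, a2):
                d = state.cond_pos[j] - pos[a]
                f = -params.F_loop_abs * d
                f_cond[j] += f
                f_mon[a] -= f
    for i in range(state.n_cond):
        for j in range(i + 1, state.n_cond):
            d = state.cond_pos[i] - state.cond_pos[j]
            r = float(np.linalg.norm(d))
            if 0 < r < params.Delta:
                # attractive: pull i toward j
                fvec = -2.0 * params.F_cond_abs * (params.Delta - r) * d / r
                f_cond[i] += fvec
                f_cond[j] -= fvec
    if confinement is not None:
        c = np.asarray(confinement.center, float)
        d = pos - c
        r = np.linalg.norm(d, axis=1)
        out = r > confinement.radius
        mag = np.minimum(confinement.k * (r[out] - confinement.radius),
                         confinement.f_max)
        f_mon[out] -= (mag / r[out])[:, None] * d[out]
    return f_mon, f_cond


def total_energy(
    state: SystemState,
    topology: Topology,
    params: SimParams,
    confinement: Optional[Confinement] = None,
) -> float:
    """Total potential energy (same interaction set as :func:`total_forces`)."""
    R, k, fmax, center = _conf_args(confinement)
    return _kernels.energy_kernel(
        state.mon_pos, state.cond_pos, topology.springs, topology.anchors,
        params.sigma, params.eps, params.eps_cut,
        1 if params.cap_mode == "linear" else 0,
        params.eps_spr, params.d_B,
        params.F_loop_abs, params.F_cond_abs, params.Delta,
        R, k, fmax, center,
    )


def kinetic_energy(state: SystemState, params: SimParams) -> float:
    """Total kinetic energy of monomers and condensins."""
    ke = 0.5 * params.mass * (np.sum(state.mon_vel ** 2)
                              + np.sum(state.cond_vel ** 2))
    return float(ke)
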