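"""Langevin-thermostatted velocity-Verlet time integration.

The integrator is the BAOAB splitting of the Langevin equation
``m dv = F dt - gamma v dt + sqrt(2 gamma kT) dW``: half kick, half drift,
exact Ornstein-Uhlenbeck velocity refresh, half drift, half kick, with the
forces recomputed once per step.  At ``gamma = 0`` the scheme reduces to
plain velocity Verlet, which makes the microcanonical limit available for
energy-conservation checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .params import SimParams
from .state import SystemState, Topology
from .forces import Confinement, total_forces, _conf_args
from . import _kernels


class IntegrationBlowupError(RuntimeError):
    """Raised when coordinates become non-finite during integration."""


@dataclass(frozen=True)
class Schedule:
    """Run schedule: step count, sampling cadence and RNG seed.

    ``sample_every`` is an interval in *time units* (multiples of ``dt``);
    observables are recorded at t = 0 and every ``sample_every`` thereafter.
    """

    dt: float = 0.01
    n_steps: int = 0
    sample_every: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.sample_every <= 0:
            raise ValueError("sample_every must be > 0")


Observer = Callable[[SystemState, Topology], Dict[str, float]]


def _ou_coeffs(params: SimParams, dt: float):
    c1 = math.exp(-params.gamma * dt / params.mass)
    c2 = math.sqrt(params.kT * (1.0 - c1 * c1) / params.mass)
    return c1, c2


def _advance(state: SystemState, topology: Topology, params: SimParams,
             n_steps: int, dt: float, rng: np.random.Generator,
             confinement: Optional[Confinement],
             f_mon: np.ndarray, f_cond: np.ndarray,
             chunk: int = 200) -> None:
    """Advance ``n_steps`` in place; ``f_mon/f_cond`` carry current forces."""
    c1, c2 = _ou_coeffs(params, dt)
    R, k, fmax, center = _conf_args(confinement)
    done = 0
    while done < n_steps:
        nb = min(chunk, n_steps - done)
        noise_mon = rng.standard_normal((nb, state.n_mon, 3))
        noise_cond = rng.standard_normal((nb, state.n_cond, 3))
        _kernels.baoab_chunk(
            state.mon_pos, state.mon_vel, state.cond_pos, state.cond_vel,
            f_mon, f_cond, noise_mon, noise_cond,
            topology.springs, topology.anchors,
            dt, params.mass, c1, c2,
            params.sigma, params.eps, params.eps_cut,
            1 if params.cap_mode == "linear" else 0,
            params.eps_spr, params.d_B,
            params.F_loop_abs, params.F_cond_abs, params.Delta,
            R, k, fmax, center,
        )
        done += nb
        if not (np.isfinite(state.mon_pos).all()
                and np.isfinite(state.cond_pos).all()):
            raise IntegrationBlowupError(
                f"non-finite coordinates after step {done} "
                f"(t = {state.time + done * dt:.4g})"
            )
    state.time += n_steps * dt


def langevin_step(state: SystemState, topology: Topology, params: SimParams,
                  rng: np.random.Generator,
                  confinement: Optional[Confinement] = None) -> SystemState:
    """One BAOAB step; returns a new state (the input is left untouched)."""
    out = state.copy()
    f_mon, f_cond = total_forces(out, topology, params, confinement)
    _advance(out, topology, params, 1, params.dt, rng, confinement,
             f_mon, f_cond)
    return out


def run(state: SystemState, topology: Topology, params: SimParams,
        schedule: Schedule,
        observers: Sequence[Observer] = (),
        confinement: Optional[Confinement] = None) -> tuple:
    """Integrate ``schedule.n_steps`` steps, sampling observers periodically.

    Observers are called at t = 0 and then every ``sample_every`` time
    units (rounded to whole steps).  Returns ``(final_state, series)`` with
    ``series`` a :class:`pandas.DataFrame` indexed by sample time.  If an
    observer raises, the error is re-raised with the sample time attached;
    the partial series collected so far is attached to the exception as
    ``exc.partial_series``.
    """
    state = state.copy()
    rng = np.random.default_rng(schedule.seed)
    stride = max(1, round(schedule.sample_every / schedule.dt))
    records: List[Dict[str, float]] = []

    def sample() -> None:
        row: Dict[str, float] = {"time": state.time}
        for obs in observers:
            try:
                row.update(obs(state, topology))
            except Exception as exc:  # noqa: BLE001 - context then re-raise
                err = RuntimeError(
                    f"observer {getattr(obs, '__name__', obs)!r} failed "
                    f"at t = {state.time:.6g}: {exc}"
                )
                err.partial_series = pd.DataFrame(records)  # type: ignore[attr-defined]
                raise err from exc
        records.append(row)

    sample()
    if schedule.n_steps > 0:
        f_mon, f_cond = total_forces(state, topology, params, confinement)
        done = 0
        while done < schedule.n_steps:
            nb = min(stride, schedule.n_steps - done)
            _advance(state, topology, params, nb, schedule.dt, rng,
                     confinement, f_mon, f_cond)
            done += nb
            if done % stride == 0 or done == schedule.n_steps:
                sample()
    series = pd.DataFrame(records)
    return state, series


# ---------------------------------------------------------------------------
# trajectory output (extended XYZ)
# ---------------------------------------------------------------------------

def write_xyz_frame(fh, state: SystemState, comment_extra: str = "") -> None:
    """Append one extended-XYZ frame: species (C = chromatin monomer,
    K = condensin), chain id, position."""
    n = state.n_mon + state.n_cond
    fh.write(f"{n}\n")
    fh.write(
        "Properties=species:S:1:chain:I:1:pos:R:3 "
        f"Time={state.time:.6f} {comment_extra}".rstrip() + "\n"
    )
    for i in range(state.n_mon):
        x, y, z = state.mon_pos[i]
        fh.write(f"C {state.mon_chain[i]} {x:.6f} {y:.6f} {z:.6f}\n")
    for i in range(state.n_cond):
        x, y, z = state.cond_pos[i]
        fh.write(f"K {state.cond_chain[i]} {x:.6f} {y:.6f} {z:.6f}\n")


def write_series(path, series: pd.DataFrame, metadata: Dict[str, object]) -> None:
    """Write an observable series as a TSV with ``# key: value`` header
    comments (seed, parameters, and friends)."""
    with open(path, "w") as fh:
        for key, val in metadata.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# time is in reduced time units; all other columns are "
                 "dimensionless\n")
        series.to_csv(fh, sep="\t", index=False)
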