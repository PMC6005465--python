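"""Initial-configuration builder.

The starting point of every production run is built in three stages:

1. each chain starts as an ideal (non-self-avoiding) random walk with step
   length ``d_B``; overlaps are tolerated because the energy-capped WCA
   potential lets subsequent dynamics relax them;
2. the chains are compacted into a spherical shell of diameter
   ``shell_D1 * n_chains**(1/3)`` (22.85 for one chain, 28.79 for two --
   constant per-chain density matching chromatin density in the nucleus)
   by a harmonic wall, and equilibrated under the thermostat; the wall is
   then released;
3. a deterministic loop-extrusion process installs M consecutive loops of
   L monomers per chain.  Each condensin starts with both bonds on the
   mid-loop monomer and the bonds step outward symmetrically, with a fixed
   interval of relaxation dynamics between advances; ``Cr`` times per loop
   the two chain springs flanking the bond pair are rewired into a crossed
   configuration, mimicking a supercoiled loop.  The final anchors of the
   i-th condensin are monomers (i-1)L and iL-1 of its chain.

For two chains the result is a pair of isotropically compacted, heavily
entangled chromosomes (overlap near 1, small asphericity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .params import SimParams
from .state import SystemState, Topology
from .forces import Confinement, total_forces
from .dynamics import Schedule, _advance
from .observables import asphericity, overlap, radius_of_gyration


class ConfinementError(RuntimeError):
    """Raised when compaction fails to confine the chains."""


class TopologyError(ValueError):
    """Raised for invalid spring rewires."""


@dataclass
class InitialReport:
    """Initial-configuration statistics (per chain, plus pairwise overlap)."""

    rg: List[float]
    asphericity: List[float]
    overlap: Optional[float]
    time: float
    seed: int

    def to_dict(self) -> Dict[str, object]:
        return {
            "rg": self.rg,
            "asphericity": self.asphericity,
            "overlap": self.overlap,
            "time": self.time,
            "seed": self.seed,
        }


def random_walk_chain(N: int, step: float, rng: np.random.Generator,
                      origin: Optional[np.ndarray] = None) -> np.ndarray:
    """Ideal random-walk chain: N positions with consecutive distances
    ``step``; self-avoidance is not enforced."""
    if N < 2:
        raise ValueError("need N >= 2")
    steps = rng.standard_normal((N - 1, 3))
    steps *= step / np.linalg.norm(steps, axis=1)[:, None]
    pos = np.empty((N, 3))
    pos[0] = 0.0 if origin is None else origin
    np.cumsum(steps, axis=0, out=pos[1:])
    if origin is not None:
        pos[1:] += origin
    return pos


def compact_into_shell(
    state: SystemState, topology: Topology, params: SimParams,
    schedule: Schedule, tolerance: Optional[float] = None,
    warmup_fraction: float = 0.5, warmup_eps_cut: float = 10.0,
) -> SystemState:
    """Equilibrate under the thermostat with a spherical harmonic wall of
    diameter ``params.shell_diameter`` centered on the monomer centroid.

    The random-walk start contains deep monomer overlaps; pairs just
    outside the cap radius of the full potential would receive violent
    kicks at the model timestep.  The first ``warmup_fraction`` of the
    scheduled steps therefore runs with the energy cap lowered to
    ``warmup_eps_cut`` (a soft potential that lets overlaps melt away);
    the remainder runs the full potential.

    Raises :class:`ConfinementError` (reporting the fraction outside) if
    monomers remain farther than ``tolerance`` (default one sigma) outside
    the shell after the scheduled steps.
    """
    state = state.copy()
    D = params.shell_diameter
    conf = Confinement(center=state.mon_pos.mean(axis=0), radius=D / 2.0)
    rng = np.random.default_rng(schedule.seed)
    n_warm = int(schedule.n_steps * warmup_fraction)
    if n_warm > 0:
        soft = params.with_(eps_cut=min(warmup_eps_cut, params.eps_cut))
        f_mon, f_cond = total_forces(state, topology, soft, conf)
        _advance(state, topology, soft, n_warm, schedule.dt, rng,
                 conf, f_mon, f_cond)
        state.mon_vel[:] = 0.0   # discard warmup heat
        # resolve the interpenetrations the soft potential tolerated
        # before the full potential sees them
        _relax(state, topology, params, n_iter=100, confinement=conf)
        _separate_overlaps(state, topology, params, rng, confinement=conf)
        _relax(state, topology, params, n_iter=100, confinement=conf)
    f_mon, f_cond = total_forces(state, topology, params, conf)
    _advance(state, topology, params, schedule.n_steps - n_warm,
             schedule.dt, rng, conf, f_mon, f_cond)
    tol = params.sigma if tolerance is None else tolerance
    r = np.linalg.norm(state.mon_pos - conf.center, axis=1)
    frac_out = float(np.mean(r > D / 2.0 + tol))
    if frac_out > 0.0:
        raise ConfinementError(
            f"compaction did not converge: {frac_out:.1%} of monomers remain "
            f"more than {tol} sigma outside the shell of diameter {D}"
        )
    return state


def crossing_rewire(springs: np.ndarray, a: int, b: int) -> np.ndarray:
    """Cross the two chain springs flanking the bond pair ``(a, b)``.

    Springs ``(a-1, a)`` and ``(b, b+1)`` are replaced by ``(a-1, b)`` and
    ``(a, b+1)``; the chain's spring graph stays a single path.  Raises
    :class:`TopologyError` if the flanking springs do not exist (boundary
    anchors without exterior neighbors) or ``a >= b``.
    """
    if a >= b:
        raise TopologyError(f"rewire needs a < b, got ({a}, {b})")
    springs = np.asarray(springs)
    key = {tuple(sorted(map(int, s))): i for i, s in enumerate(springs)}
    left = tuple(sorted((a - 1, a)))
    right = tuple(sorted((b, b + 1)))
    if a - 1 < 0 or left not in key:
        raise TopologyError(
            f"cannot rewire at ({a}, {b}): no spring ({a-1}, {a})")
    if right not in key:
        raise TopologyError(
            f"cannot rewire at ({a}, {b}): no spring ({b}, {b+1})")
    out = springs.copy()
    out[key[left]] = (a - 1, b)
    out[key[right]] = (a, b + 1)
    return out


@dataclass
class ExtrusionState:
    """Book-keeping of the deterministic extrusion, per condensin."""

    bond_left: np.ndarray        # current left bond monomer (global index)
    bond_right: np.ndarray       # current right bond monomer
    target_left: np.ndarray
    target_right: np.ndarray
    crossings_done: np.ndarray   # crossings installed so far
    step: int = 0                # extrusion step counter

    @property
    def extruded_length(self) -> np.ndarray:
        return self.bond_right - self.bond_left + 1

    @property
    def done(self) -> bool:
        return bool(np.all(self.bond_left == self.target_left)
                    and np.all(self.bond_right == self.target_right))


def _extrusion_init(params: SimParams) -> ExtrusionState:
    N, M, L = params.N, params.M, params.L
    left, right, tl, tr = [], [], [], []
    for c in range(params.n_chains):
        off = c * N
        for i in range(1, M + 1):
            start = off + (i - 1) * L + L // 2   # the (i - 0.5)L-th monomer
            left.append(start)
            right.append(start)
            tl.append(off + (i - 1) * L)
            tr.append(off + i * L - 1)
    return ExtrusionState(
        bond_left=np.array(left, dtype=np.int64),
        bond_right=np.array(right, dtype=np.int64),
        target_left=np.array(tl, dtype=np.int64),
        target_right=np.array(tr, dtype=np.int64),
        crossings_done=np.zeros(len(left), dtype=np.int64),
    )


def _separate_overlaps(state: SystemState, topology: Topology,
                       params: SimParams, rng: np.random.Generator,
                       r_min: float = 0.95, max_rounds: int = 60,
                       confinement: Optional[Confinement] = None) -> None:
    """Push residual deep monomer overlaps apart, in place.

    Pairs closer than the cap radius sit on the flat part of the capped
    potential where no force acts; once thermal motion carries them across
    the cap radius they slide down a cliff of ``eps_cut`` and detonate the
    integrator.  Each round moves every pair closer than ``r_min * sigma``
    symmetrically apart along the pair axis, then briefly descent-relaxes
    the stretched springs; rounds repeat until no close pair remains.
    """
    from scipy.spatial import cKDTree

    target = r_min * params.sigma
    for _ in range(max_rounds):
        pairs = cKDTree(state.mon_pos).query_pairs(
            target, output_type="ndarray")
        if len(pairs) == 0:
            return
        for i, j in pairs:
            d = state.mon_pos[j] - state.mon_pos[i]
            r = float(np.linalg.norm(d))
            if r < 1e-9:
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                r = 1.0
            else:
                d = d / r
            push = 0.5 * (target + 0.02 - r)
            if push > 0:
                state.mon_pos[i] -= push * d
                state.mon_pos[j] += push * d
        _relax(state, topology, params, n_iter=30, confinement=confinement)


def _max_spring_length(state: SystemState, topology: Topology) -> float:
    d = state.mon_pos[topology.springs[:, 0]] \
        - state.mon_pos[topology.springs[:, 1]]
    return float(np.linalg.norm(d, axis=1).max())


def _max_anchor_distance(state: SystemState, topology: Topology) -> float:
    if topology.anchors.shape[0] != state.n_cond or state.n_cond == 0:
        return 0.0
    d = np.linalg.norm(
        state.cond_pos[:, None, :] - state.mon_pos[topology.anchors],
        axis=2)
    return float(d.max())


def _relax(state: SystemState, topology: Topology, params: SimParams,
           n_iter: int = 40, alpha: float = 2e-4, max_step: float = 0.02,
           spring_tol: Optional[float] = None, n_max: int = 2000,
           confinement: Optional[Confinement] = None) -> None:
    """Displacement-limited steepest descent, in place.

    Used after crossing rewires: the freshly connected springs start
    stretched by a few sigma and, at the spring coefficient of 1000, any
    bond stretched much beyond its natural length acts as a catapult once
    thermal dynamics resumes, blowing the compacted melt apart.  Gradient
    descent drains that strain without generating kinetic energy.  Step
    size ``alpha`` satisfies ``alpha * eps_spr < 1`` for spring stability;
    per-particle moves are clipped at ``max_step`` to tame near-cap WCA
    forces.  With ``spring_tol`` set, iteration continues (up to ``n_max``)
    until the longest spring is shorter than ``d_B + spring_tol`` and every
    condensin sits within ``d_B`` of both anchors (condensin bonds share
    the stiff-spring force scale, so a stretched bond of either kind is
    equally explosive).
    """
    target = None if spring_tol is None \
        else params.d_B + spring_tol
    for it in range(n_max if target is not None else n_iter):
        if target is not None and it % 10 == 0 \
                and _max_spring_length(state, topology) < target \
                and _max_anchor_distance(state, topology) < params.d_B:
            break
        f_mon, f_cond = total_forces(state, topology, params, confinement)
        for pos, f in ((state.mon_pos, f_mon), (state.cond_pos, f_cond)):
            step = alpha * f
            norm = np.linalg.norm(step, axis=1)
            big = norm > max_step
            if big.any():
                step[big] *= (max_step / norm[big])[:, None]
            pos += step


def _crossing_threshold(k: int, L: int, Cr: int) -> int:
    """Extruded length at which the k-th crossing (k = 1..Cr) fires.

    Nominally k*L/Cr; capped at L-3 so that every rewire happens at a bond
    pair strictly inside the loop, where the flanking springs always exist
    (the chain-terminal loops have no exterior springs at their final
    anchors).
    """
    return min(k * (L // Cr), L - 3)


def default_pacing_time(N: int) -> float:
    """MD relaxation interval between extrusion bond advances, in time
    units.

    One time unit (the friction time) at the reference chain length
    N = 5000, scaled as N^(2/3) for smaller chains so that the free
    expansion of the released melt during extrusion stays proportionate
    to the compacted chain size.
    """
    return max(0.05, (N / 5000.0) ** (2.0 / 3.0))


def extrude_loops(
    state: SystemState, topology: Topology, params: SimParams,
    schedule: Schedule, pacing: Optional[float] = None,
    tether_strength: Optional[float] = None,
) -> Tuple[SystemState, Topology]:
    """Run the deterministic loop-extrusion process.

    Condensin particles are created on their start monomers; between bond
    advances the system relaxes for ``pacing`` time units of
    thermostatted MD (default :func:`default_pacing_time`; ``pacing=0``
    skips relaxation entirely, for topology-only use) with each condensin
    bonded to its
    current bond pair by a zero-length harmonic of absolute strength
    ``tether_strength`` (default: the chain-spring coefficient
    ``eps_spr``, making the extrusion bonds ordinary stiff bonds).  The
    stiff bonds keep both bond monomers right at the condensin, so the
    springs created by a crossing rewire start short, and they make the
    finished initial configuration independent of ``F_loop``, as observed.
    Each advance is followed by a gradient-descent relaxation and a
    velocity quench; the production run re-thermalizes in about one
    friction time.  Returns the final state and the extrusion-complete
    topology (anchors ``((i-1)L, iL-1)``, ``Cr`` crossings per loop).
    """
    if pacing is None:
        pacing = default_pacing_time(params.N)
    pacing_steps = int(round(pacing / schedule.dt))
    state = state.copy()
    topology = topology.copy()
    ext = _extrusion_init(params)
    n_cond = ext.bond_left.size
    L, Cr = params.L, params.Cr
    if tether_strength is None:
        tether_strength = params.eps_spr
    ext_params = params.with_(F_loop=tether_strength / params.eps_cut)

    state.cond_pos = state.mon_pos[ext.bond_left].copy()
    state.cond_vel = np.zeros((n_cond, 3))
    state.cond_chain = np.repeat(
        np.arange(params.n_chains, dtype=np.int64), params.M)
    topology.anchors = np.column_stack([ext.bond_left, ext.bond_right]).copy()

    rng = np.random.default_rng(schedule.seed)
    springs = topology.springs
    while not ext.done:
        if pacing_steps > 0:
            f_mon, f_cond = total_forces(state, topology, ext_params)
            _advance(state, topology, ext_params, pacing_steps, schedule.dt,
                     rng, None, f_mon, f_cond)
        # crossings fire at the *currently held* bond pair, which the
        # tether has just pulled tight around the condensin, so the
        # rewired springs start short; the bonds then continue to proceed
        lengths = ext.extruded_length
        rewired = False
        for j in range(n_cond):
            # at most one rewire per condensin per advance: consecutive
            # rewires at the same bond pair would reuse removed springs
            if (ext.crossings_done[j] < Cr
                    and lengths[j] >= _crossing_threshold(
                        int(ext.crossings_done[j]) + 1, L, Cr)
                    and ext.bond_left[j] < ext.bond_right[j]):
                a, b = int(ext.bond_left[j]), int(ext.bond_right[j])
                springs = crossing_rewire(springs, a, b)
                ext.crossings_done[j] += 1
                topology.crossings.append((j, a, b))
                rewired = True
        topology.springs = springs
        if rewired:
            _relax(state, topology, ext_params, spring_tol=0.4)
            _separate_overlaps(state, topology, ext_params, rng)
            _relax(state, topology, ext_params, n_iter=30)
        # advance both bonds one monomer outward where not yet at target
        np.maximum(ext.bond_left - 1, ext.target_left, out=ext.bond_left)
        np.minimum(ext.bond_right + 1, ext.target_right, out=ext.bond_right)
        ext.step += 1
        topology.anchors = np.column_stack(
            [ext.bond_left, ext.bond_right]).copy()
        _relax(state, topology, ext_params, spring_tol=0.4)
        state.mon_vel[:] = 0.0
        state.cond_vel[:] = 0.0
    if not np.all(ext.crossings_done == Cr):
        raise TopologyError("extrusion finished with missing crossings")
    # anneal out residual bond strain and squeezed monomer pairs left by
    # the extrusion before handing the state to production dynamics
    for _ in range(4):
        _relax(state, topology, ext_params, spring_tol=0.3)
        _separate_overlaps(state, topology, ext_params, rng)
        f_mon, f_cond = total_forces(state, topology, ext_params)
        _advance(state, topology, ext_params,
                 max(pacing_steps, int(round(1.0 / schedule.dt))),
                 schedule.dt, rng, None, f_mon, f_cond)
        state.mon_vel[:] = 0.0
        state.cond_vel[:] = 0.0
    _relax(state, topology, params, spring_tol=0.2)
    _separate_overlaps(state, topology, params, rng)
    _relax(state, topology, params, n_iter=50)
    return state, topology


def initial_report(state: SystemState, params: SimParams,
                   seed: int) -> InitialReport:
    rgs, asps = [], []
    for c in range(params.n_chains):
        chain = state.chain_monomers(c)
        rgs.append(radius_of_gyration(chain))
        asps.append(asphericity(chain))
    ov = None
    if params.n_chains >= 2:
        ov = overlap(state.chain_monomers(0), state.chain_monomers(1),
                     params.L)
    return InitialReport(rg=rgs, asphericity=asps, overlap=ov,
                         time=state.time, seed=seed)


def build_initial(
    params: SimParams, seed: int,
    compaction_time: float = 40.0,
    extrusion_pacing: Optional[float] = None,
) -> Tuple[SystemState, Topology, InitialReport]:
    """Full pipeline: random walks -> shell compaction -> release ->
    deterministic extrusion -> initial report.

    ``compaction_time`` (time units) covers both the soft warmup and the
    full-potential equilibration under the wall; distinct chains need the
    thermal part of it to interpenetrate, so very short schedules yield
    poorly entangled (low-overlap) initial states.  Chains start from
    origins spread ``shell_D1/8`` apart.  All randomness derives from
    ``seed``.
    """
    walk_ss, comp_ss, ext_ss = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(walk_ss)
    chains = []
    for c in range(params.n_chains):
        origin = rng.standard_normal(3) * params.shell_D1 / 8.0
        chains.append(random_walk_chain(params.N, params.d_B, rng, origin))
    state = SystemState.from_monomers(np.vstack(chains), params.n_chains)
    topology = Topology.linear_chains(params.n_chains, params.N)

    comp_sched = Schedule(dt=params.dt,
                          n_steps=int(round(compaction_time / params.dt)),
                          seed=int(comp_ss.generate_state(1)[0] % (2 ** 31)))
    state = compact_into_shell(state, topology, params, comp_sched)
    # confinement released before extrusion
    ext_sched = Schedule(dt=params.dt, n_steps=0,
                         seed=int(ext_ss.generate_state(1)[0] % (2 ** 31)))
    state, topology = extrude_loops(state, topology, params, ext_sched,
                                    pacing=extrusion_pacing)
    report = initial_report(state, params, seed)
    return state, topology, report


# ---------------------------------------------------------------------------
# export for external engines
# ---------------------------------------------------------------------------

def write_topology(path, topology: Topology) -> None:
    """Topology sidecar: delimited table of springs, anchors and crossing
    events, one record per line."""
    with open(path, "w") as fh:
        fh.write("# kind\tidx\ti\tj\n")
        for i, (a, b) in enumerate(topology.springs):
            fh.write(f"spring\t{i}\t{a}\t{b}\n")
        for i, (a, b) in enumerate(topology.anchors):
            fh.write(f"anchor\t{i}\t{a}\t{b}\n")
        for loop, a, b in topology.crossings:
            fh.write(f"crossing\t{loop}\t{a}\t{b}\n")
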