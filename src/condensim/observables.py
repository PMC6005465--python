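"""Order parameters for chromosome shaping and segregation.

Shape is characterized by the gyration tensor of a chain's monomers: with
eigenvalues ``l1^2 >= l2^2 >= l3^2``, the normalized asphericity

    A = [l1^2 - (l2^2 + l3^2)/2] / (l1^2 + l2^2 + l3^2)

is 0 for a sphere and 1 for a rod.  Segregation of two chains is measured
by the overlap: each chromosome's region is the union of one sphere per
loop (center = loop center of mass, radius = farthest loop monomer), and
the overlap is the fraction of one chain's monomers lying inside the other
chain's region.  The trans-(cis-)attraction is the fraction of condensins
with at least one condensin of another (the same) chain within the
attraction range ``Delta``.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .params import SimParams
from .state import SystemState, Topology


class DegenerateConfigurationError(ValueError):
    """Raised when an observable is undefined (e.g. all points coincident)."""


def gyration_tensor(positions: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Gyration tensor ``G_ab = <(r_a - r_CM,a)(r_b - r_CM,b)>`` and its
    eigenvalues sorted descending (these are the squared principal-axis
    lengths l1^2 >= l2^2 >= l3^2)."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] == 0:
        raise ValueError("positions must be a non-empty (n, 3) array")
    centered = pos - pos.mean(axis=0)
    G = centered.T @ centered / pos.shape[0]
    lam = np.linalg.eigvalsh(G)[::-1]
    return G, lam


def radius_of_gyration(positions: np.ndarray) -> float:
    """Rg = sqrt(l1^2 + l2^2 + l3^2) (equivalently the RMS distance from
    the center of mass)."""
    _, lam = gyration_tensor(positions)
    return float(np.sqrt(lam.sum()))


def asphericity(positions: np.ndarray) -> float:
    """Normalized asphericity in [0, 1]; 0 = sphere, 1 = rod."""
    _, lam = gyration_tensor(positions)
    total = lam.sum()
    if total <= 0:
        raise DegenerateConfigurationError(
            "asphericity undefined: all points coincident")
    return float((lam[0] - 0.5 * (lam[1] + lam[2])) / total)


def loop_spheres(
    positions: np.ndarray, L: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-loop bounding spheres for one chain.

    Loop i (i = 1..M) consists of monomers (i-1)L .. iL-1 of the chain.
    Returns (centers (M, 3), radii (M,)) with center the loop's center of
    mass and radius the maximum center-to-monomer distance.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] % L != 0:
        raise ValueError("chain length not a multiple of the loop length")
    M = pos.shape[0] // L
    loops = pos.reshape(M, L, 3)
    centers = loops.mean(axis=1)
    radii = np.linalg.norm(loops - centers[:, None, :], axis=2).max(axis=1)
    return centers, radii


def _fraction_inside(points: np.ndarray, centers: np.ndarray,
                     radii: np.ndarray) -> float:
    d2 = np.sum((points[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    inside = (d2 <= (radii[None, :] ** 2)).any(axis=1)
    return float(inside.mean())


def overlap(
    chain_a: np.ndarray, chain_b: np.ndarray, L: int,
    symmetrize: bool = True,
) -> float:
    """Overlap of two chains' territories.

    Directional overlap a->b is the fraction of chain-a monomers inside the
    union of chain b's loop spheres.  The reported scalar is the mean of the
    two directions (``symmetrize=False`` returns a->b only).
    """
    ca, ra = loop_spheres(chain_a, L)
    cb, rb = loop_spheres(chain_b, L)
    a_in_b = _fraction_inside(np.asarray(chain_a, float), cb, rb)
    if not symmetrize:
        return a_in_b
    b_in_a = _fraction_inside(np.asarray(chain_b, float), ca, ra)
    return 0.5 * (a_in_b + b_in_a)


def attraction_fractions(
    cond_pos: np.ndarray, cond_chain: np.ndarray, Delta: float
) -> Tuple[float, float]:
    """(trans, cis) attraction fractions.

    A condensin counts toward trans if at least one condensin of another
    chain lies strictly within ``Delta``, toward cis if at least one of its
    own chain does; it may count toward both.  Both fractions divide by the
    total condensin count.
    """
    pos = np.asarray(cond_pos, dtype=float)
    chain = np.asarray(cond_chain)
    m = pos.shape[0]
    if m == 0:
        return 0.0, 0.0
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    close = d2 < Delta * Delta
    same = chain[:, None] == chain[None, :]
    trans = (close & ~same).any(axis=1).mean()
    cis = (close & same).any(axis=1).mean()
    return float(trans), float(cis)


# ---------------------------------------------------------------------------
# time-series metrics
# ---------------------------------------------------------------------------

def first_crossing_time(
    times: np.ndarray, values: np.ndarray, threshold: float
) -> Optional[float]:
    """First time ``values`` crosses below ``threshold``, linearly
    interpolated between samples; None if never crossed."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if v[0] < threshold:
        return float(t[0])
    below = np.nonzero(v < threshold)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    t0, t1 = t[i - 1], t[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))


def trans_decay_time(times: np.ndarray, trans: np.ndarray) -> Optional[float]:
    """First sample time at which the trans-attraction is exactly zero and
    stays zero for at least one further sample (so a single-sample flicker
    to zero does not count); None if it never decays."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(trans, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    zero = v == 0.0
    for i in range(len(t) - 1):
        if zero[i] and zero[i + 1]:
            return float(t[i])
    return None


def segregation_metrics(
    times: np.ndarray,
    overlap_series: np.ndarray,
    trans_series: Optional[np.ndarray] = None,
    threshold: float = 0.2,
) -> Dict[str, float]:
    """Segregation time/speed and trans-decay time/speed from time series.

    The segregation time is the first (interpolated) time the overlap falls
    below ``threshold``; its inverse is the segregation speed.  If the
    series never crosses, the run is censored: time is NaN, speed 0, and
    ``segregation_censored`` is set.  Trans-decay follows the same pattern
    using :func:`trans_decay_time`.
    """
    t_seg = first_crossing_time(times, overlap_series, threshold)
    out: Dict[str, float] = {
        "segregation_time": t_seg if t_seg is not None else float("nan"),
        "segregation_speed": (1.0 / t_seg) if t_seg else 0.0,
        "segregation_censored": float(t_seg is None),
    }
    if trans_series is not None:
        t_dec = trans_decay_time(times, trans_series)
        out.update({
            "trans_decay_time": t_dec if t_dec is not None else float("nan"),
            "trans_decay_speed": (1.0 / t_dec) if t_dec else 0.0,
            "trans_decay_censored": float(t_dec is None),
        })
    return out


# ---------------------------------------------------------------------------
# condensin axis density profile
# ---------------------------------------------------------------------------

def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    s = float((p - a) @ ab) / denom
    s = min(1.0, max(0.0, s))
    return float(np.linalg.norm(p - (a + s * ab)))


def axis_distances(cond_pos: np.ndarray, interval: int = 5) -> np.ndarray:
    """Distance of each condensin from its own segment of the piecewise-
    linear condensin axis.

    The axis of one chain is approximated by straight segments: segment i
    joins condensins ``interval*(i-1)`` and ``interval*i - 1`` in chain
    order (0-based), and every condensin in that order range is measured
    against its own segment.
    """
    pos = np.asarray(cond_pos, dtype=float)
    m = pos.shape[0]
    if m % interval != 0:
        raise ValueError("condensin count must be divisible by the interval")
    n_seg = m // interval
    if n_seg < 2:
        raise ValueError(
            f"too few segments: {m} condensins at interval {interval} "
            "yield fewer than 2 axis segments")
    dists = np.empty(m)
    for i in range(n_seg):
        a = pos[interval * i]
        b = pos[interval * (i + 1) - 1]
        for j in range(interval * i, interval * (i + 1)):
            dists[j] = _point_segment_distance(pos[j], a, b)
    return dists


def axis_density(
    cond_pos: np.ndarray, interval: int = 5, bin_width: float = 0.25,
    n_bins: int = 24,
) -> pd.DataFrame:
    """Radial density profile of condensins about the chain axis,
    normalized so the origin bin equals 1."""
    d = axis_distances(cond_pos, interval)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    dens = counts.astype(float)
    if dens[0] > 0:
        dens = dens / dens[0]
    return pd.DataFrame({
        "r": 0.5 * (edges[:-1] + edges[1:]),
        "density": dens,
    })


# ---------------------------------------------------------------------------
# standard observer set for dynamics.run
# ---------------------------------------------------------------------------

def standard_observer(params: SimParams):
    """Observer recording per-chain asphericity and Rg, pairwise overlap
    (first pair, for n_chains >= 2) and trans/cis attraction fractions."""

    def observe(state: SystemState, topology: Topology) -> Dict[str, float]:
        row: Dict[str, float] = {}
        for c in range(params.n_chains):
            chain = state.chain_monomers(c)
            row[f"asphericity_{c}"] = asphericity(chain)
            row[f"rg_{c}"] = radius_of_gyration(chain)
        if params.n_chains >= 2:
            row["overlap"] = overlap(
                state.chain_monomers(0), state.chain_monomers(1), params.L)
            # all pairwise overlaps for three or more chromosomes
            if params.n_chains > 2:
                for a in range(params.n_chains):
                    for b in range(a + 1, params.n_chains):
                        row[f"overlap_{a}_{b}"] = overlap(
                            state.chain_monomers(a),
                            state.chain_monomers(b), params.L)
        if state.n_cond:
            trans, cis = attraction_fractions(
                state.cond_pos, state.cond_chain, params.Delta)
            row["trans_attraction"] = trans
            row["cis_attraction"] = cis
        return row

    return observe
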