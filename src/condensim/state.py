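"""In-memory containers: particle state and bonded topology."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimParams


@dataclass
class SystemState:
    """Positions and velocities of chromatin monomers and condensins.

    Monomers of chain ``c`` occupy the contiguous global index range
    ``[c*N, (c+1)*N)``; condensins of chain ``c`` occupy ``[c*M, (c+1)*M)``.
    """

    mon_pos: np.ndarray          # (n_mon, 3) float64
    mon_vel: np.ndarray          # (n_mon, 3) float64
    cond_pos: np.ndarray         # (n_cond, 3) float64
    cond_vel: np.ndarray         # (n_cond, 3) float64
    mon_chain: np.ndarray        # (n_mon,) int64
    cond_chain: np.ndarray       # (n_cond,) int64
    time: float = 0.0

    @property
    def n_mon(self) -> int:
        return self.mon_pos.shape[0]

    @property
    def n_cond(self) -> int:
        return self.cond_pos.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(
            self.mon_pos.copy(), self.mon_vel.copy(),
            self.cond_pos.copy(), self.cond_vel.copy(),
            self.mon_chain.copy(), self.cond_chain.copy(), self.time,
        )

    def chain_monomers(self, chain: int) -> np.ndarray:
        """Positions of the monomers of one chain, (N, 3)."""
        return self.mon_pos[self.mon_chain == chain]

    def validate(self, params: SimParams) -> None:
        if self.n_mon != params.n_chains * params.N:
            raise ValueError("monomer count does not match n_chains * N")
        if self.n_cond not in (0, params.n_chains * params.M):
            raise ValueError("condensin count does not match n_chains * M")
        for arr in (self.mon_pos, self.mon_vel, self.cond_pos, self.cond_vel):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("particle arrays must be (n, 3)")
        if self.mon_chain.min(initial=0) < 0 or (
            self.n_mon and self.mon_chain.max() >= params.n_chains
        ):
            raise ValueError("chain ids out of range")

    @staticmethod
    def from_monomers(mon_pos: np.ndarray, n_chains: int) -> "SystemState":
        """Build a condensin-free state from monomer positions."""
        mon_pos = np.asarray(mon_pos, dtype=np.float64)
        n_mon = mon_pos.shape[0]
        N = n_mon // n_chains
        mon_chain = np.repeat(np.arange(n_chains, dtype=np.int64), N)
        return SystemState(
            mon_pos=mon_pos,
            mon_vel=np.zeros_like(mon_pos),
            cond_pos=np.zeros((0, 3)),
            cond_vel=np.zeros((0, 3)),
            mon_chain=mon_chain,
            cond_chain=np.zeros(0, dtype=np.int64),
        )


@dataclass
class Topology:
    """Bonded topology: chain springs and condensin anchor pairs.

    ``springs`` holds monomer index pairs connected by harmonic springs,
    including the rewired (crossed) connections installed during extrusion.
    ``anchors[j]`` holds the two monomer indices the j-th condensin is
    harmonically tied to (the loop base points once extrusion completes).
    ``crossings`` records each installed crossing as
    (global loop index, a, b) where (a, b) was the condensin bond pair at
    rewire time.  Bonds never change after initialization.
    """

    springs: np.ndarray                       # (n_spr, 2) int64
    anchors: np.ndarray                       # (n_cond, 2) int64
    crossings: list = field(default_factory=list)

    def copy(self) -> "Topology":
        return Topology(self.springs.copy(), self.anchors.copy(),
                        list(self.crossings))

    @staticmethod
    def linear_chains(n_chains: int, N: int) -> "Topology":
        """Plain path topology: springs (i, i+1) within each chain, no anchors."""
        springs = []
        for c in range(n_chains):
            off = c * N
            for i in range(N - 1):
                springs.append((off + i, off + i + 1))
        return Topology(
            springs=np.asarray(springs, dtype=np.int64).reshape(-1, 2),
            anchors=np.zeros((0, 2), dtype=np.int64),
        )

    def spring_adjacency(self, n_mon: int) -> list:
        """Adjacency list of the spring graph."""
        adj: list = [[] for _ in range(n_mon)]
        for a, b in self.springs:
            adj[a].append(int(b))
            adj[b].append(int(a))
        return adj

    def is_single_path(self, indices: np.ndarray) -> bool:
        """Check that the spring graph restricted to ``indices`` is one
        simple path visiting every listed monomer exactly once."""
        index_set = set(int(i) for i in indices)
        adj = {i: [] for i in index_set}
        n_edges = 0
        for a, b in self.springs:
            a, b = int(a), int(b)
            if a in index_set and b in index_set:
                adj[a].append(b)
                adj[b].append(a)
                n_edges += 1
        n = len(index_set)
        if n_edges != n - 1:
            return False
        degs = [len(v) for v in adj.values()]
        if sorted(degs)[:2] != [1, 1] or max(degs) > 2:
            return False
        # walk from one endpoint and count reachable vertices
        start = next(i for i, v in adj.items() if len(v) == 1)
        prev, cur, seen = -1, start, 1
        while True:
            nxt = [x for x in adj[cur] if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            seen += 1
        return seen == n
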