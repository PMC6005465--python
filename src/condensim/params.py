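"""Physical and numerical parameters of the chromosome--condensin model.

All quantities are expressed in reduced units: the chromatin monomer
diameter ``sigma`` is the unit of length, the thermal energy ``kT`` the unit
of energy, and the monomer mass the unit of mass.  A monomer coarse-grains
roughly ten nucleosomes (a few kilobases of DNA); a chain of N = 5000
monomers therefore corresponds to a few tens of megabases, about the size of
the shortest human chromosome arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace


@dataclass(frozen=True)
class SimParams:
    """Complete parameter set for one simulation.

    Parameters
    ----------
    n_chains : int
        Number of chromosome chains.
    N : int
        Monomers per chain.
    M : int
        Condensins (= chromatin loops) per chain.  The loop length is
        ``L = N // M`` and ``N`` must be an exact multiple of ``M``.
    Cr : int
        Crossings installed per loop during the deterministic extrusion,
        mimicking a supercoiled loop.  ``L`` must be divisible by ``Cr``.
    sigma : float
        Monomer diameter (length unit).
    d_B : float
        Natural length of the chain springs.
    eps : float
        WCA contact energy; the pair energy at ``r = sigma`` equals ``eps``.
    eps_cut : float
        Energy cap of the WCA potential (numerical-stability device).
    eps_spr : float
        Harmonic spring coefficient; defaults to ``eps_cut``.
    F_loop : float
        Loop-holding strength: dimensionless, measured in units of the cap
        energy ``eps_cut`` like the spring coefficient (``eps_spr =
        eps_cut``).  The physical harmonic coefficient tying a condensin to
        its two base-point monomers is ``F_loop * eps_cut`` (see
        ``F_loop_abs``), so ``F_loop = 1`` gives condensin bonds as stiff
        as the chain springs.
    F_cond : float
        Inter-condensin attraction strength, dimensionless in units of
        ``eps_cut`` (physical coefficient ``F_cond * eps_cut``, see
        ``F_cond_abs``).
    Delta : float
        Attraction threshold distance (in units of sigma); condensin pairs
        farther apart than ``Delta`` do not interact.
    mass, gamma, kT : float
        Particle mass, Langevin friction and thermal energy.
    dt : float
        Integration timestep.  The nominal model timestep is 0.01, which
        is fine for chains alone; with loop-holding bonds at the stiff
        force scale the bonds press base-point monomers against the steep
        part of the capped excluded-volume potential (pair distances
        around 0.8 sigma), where the local oscillation frequency reaches
        the velocity-Verlet stability boundary at dt = 0.01 and rare
        fluctuations detonate.  The default 0.005 keeps a safe stability
        margin for production dynamics.
    shell_D1 : float
        Diameter of the compaction shell for a single chain; for ``n``
        chains the shell diameter is ``shell_D1 * n**(1/3)`` (constant
        per-chain density, reproducing 22.85 -> 28.79 for 1 -> 2 chains).
    cap_mode : str
        ``"flat"``: for separations below the cap radius the pair energy is
        clamped at ``eps_cut`` with zero force.  ``"linear"``: the force is
        held constant at its cap-radius value instead (energy continues
        linearly).
    """

    n_chains: int = 1
    N: int = 5000
    M: int = 100
    Cr: int = 5
    sigma: float = 1.0
    d_B: float = 1.0
    eps: float = 1.0
    eps_cut: float = 1000.0
    eps_spr: float = None  # type: ignore[assignment]  # defaults to eps_cut
    F_loop: float = 1.0
    F_cond: float = 1.0
    Delta: float = 1.0
    mass: float = 1.0
    gamma: float = 1.0
    kT: float = 1.0
    dt: float = 0.005
    shell_D1: float = 22.85
    cap_mode: str = "flat"

    def __post_init__(self) -> None:
        if self.eps_spr is None:
            object.__setattr__(self, "eps_spr", self.eps_cut)
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.M < 1 or self.N < 1:
            raise ValueError("need N >= 1 monomers and M >= 1 loops")
        if self.N % self.M != 0:
            raise ValueError(
                f"N = {self.N} is not an exact multiple of M = {self.M}; "
                "consecutive loops require N = L*M"
            )
        L = self.N // self.M
        if self.Cr < 0:
            raise ValueError("Cr must be >= 0")
        if self.Cr > 0 and L % self.Cr != 0:
            raise ValueError(f"loop length L = {L} not divisible by Cr = {self.Cr}")
        if self.Cr > 0 and L // self.Cr < 2:
            raise ValueError("crossing spacing L/Cr must be >= 2")
        for name in ("sigma", "d_B", "mass", "gamma", "kT", "dt"):
            if getattr(self, name) <= 0 and name != "gamma":
                raise ValueError(f"{name} must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        for name in ("F_loop", "F_cond", "Delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eps <= 0 or self.eps_cut <= 0:
            raise ValueError("eps and eps_cut must be > 0")
        if self.cap_mode not in ("flat", "linear"):
            raise ValueError("cap_mode must be 'flat' or 'linear'")

    # ---- derived quantities -------------------------------------------------

    @property
    def L(self) -> int:
        """Loop length in monomers."""
        return self.N // self.M

    @property
    def r_cut(self) -> float:
        """WCA cutoff radius 2^(1/6) sigma."""
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def r_cap(self) -> float:
        """Radius below which the WCA energy reaches the cap ``eps_cut``.

        Solving 4 eps (x^2 - x + 1/4) = eps_cut with x = (sigma/r)^6 gives
        x = 1/2 + sqrt(eps_cut / (4 eps)).
        """
        x = 0.5 + math.sqrt(self.eps_cut / (4.0 * self.eps))
        return self.sigma * x ** (-1.0 / 6.0)

    @property
    def F_loop_abs(self) -> float:
        """Physical loop-holding coefficient, kT/sigma^2."""
        return self.F_loop * self.eps_cut

    @property
    def F_cond_abs(self) -> float:
        """Physical inter-condensin attraction coefficient, kT/sigma^2."""
        return self.F_cond * self.eps_cut

    @property
    def shell_diameter(self) -> float:
        """Compaction-shell diameter for ``n_chains`` chains."""
        return self.shell_D1 * self.n_chains ** (1.0 / 3.0)

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
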