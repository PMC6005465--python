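"""Config-driven experiment runner.

Four modes cover the study designs the model is used for:

* ``init_only`` -- build initial configurations and report their
  radius of gyration, asphericity and overlap;
* ``equilibrium_shape`` -- single-chain production dynamics; report the
  equilibrium asphericity (mean over the final quarter of the series);
* ``segregation`` -- two-chain production dynamics; report segregation
  time/speed (overlap crossing 0.2) and trans-decay time/speed, with
  explicit censoring when a run never crosses within its time budget;
* ``axis_density`` -- single-chain equilibrium plus the radial density
  profile of condensins about their piecewise-linear axis.

Replicates use seeds spawned deterministically from a master seed via
``numpy.random.SeedSequence(master_seed).spawn``; every reported number is
regenerable from (config, master seed) alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .params import SimParams
from .state import SystemState, Topology
from .dynamics import Schedule, run, write_series
from .initializer import build_initial, InitialReport
from .observables import (
    asphericity, axis_density, radius_of_gyration, segregation_metrics,
    standard_observer,
)

MODES = ("init_only", "equilibrium_shape", "segregation", "axis_density")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    mode: str = "segregation"
    params: SimParams = field(default_factory=SimParams)
    production_time: float = 10_000.0     # segregation budget, time units
    sample_every: float = 10.0
    n_replicates: int = 5
    compaction_time: float = 40.0
    extrusion_pacing: float = None  # type: ignore[assignment]
    sweep: Optional[Dict[str, Sequence[float]]] = None
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sweep is not None:
            for key, grid in self.sweep.items():
                if key not in ("F_cond", "Delta", "F_loop"):
                    raise ValueError(f"cannot sweep over {key!r}")
                if len(grid) == 0:
                    raise ValueError(f"empty sweep grid for {key!r}")

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        """Load from a flat key-value YAML document; keys matching
        :class:`SimParams` fields go to the parameter set."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        pkeys = set(SimParams.__dataclass_fields__)
        pargs = {k: v for k, v in doc.items() if k in pkeys}
        cargs = {k: v for k, v in doc.items() if k not in pkeys}
        return ExperimentConfig(params=SimParams(**pargs), **cargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class ExperimentResult:
    """Per-replicate and aggregated outcomes of one experiment."""

    config: ExperimentConfig
    master_seed: int
    replicates: List[Dict[str, object]]
    aggregate: Dict[str, float]
    failures: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = {
            "config": self.config.to_dict(),
            "master_seed": self.master_seed,
            "replicates": self.replicates,
            "aggregate": self.aggregate,
            "failures": self.failures,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def replicate_seeds(master_seed: int, n: int) -> List[int]:
    """Deterministic replicate seeds: the first 32-bit word of each child
    of ``SeedSequence(master_seed)``, reduced below 2**31."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def _equilibrium_mean(series: pd.DataFrame, column: str) -> float:
    """Mean over the final quarter of the sampled series."""
    tail = series.iloc[3 * len(series) // 4:]
    return float(tail[column].mean())


def run_replicate(config: ExperimentConfig, seed: int) -> Dict[str, object]:
    """One full replicate: initial configuration, production, observables."""
    params = config.params
    state, topology, report = build_initial(
        params, seed,
        compaction_time=config.compaction_time,
        extrusion_pacing=config.extrusion_pacing,
    )
    out: Dict[str, object] = {"seed": seed, "initial": report.to_dict()}
    if config.mode == "init_only":
        return out

    n_steps = int(round(config.production_time / params.dt))
    sched = Schedule(dt=params.dt, n_steps=n_steps,
                     sample_every=config.sample_every, seed=seed)
    final, series = run(state, topology, params, sched,
                        observers=[standard_observer(params)])
    out["equilibrium_asphericity"] = _equilibrium_mean(series, "asphericity_0")
    out["equilibrium_rg"] = _equilibrium_mean(series, "rg_0")
    if config.mode == "segregation":
        if params.n_chains < 2:
            raise ValueError("segregation mode needs n_chains >= 2")
        metrics = segregation_metrics(
            series["time"].to_numpy(), series["overlap"].to_numpy(),
            series["trans_attraction"].to_numpy())
        out.update(metrics)
    if config.mode == "axis_density":
        profile = axis_density(final.cond_pos[final.cond_chain == 0])
        out["axis_profile"] = profile.to_dict(orient="list")
    out["_series"] = series
    return out


def _aggregate(replicates: List[Dict[str, object]]) -> Dict[str, float]:
    agg: Dict[str, float] = {"n_replicates": float(len(replicates))}
    if not replicates:
        return agg
    scalar_keys = sorted(
        k for k in replicates[0]
        if isinstance(replicates[0][k], (int, float)) and k != "seed"
    )
    for k in scalar_keys:
        vals = np.array([r[k] for r in replicates], dtype=float)
        if k.endswith("_time"):      # censored replicates carry NaN times
            ok = ~np.isnan(vals)
            agg[f"mean_{k}"] = float(vals[ok].mean()) if ok.any() else float("nan")
            agg[f"n_uncensored_{k}"] = float(ok.sum())
        else:
            agg[f"mean_{k}"] = float(vals.mean())
    # initial-report aggregates
    if "initial" in replicates[0]:
        rgs = [np.mean(r["initial"]["rg"]) for r in replicates]
        asps = [np.mean(r["initial"]["asphericity"]) for r in replicates]
        agg["mean_initial_rg"] = float(np.mean(rgs))
        agg["mean_initial_asphericity"] = float(np.mean(asps))
        ovs = [r["initial"]["overlap"] for r in replicates
               if r["initial"]["overlap"] is not None]
        if ovs:
            agg["mean_initial_overlap"] = float(np.mean(ovs))
    return agg


def run_experiment(config: ExperimentConfig,
                   master_seed: int = 0) -> ExperimentResult:
    """Run all replicates and aggregate.

    Per-replicate failures are recorded; the aggregate is still produced
    from the successful replicates provided at least one succeeded.
    """
    seeds = replicate_seeds(master_seed, config.n_replicates)
    replicates, failures = [], []
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, seed in enumerate(seeds):
        try:
            rep = run_replicate(config, seed)
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            failures.append(f"replicate {i} (seed {seed}): {exc}")
            continue
        series = rep.pop("_series", None)
        if out_dir is not None and series is not None:
            write_series(
                out_dir / f"series_rep{i}.tsv", series,
                {"seed": seed, "mode": config.mode,
                 "params": config.params.to_dict(),
                 "version": "condensim-0.1.0"})
        replicates.append(rep)
    if not replicates:
        raise RuntimeError("all replicates failed: " + "; ".join(failures))
    result = ExperimentResult(
        config=config, master_seed=master_seed,
        replicates=replicates, aggregate=_aggregate(replicates),
        failures=failures,
    )
    if out_dir is not None:
        result.to_json(out_dir / "summary.json")
    return result


def sweep(config: ExperimentConfig, master_seed: int = 0,
          out_path=None) -> pd.DataFrame:
    """Grid sweep over F_cond / Delta / F_loop.

    One :func:`run_experiment` per grid point; returns a table with one row
    per point carrying the equilibrium asphericity and (for segregation
    mode) the segregation speed, plus a branch label at the Delta = 2.5
    bifurcation.  The table is written incrementally if ``out_path`` is
    given, so partial grids survive interruption.
    """
    if not config.sweep:
        raise ValueError("config.sweep must define at least one grid")
    grids = {k: list(v) for k, v in config.sweep.items()}
    keys = sorted(grids)
    mesh = np.meshgrid(*[grids[k] for k in keys], indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    rows = []
    for vals in points:
        overrides = dict(zip(keys, (float(v) for v in vals)))
        sub = ExperimentConfig(
            mode=config.mode,
            params=config.params.with_(**overrides),
            production_time=config.production_time,
            sample_every=config.sample_every,
            n_replicates=config.n_replicates,
            compaction_time=config.compaction_time,
            extrusion_pacing=config.extrusion_pacing,
        )
        res = run_experiment(sub, master_seed)
        row = {
            "F_cond": sub.params.F_cond,
            "Delta": sub.params.Delta,
            "F_loop": sub.params.F_loop,
        }
        agg = res.aggregate
        if "mean_equilibrium_asphericity" in agg:
            row["asphericity"] = agg["mean_equilibrium_asphericity"]
        if "mean_segregation_speed" in agg:
            row["segregation_speed"] = agg["mean_segregation_speed"]
            row["n_censored"] = config.n_replicates - agg.get(
                "n_uncensored_segregation_time", 0.0)
        row["branch"] = "low_Delta" if sub.params.Delta < 2.5 else "high_Delta"
        rows.append(row)
        if out_path is not None:
            pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

def make_fixture(name: str, n_chains: int = 1, **overrides):
    """Deterministic miniature configurations with precomputed topology
    facts for the test suite.

    Registry: ``tiny`` (N=60, M=3, Cr=1), ``small`` (N=500, M=10, Cr=5),
    ``paper`` (N=5000, M=100, Cr=5).
    """
    registry = {
        "tiny": dict(N=60, M=3, Cr=1),
        "small": dict(N=500, M=10, Cr=5),
        "paper": dict(N=5000, M=100, Cr=5),
    }
    if name not in registry:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(registry)}")
    spec = dict(registry[name])
    # shell diameter scaled to keep the reference per-chain chromatin
    # density (22.85 belongs to a 5000-monomer chain)
    spec["shell_D1"] = 22.85 * (spec["N"] / 5000.0) ** (1.0 / 3.0)
    spec.update(overrides)
    params = SimParams(n_chains=n_chains, **spec)
    L, M = params.L, params.M
    anchors = []
    for c in range(n_chains):
        off = c * params.N
        for i in range(1, M + 1):
            anchors.append((off + (i - 1) * L, off + i * L - 1))
    facts = {
        "loop_length": L,
        "n_loops": n_chains * M,
        "crossings_per_loop": params.Cr,
        "anchors": anchors,
    }
    return params, facts
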