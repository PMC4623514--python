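"""Scripted, reproducible experiments: deep quench, near-critical quench,
temperature sweep, and theory tables.

Every output file is plain text (CSV or the snapshot format) with a
'#'-prefixed provenance header (parameter hash, master seed, code version),
so identical specs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (
    QuenchConfig,
    Trajectory,
    _draw_sweep_randoms,
    _sweep_cached,
    compute_local_fields,
    run_quench,
)
from .lattice import build_coupling_kernel, make_fixture, write_snapshot
from .observables import (
    CorrelationProfile,
    GrowthSeries,
    StructureProfile,
    correlation_function,
    domain_length,
    growth_exponent,
    magnetization_curve,
    scaling_collapse,
    structure_factor,
)
from .theory import critical_temperature, f2_lattice_sum, potential_closed_form

__all__ = [
    "QuenchResult",
    "SweepResult",
    "ensemble_profiles",
    "measure_growth",
    "run_quench_experiment",
    "run_near_critical_experiment",
    "run_sweep_experiment",
    "theory_table",
    "write_table",
]


# ---------------------------------------------------------------------------
# provenance helpers
# ---------------------------------------------------------------------------


def _spec_hash(params: dict) -> str:
    canon = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(params: dict, seed) -> dict:
    return {
        "spec_hash": _spec_hash(params),
        "seed": seed,
        "code_version": f"lrising {__version__}",
    }


def write_table(path, df: pd.DataFrame, meta: dict) -> None:
    """CSV with '#'-prefixed key=value metadata header, then a header row."""
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in meta.items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# quench experiments
# ---------------------------------------------------------------------------


@dataclass
class QuenchResult:
    config: QuenchConfig
    trajectories: list[Trajectory]
    correlations: dict[int, CorrelationProfile]
    structures: dict[int, StructureProfile]
    growth: GrowthSeries | None
    collapse: object | None = None

    def length_at(self, t: int) -> float:
        return domain_length(self.correlations[t])


def ensemble_profiles(
    trajectories: list[Trajectory], times, bins: str = "unit"
) -> tuple[dict[int, CorrelationProfile], dict[int, StructureProfile]]:
    """Ensemble-averaged C(r, t) and S(k, t) at each scheduled time."""
    correlations: dict[int, CorrelationProfile] = {}
    structures: dict[int, StructureProfile] = {}
    for t in times:
        snaps = [traj.snapshots[t] for traj in trajectories]
        meta = {"n_runs": len(snaps)}
        correlations[t] = correlation_function(snaps, t=t, bins=bins, meta=meta)
        structures[t] = structure_factor(snaps, t=t, meta=meta)
    return correlations, structures


def measure_growth(
    correlations: dict[int, CorrelationProfile], level: float = 0.5, meta: dict | None = None
) -> GrowthSeries:
    times = sorted(t for t in correlations if t > 0)
    lengths = [domain_length(correlations[t], level=level) for t in times]
    return GrowthSeries(
        times=np.asarray(times, dtype=np.float64),
        lengths=np.asarray(lengths, dtype=np.float64),
        meta=dict(meta or {}),
    )


def _config_params(config: QuenchConfig) -> dict:
    return {
        "L_s": config.L_s,
        "n": config.n,
        "J": config.J,
        "T": config.temperature,
        "n_mcs": config.n_mcs,
        "snapshot_times": list(config.snapshot_times),
        "n_runs": config.n_runs,
        "seed": config.seed,
        "cutoff_override": config.cutoff_override,
    }


def run_quench_experiment(
    config: QuenchConfig,
    outdir=None,
    fit_window: tuple[float, float] | None = None,
    write_snapshots: bool = True,
) -> QuenchResult:
    """Deep-quench protocol: ensemble of quenches, C/S profiles, L(t), phi fit.

    Defaults mirror the published protocol (T = 1 well below T_c, balanced
    random start, snapshot times including 100, 200, 500) at a caller-chosen
    lattice scale.  Artifacts (snapshots, per-run series, profiles, growth
    table) are written under ``outdir`` when given.
    """
    trajectories = run_quench(config)
    times = [t for t in config.snapshot_times]
    correlations, structures = ensemble_profiles(trajectories, times)

    growth = None
    positive_times = [t for t in times if t > 0]
    if len(positive_times) >= 1:
        meta = _config_params(config)
        growth = measure_growth({t: correlations[t] for t in positive_times}, meta=meta)
        if growth.times.size >= 4:
            growth_exponent(growth, fit_window)

    result = QuenchResult(
        config=config,
        trajectories=trajectories,
        correlations=correlations,
        structures=structures,
        growth=growth,
    )
    if outdir is not None:
        _write_quench_artifacts(result, Path(outdir), write_snapshots)
    return result


def _profile_frame(profile) -> pd.DataFrame:
    if isinstance(profile, CorrelationProfile):
        return pd.DataFrame({"r": profile.r, "C": profile.C, "count": profile.counts})
    return pd.DataFrame({"k": profile.k, "S": profile.S, "count": profile.counts})


def _write_quench_artifacts(result: QuenchResult, outdir: Path, write_snaps: bool) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config = result.config
    params = _config_params(config)
    prov = _provenance(params, config.seed)
    header = {**prov, **params}

    for traj in result.trajectories:
        n_mcs = config.n_mcs
        series = pd.DataFrame(
            {
                "t": np.arange(n_mcs + 1),
                "m": traj.magnetization,
                "energy": traj.energy,
                "accepted": np.concatenate([[0], traj.acceptance]),
            }
        )
        write_table(
            outdir / f"run{traj.run_index:02d}_series.csv",
            series,
            {**header, "run": traj.run_index},
        )
        if write_snaps:
            for t, snap in traj.snapshots.items():
                write_snapshot(
                    outdir / f"run{traj.run_index:02d}_t{t:05d}.txt",
                    snap,
                    {
                        "n": config.n,
                        "J": config.J,
                        "T": config.temperature,
                        "mcs": t,
                        "seed": config.seed,
                        **prov,
                    },
                )

    for t, prof in result.correlations.items():
        write_table(outdir / f"correlation_t{t:05d}.csv", _profile_frame(prof), {**header, "t": t})
    for t, prof in result.structures.items():
        write_table(outdir / f"structure_t{t:05d}.csv", _profile_frame(prof), {**header, "t": t})

    if result.growth is not None:
        df = pd.DataFrame({"t": result.growth.times, "L": result.growth.lengths})
        meta = dict(header)
        if result.growth.phi is not None:
            meta["phi"] = f"{result.growth.phi:.6f}"
            meta["phi_stderr"] = f"{result.growth.phi_stderr:.6f}"
            meta["prefactor"] = f"{result.growth.prefactor:.6f}"
        write_table(outdir / "growth.csv", df, meta)


def run_near_critical_experiment(
    config: QuenchConfig, outdir=None, write_snapshots: bool = True
) -> QuenchResult:
    """Quench at T ~ T_c: profiles plus the r/L scaling collapse.

    The caller supplies the near-critical temperature (typically the
    susceptibility-peak estimate from a prior sweep at the same n and L_s).
    """
    result = run_quench_experiment(
        config, outdir=outdir, fit_window=None, write_snapshots=write_snapshots
    )
    times = [t for t in config.snapshot_times if t > 0]
    if len(times) >= 2:
        result.collapse = scaling_collapse([result.correlations[t] for t in times])
    return result


# ---------------------------------------------------------------------------
# temperature sweep (magnetization curve, empirical T_c)
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    n: float
    L_s: int
    temperatures: np.ndarray
    mean_abs_m: np.ndarray
    chi: np.ndarray
    t_c: float
    meta: dict = field(default_factory=dict)
    samples: list = field(default_factory=list)


def run_sweep_experiment(
    n: float,
    L_s: int,
    temperatures,
    mcs_per_temp: int = 400,
    measure_every: int = 5,
    seed: int = 0,
    J: float = 1.0,
    cutoff_override: float | None = None,
    outdir=None,
) -> SweepResult:
    """Annealed temperature sweep feeding the magnetization curve.

    Anneals from the highest temperature downward, reusing the previous
    temperature's final state to shorten equilibration; at each T the first
    half of ``mcs_per_temp`` sweeps is discarded and |m| is sampled every
    ``measure_every`` MCS in the second half.
    """
    temps = np.asarray(sorted(temperatures), dtype=np.float64)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be distinct")
    kernel = build_coupling_kernel(n, J, cutoff_override)
    if kernel.r_c >= L_s / 2:
        raise ValueError(f"cutoff r_c = {kernel.r_c:g} >= L_s/2; enlarge L_s")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lattice = make_fixture("balanced_random", L_s, rng)
    h = compute_local_fields(lattice, kernel)
    n_sites = lattice.n_sites
    equil = mcs_per_temp // 2

    blocks: list[np.ndarray] = []
    for T in temps[::-1]:  # anneal downward
        beta = 1.0 / T
        samples = []
        for sweep in range(mcs_per_temp):
            sites, us = _draw_sweep_randoms(rng, n_sites)
            _sweep_cached(
                lattice.spins, h, kernel.d_rows, kernel.d_cols, kernel.weights,
                L_s, beta, sites, us,
            )
            if sweep >= equil and (sweep - equil) % measure_every == 0:
                samples.append(lattice.magnetization())
        blocks.append(np.asarray(samples))
    blocks.reverse()  # back to ascending-T order

    T_grid, mean_abs, chi, t_c = magnetization_curve(temps, blocks, n_sites)
    params = {
        "n": n, "L_s": L_s, "J": J, "cutoff_override": cutoff_override,
        "mcs_per_temp": mcs_per_temp, "measure_every": measure_every, "seed": seed,
        "temperatures": [float(t) for t in temps],
    }
    result = SweepResult(
        n=n, L_s=L_s, temperatures=T_grid, mean_abs_m=mean_abs, chi=chi, t_c=t_c,
        meta=_provenance(params, seed) | {"n": n, "L_s": L_s, "T_c_estimate": t_c},
        samples=blocks,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame({"T": T_grid, "mean_abs_m": mean_abs, "chi": chi})
        write_table(outdir / f"sweep_n{n:g}.csv", df, result.meta)
    return result


# ---------------------------------------------------------------------------
# theory tables
# ---------------------------------------------------------------------------


def theory_table(pairs, J: float = 1.0, k_B: float = 1.0, outdir=None) -> pd.DataFrame:
    """Tabulate U(n), T_c, branch, and f_2 for a list of (n, N) pairs.

    N may be math.inf; f_2 uses the default-cutoff kernel for that n.
    """
    rows = []
    for n, N in pairs:
        pot = potential_closed_form(n, N, J=J)
        kern = build_coupling_kernel(n, J)
        tc = critical_temperature(n, N, J=J, k_B=k_B, kernel=kern)
        rows.append(
            {
                "n": n,
                "N": N,
                "U": pot.U,
                "T_c": tc.T_c,
                "diverges": tc.diverges,
                "branch": pot.branch,
                "f_2": f2_lattice_sum(kern),
                "r_c": kern.r_c,
                "n_offsets": kern.n_offsets,
            }
        )
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        params = {"pairs": [[p[0], p[1]] for p in pairs], "J": J, "k_B": k_B}
        write_table(outdir / "theory.csv", df, _provenance(params, None))
    return df
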