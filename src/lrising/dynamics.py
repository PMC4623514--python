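"""Nonconserved spin-flip (Glauber) Monte Carlo with Metropolis acceptance.

One Monte Carlo step (MCS) is N single-site flip attempts at uniformly random
sites, N being the number of lattice sites; attempts are sequential, so each
sees all previously accepted flips.  A flip of s_i changes the energy by
dH = 2 s_i h_i with h_i the local field from the coupling kernel; it is
accepted with probability min(1, exp(-beta * dH)) (dH <= 0, including 0, is
always accepted).  Magnetization is not conserved: after a deep quench a
finite system eventually drifts toward m = +-1.

Two equivalent engines are provided: a direct one that recomputes the local
field from the offset list at every attempt (``mc_sweep``), and a cached one
that maintains the full field array and updates it incrementally on each
accepted flip (used by ``run_quench``; essential for the n = 2 kernel with
~750 offsets).  Both consume randomness identically and produce the same
trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .lattice import CouplingKernel, SpinLattice, build_coupling_kernel, make_fixture, total_energy

__all__ = [
    "QuenchConfig",
    "Trajectory",
    "metropolis_probability",
    "metropolis_accept",
    "mc_sweep",
    "run_quench",
    "run_seeds",
    "compute_local_fields",
]


def metropolis_probability(delta_H: float, beta: float) -> float:
    """Acceptance probability min(1, exp(-beta * dH))."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if delta_H <= 0:
        return 1.0
    return math.exp(-beta * delta_H)


def metropolis_accept(delta_H: float, beta: float, u: float) -> bool:
    """Metropolis decision for a proposed flip, given uniform u in [0, 1).

    Energy-lowering and energy-neutral moves are always accepted; an
    energy-raising move is accepted iff u < exp(-beta * dH).
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if delta_H <= 0:
        return True
    return u < math.exp(-beta * delta_H)


def compute_local_fields(lattice: SpinLattice, kernel: CouplingKernel) -> np.ndarray:
    """Field h_i at every site, vectorized over the offset star."""
    s = lattice.spins.astype(np.float64)
    h = np.zeros_like(s)
    for di, dj, w in zip(kernel.d_rows, kernel.d_cols, kernel.weights):
        h += w * np.roll(s, (-di, -dj), axis=(0, 1))
    return h


@njit(cache=True)
def _sweep_direct(spins, d_rows, d_cols, weights, L, beta, sites, us):
    """One MCS, local field recomputed from the offset list per attempt."""
    n_acc = 0
    d_energy = 0.0
    n_off = weights.size
    for t in range(sites.size):
        idx = sites[t]
        i = idx // L
        j = idx - i * L
        h = 0.0
        for k in range(n_off):
            h += weights[k] * spins[(i + d_rows[k]) % L, (j + d_cols[k]) % L]
        dH = 2.0 * spins[i, j] * h
        if dH <= 0.0 or us[t] < math.exp(-beta * dH):
            spins[i, j] = -spins[i, j]
            n_acc += 1
            d_energy += dH
    return n_acc, d_energy


@njit(cache=True)
def _sweep_cached(spins, h, d_rows, d_cols, weights, L, beta, sites, us):
    """One MCS against a maintained field array h (updated on accepted flips)."""
    n_acc = 0
    d_energy = 0.0
    n_off = weights.size
    for t in range(sites.size):
        idx = sites[t]
        i = idx // L
        j = idx - i * L
        dH = 2.0 * spins[i, j] * h[i, j]
        if dH <= 0.0 or us[t] < math.exp(-beta * dH):
            s_new = -spins[i, j]
            spins[i, j] = s_new
            n_acc += 1
            d_energy += dH
            dh = 2.0 * s_new
            for k in range(n_off):
                h[(i + d_rows[k]) % L, (j + d_cols[k]) % L] += dh * weights[k]
    return n_acc, d_energy


def _draw_sweep_randoms(rng: np.random.Generator, n_sites: int):
    sites = rng.integers(0, n_sites, size=n_sites)
    us = rng.random(n_sites)
    return sites, us


def mc_sweep(
    lattice: SpinLattice,
    kernel: CouplingKernel,
    beta: float,
    rng: np.random.Generator,
) -> tuple[SpinLattice, int]:
    """Perform one MCS in place (direct field evaluation); returns (lattice, n_accepted).

    beta = 0 (infinite temperature) is allowed here: every attempt is accepted.
    """
    if beta < 0:
        raise ValueError(f"beta must be nonnegative, got {beta}")
    if kernel.r_c >= lattice.linear_size / 2:
        raise ValueError("kernel cutoff violates the minimum-image condition r_c < L_s/2")
    L = lattice.linear_size
    sites, us = _draw_sweep_randoms(rng, lattice.n_sites)
    n_acc, _ = _sweep_direct(
        lattice.spins, kernel.d_rows, kernel.d_cols, kernel.weights, L, beta, sites, us
    )
    return lattice, int(n_acc)


@dataclass
class QuenchConfig:
    """Parameters of one quench experiment (k_B = 1: T in units of J/k_B)."""

    L_s: int
    n: float
    temperature: float
    n_mcs: int
    snapshot_times: tuple[int, ...]
    seed: int
    n_runs: int = 10
    J: float = 1.0
    cutoff_override: float | None = None

    def __post_init__(self) -> None:
        self.snapshot_times = tuple(sorted(int(t) for t in self.snapshot_times))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.L_s % 2 != 0:
            raise ValueError("L_s must be even (balanced initial condition)")
        if self.snapshot_times and self.snapshot_times[-1] > self.n_mcs:
            raise ValueError(
                f"snapshot schedule {self.snapshot_times} exceeds n_mcs = {self.n_mcs}"
            )
        if any(t < 0 for t in self.snapshot_times):
            raise ValueError("snapshot times must be non-negative")

    @property
    def beta(self) -> float:
        return 1.0 / self.temperature

    def kernel(self) -> CouplingKernel:
        return build_coupling_kernel(self.n, self.J, self.cutoff_override)


@dataclass
class Trajectory:
    """One quench run: snapshots plus per-MCS scalar series.

    ``magnetization`` and ``energy`` have length n_mcs + 1 (entry 0 is the
    initial state); ``acceptance`` has length n_mcs (accepted flips per MCS).
    """

    config: QuenchConfig
    run_index: int
    snapshots: dict[int, SpinLattice] = field(default_factory=dict)
    magnetization: np.ndarray | None = None
    energy: np.ndarray | None = None
    acceptance: np.ndarray | None = None


def run_seeds(master_seed: int, n_runs: int) -> list[np.random.SeedSequence]:
    """Per-run seeds: children of SeedSequence(master_seed), spawn index = run index."""
    return np.random.SeedSequence(master_seed).spawn(n_runs)


def run_quench(
    config: QuenchConfig, track_energy: bool = True
) -> list[Trajectory]:
    """Run n_runs independent quenches from fresh balanced random states.

    Each run r draws its stream from SeedSequence(seed).spawn(n_runs)[r], so
    the ensemble is reproducible and runs are independent.  Uses the cached
    field engine; the initial energy comes from ``total_energy`` and is then
    updated by the accepted dH increments.
    """
    kernel = config.kernel()
    if kernel.r_c >= config.L_s / 2:
        raise ValueError(
            f"cutoff r_c = {kernel.r_c:g} >= L_s/2 = {config.L_s / 2:g}; enlarge L_s"
        )
    trajectories = []
    for run_index, child in enumerate(run_seeds(config.seed, config.n_runs)):
        rng = np.random.default_rng(child)
        lattice = make_fixture("balanced_random", config.L_s, rng)
        traj = _run_single(config, kernel, lattice, rng, run_index, track_energy)
        trajectories.append(traj)
    return trajectories


def _run_single(
    config: QuenchConfig,
    kernel: CouplingKernel,
    lattice: SpinLattice,
    rng: np.random.Generator,
    run_index: int,
    track_energy: bool,
) -> Trajectory:
    L = config.L_s
    n_sites = lattice.n_sites
    beta = config.beta
    schedule = set(config.snapshot_times)

    h = compute_local_fields(lattice, kernel)
    mags = np.empty(config.n_mcs + 1)
    energies = np.empty(config.n_mcs + 1) if track_energy else None
    accepts = np.empty(config.n_mcs, dtype=np.int64)

    traj = Trajectory(config=config, run_index=run_index)
    mags[0] = lattice.magnetization()
    energy = total_energy(lattice, kernel) if track_energy else 0.0
    if track_energy:
        energies[0] = energy
    if 0 in schedule:
        traj.snapshots[0] = lattice.copy()

    for t in range(1, config.n_mcs + 1):
        sites, us = _draw_sweep_randoms(rng, n_sites)
        n_acc, d_e = _sweep_cached(
            lattice.spins, h, kernel.d_rows, kernel.d_cols, kernel.weights,
            L, beta, sites, us,
        )
        accepts[t - 1] = n_acc
        mags[t] = lattice.magnetization()
        if track_energy:
            energy += d_e
            energies[t] = energy
        if t in schedule:
            traj.snapshots[t] = lattice.copy()

    traj.magnetization = mags
    traj.energy = energies
    traj.acceptance = accepts
    return traj
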