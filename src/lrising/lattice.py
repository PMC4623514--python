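"""Lattice representation, power-law coupling kernels, and energy computations.

The model is a two-dimensional ferromagnetic Ising system on a periodic square
lattice with couplings that decay as a power law of the pair separation,

    H = - sum_<ij> J(r_ij, n) s_i s_j,      J(r, n) = J / r^n,   s_i = +-1,

where ``n`` controls the interaction range: n <= 4 is the long-range regime
(the potential energy per site diverges with system size), n > 4 behaves like
a short-range ferromagnet.  Interactions are truncated at a cutoff radius
``r_c`` (default ``2.5**(6/n)``) and evaluated under the minimum-image
convention, which requires ``r_c < L_s / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpinLattice",
    "CouplingKernel",
    "build_coupling_kernel",
    "default_cutoff",
    "total_energy",
    "local_field",
    "make_fixture",
    "write_snapshot",
    "read_snapshot",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("balanced_random", "checkerboard", "slab", "uniform_up", "uniform_down")


@dataclass
class SpinLattice:
    """Square periodic grid of +-1 spins, indexed (row, col), 0-based."""

    spins: np.ndarray

    def __post_init__(self) -> None:
        spins = np.asarray(self.spins)
        if spins.ndim != 2 or spins.shape[0] != spins.shape[1]:
            raise ValueError(f"spins must be a square 2D array, got shape {spins.shape}")
        if spins.shape[0] < 2:
            raise ValueError("linear size must be >= 2")
        if not np.all(np.abs(spins) == 1):
            raise ValueError("every spin must be exactly -1 or +1")
        self.spins = spins.astype(np.int8, copy=False)

    @property
    def linear_size(self) -> int:
        return self.spins.shape[0]

    @property
    def n_sites(self) -> int:
        return self.spins.size

    def magnetization(self) -> float:
        """Order parameter m = <s_i>, the volume-averaged spin."""
        return float(self.spins.mean())

    def flipped(self) -> "SpinLattice":
        """Global spin flip (Z2 symmetry partner)."""
        return SpinLattice(-self.spins)

    def copy(self) -> "SpinLattice":
        return SpinLattice(self.spins.copy())


def default_cutoff(n: float) -> float:
    """Interaction cutoff r_c = 2.5**(6/n) used throughout the simulations."""
    return 2.5 ** (6.0 / n)


@dataclass(frozen=True)
class CouplingKernel:
    """Relative-offset star of ferromagnetic couplings J/r^n within r <= r_c.

    ``d_rows``/``d_cols`` hold every integer offset (di, dj) != (0, 0) with
    Euclidean length <= r_c; ``weights`` holds J/r^n for each.  The star is
    closed under sign flips and axis swap, so summing over it visits every
    interacting pair twice (handled by the 1/2 in the Hamiltonian sum).
    """

    n: float
    J: float
    r_c: float
    d_rows: np.ndarray = field(repr=False)
    d_cols: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    @property
    def n_offsets(self) -> int:
        return self.weights.size

    @property
    def offsets(self) -> list[tuple[int, int, float]]:
        return [
            (int(di), int(dj), float(w))
            for di, dj, w in zip(self.d_rows, self.d_cols, self.weights)
        ]

    def weight_sum(self) -> float:
        """Sum of all coupling weights (per-site first moment)."""
        return float(self.weights.sum())


def build_coupling_kernel(
    n: float, J: float = 1.0, cutoff_override: float | None = None
) -> CouplingKernel:
    """Enumerate all lattice offsets with 0 < r <= r_c and weight J/r^n.

    The cutoff boundary is inclusive: for n = 6 (r_c = 2.5) the r = sqrt(5)
    shell is kept; for n = 12 (r_c = 2.5^0.5) the r = sqrt(2) shell is kept.
    Weights are computed as J * (di^2 + dj^2)^(-n/2) so that shells with
    power-of-two r^2 carry exactly representable weights.
    """
    if n <= 0:
        raise ValueError(f"interaction exponent n must be positive, got {n}")
    if J <= 0:
        raise ValueError(f"coupling J must be positive (ferromagnetic), got {J}")
    r_c = default_cutoff(n) if cutoff_override is None else float(cutoff_override)
    if r_c <= 0:
        raise ValueError(f"cutoff must be positive, got {r_c}")

    rmax = int(math.floor(r_c))
    d = np.arange(-rmax, rmax + 1)
    di, dj = np.meshgrid(d, d, indexing="ij")
    r2 = di**2 + dj**2
    keep = (r2 > 0) & (r2 <= r_c * r_c + 1e-12)
    di, dj, r2 = di[keep], dj[keep], r2[keep]
    order = np.lexsort((dj, di, r2))  # sorted by shell, then offset: deterministic
    di, dj, r2 = di[order], dj[order], r2[order]
    weights = J * r2.astype(np.float64) ** (-n / 2.0)
    return CouplingKernel(
        n=float(n),
        J=float(J),
        r_c=r_c,
        d_rows=di.astype(np.int64),
        d_cols=dj.astype(np.int64),
        weights=weights,
    )


def _check_minimum_image(lattice: SpinLattice, kernel: CouplingKernel) -> None:
    if kernel.r_c >= lattice.linear_size / 2:
        raise ValueError(
            f"cutoff r_c = {kernel.r_c:g} >= L_s/2 = {lattice.linear_size / 2:g}: "
            "periodic images are ambiguous; enlarge the lattice or shrink the cutoff"
        )


def total_energy(lattice: SpinLattice, kernel: CouplingKernel) -> float:
    """Total Hamiltonian H = -sum_<ij> J(r_ij, n) s_i s_j, in units of J.

    Realized as -(1/2) sum_i sum_offsets w * s_i * s_{i+offset} under periodic
    wrap; each unordered pair is seen twice through the full offset star.
    """
    _check_minimum_image(lattice, kernel)
    s = lattice.spins.astype(np.float64)
    e = 0.0
    for di, dj, w in zip(kernel.d_rows, kernel.d_cols, kernel.weights):
        e += w * float(np.sum(s * np.roll(s, (di, dj), axis=(0, 1))))
    return -0.5 * e


def local_field(
    lattice: SpinLattice, site: tuple[int, int], kernel: CouplingKernel
) -> float:
    """Field h_i = sum_offsets w * s_{i+offset}; flipping s_i costs dH = 2 s_i h_i."""
    _check_minimum_image(lattice, kernel)
    i, j = site
    L = lattice.linear_size
    if not (0 <= i < L and 0 <= j < L):
        raise IndexError(f"site {site} out of range for L_s = {L}")
    rows = (i + kernel.d_rows) % L
    cols = (j + kernel.d_cols) % L
    return float(np.dot(kernel.weights, lattice.spins[rows, cols]))


def make_fixture(
    kind: str, L_s: int, seed: int | np.random.Generator = 0
) -> SpinLattice:
    """Reference configurations for tests and quench initial conditions.

    ``balanced_random`` is an exact N/2 up, N/2 down shuffle (not independent
    coin flips), so the magnetization is 0 exactly; the same seed yields an
    identical lattice.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if L_s < 2:
        raise ValueError("L_s must be >= 2")
    if kind in ("balanced_random", "checkerboard") and L_s % 2 != 0:
        raise ValueError(f"{kind} requires an even linear size, got L_s = {L_s}")

    if kind == "uniform_up":
        return SpinLattice(np.ones((L_s, L_s), dtype=np.int8))
    if kind == "uniform_down":
        return SpinLattice(-np.ones((L_s, L_s), dtype=np.int8))
    if kind == "checkerboard":
        i, j = np.indices((L_s, L_s))
        return SpinLattice(np.where((i + j) % 2 == 0, 1, -1).astype(np.int8))
    if kind == "slab":
        s = np.ones((L_s, L_s), dtype=np.int8)
        s[L_s // 2 :, :] = -1
        return SpinLattice(s)
    # balanced_random
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = L_s * L_s // 2
    flat = np.concatenate([np.ones(half, dtype=np.int8), -np.ones(half, dtype=np.int8)])
    return SpinLattice(rng.permutation(flat).reshape(L_s, L_s))


# ---------------------------------------------------------------------------
# Snapshot text format: '#'-prefixed key=value header lines, then L_s rows of
# L_s space-separated spins in {-1, 1}.
# ---------------------------------------------------------------------------


def write_snapshot(path, lattice: SpinLattice, header: dict | None = None) -> None:
    lines = [f"# L_s={lattice.linear_size}"]
    for key, value in (header or {}).items():
        if key == "L_s":
            continue
        lines.append(f"# {key}={value}")
    body = "\n".join(" ".join(str(int(v)) for v in row) for row in lattice.spins)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n" + body + "\n")


def read_snapshot(path) -> tuple[SpinLattice, dict]:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                entry = line.lstrip("#").strip()
                if "=" in entry:
                    key, _, value = entry.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                rows.append([int(tok) for tok in line.split()])
    return SpinLattice(np.array(rows, dtype=np.int8)), meta
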