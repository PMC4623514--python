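"""Closed-form potential U(n) and critical-temperature estimates.

For couplings J/r^n on a 2D lattice of N sites (linear size sqrt(N)), the
per-site potential U(n) = (1/N) sum_{i != j} J / r_ij^n is approximated by the
continuum integral 2 * integral_1^sqrt(N) dr r^(3-n) (pair-distribution
g(r) ~ 1), which splits into three branches:

    U(n) ~ J * (1/2) ln N                          n = 4
    U(n) ~ J / (n - 4) * (1 - N^(2 - n/2))         n > 4   (finite as N -> inf)
    U(n) ~ J / (4 - n) * N^(2 - n/2)               0 < n < 4  (diverges with N)

A closed-form high-temperature estimate then gives T_c ~ U(n) / k_B: finite
and ~ J / (k_B (n - 4)) for short range, growing as N^(2 - n/2) for long range
and as (ln N)/2 at the marginal exponent n = 4.  The next-order correction
coefficient f_2 = sum of squared couplings is computed for diagnostics only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import CouplingKernel

__all__ = [
    "PotentialResult",
    "CriticalTemperature",
    "potential_closed_form",
    "critical_temperature",
    "f2_lattice_sum",
]

_BRANCHES = {"n_eq_4": "n = 4", "n_gt_4": "n > 4", "n_lt_4": "0 < n < 4"}


def _branch_of(n: float) -> str:
    if n == 4:
        return "n_eq_4"
    return "n_gt_4" if n > 4 else "n_lt_4"


@dataclass(frozen=True)
class PotentialResult:
    n: float
    N: float  # site count; math.inf allowed
    U: float  # units of J
    branch: str


@dataclass(frozen=True)
class CriticalTemperature:
    n: float
    N: float
    T_c: float  # units of J/k_B; math.inf when the estimate diverges
    diverges: bool
    f_2: float | None = None


def potential_closed_form(n: float, N: float, J: float = 1.0) -> PotentialResult:
    """Evaluate the branch closed form of U(n) at site count N (or math.inf)."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not math.isinf(N) and N < 4:
        raise ValueError(f"N must be >= 4 (or inf), got {N}")
    branch = _branch_of(n)
    if branch == "n_eq_4":
        U = math.inf if math.isinf(N) else 0.5 * J * math.log(N)
    elif branch == "n_gt_4":
        tail = 0.0 if math.isinf(N) else float(N) ** (2.0 - n / 2.0)
        U = J / (n - 4.0) * (1.0 - tail)
    else:  # 0 < n < 4
        U = math.inf if math.isinf(N) else J / (4.0 - n) * float(N) ** (2.0 - n / 2.0)
    return PotentialResult(n=float(n), N=float(N), U=U, branch=branch)


def critical_temperature(
    n: float,
    N: float,
    J: float = 1.0,
    k_B: float = 1.0,
    kernel: CouplingKernel | None = None,
) -> CriticalTemperature:
    """Leading-order critical temperature T_c = U(n, N) / k_B.

    For n <= 4 at N = inf the estimate diverges and is flagged rather than
    returned as a number.  If a kernel is supplied, its f_2 sum is attached
    for diagnostic comparison with the leading-order approximation.
    """
    pot = potential_closed_form(n, N, J=J)
    f2 = f2_lattice_sum(kernel) if kernel is not None else None
    if math.isinf(pot.U):
        return CriticalTemperature(
            n=float(n), N=float(N), T_c=math.inf, diverges=True, f_2=f2
        )
    return CriticalTemperature(
        n=float(n), N=float(N), T_c=pot.U / k_B, diverges=False, f_2=f2
    )


def f2_lattice_sum(kernel: CouplingKernel) -> float:
    """Per-site second moment of the couplings, sum over offsets of weight^2."""
    return float(np.sum(kernel.weights**2))
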