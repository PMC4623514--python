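"""Phase-ordering observables: C(r,t), S(k,t), L(t), scaling collapse, Porod tail.

The equal-time correlation function C(r, t) = <s_i s_{i+r}> - <s_i>^2 is
computed for all periodic separations via FFT autocorrelation, averaged over
an ensemble of independent runs, normalized so C(0) = 1, and spherically
averaged.  Its Fourier transform, the structure factor S(k, t), is spherically
averaged over k-shells of one grid mode; the convention (plain DFT of the
normalized correlation field) makes Parseval's identity exact:
sum_k S(k) = N * C(0) = N.

The characteristic domain size L(t) is the half-height point of C(r, t).
In the scaling regime C(r, t) = g(r/L) and S(k, t) = L^2 f(kL); for a
nonconserved scalar order parameter g is well approximated by the
Ohta-Jasnow-Kawasaki (OJK) function (2/pi) arcsin(exp(-x^2)), and the
large-k tail of S follows Porod's law S ~ k^-(d+1) = k^-3 in d = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lattice import SpinLattice

__all__ = [
    "CorrelationProfile",
    "StructureProfile",
    "GrowthSeries",
    "CollapseReport",
    "correlation_field_2d",
    "correlation_function",
    "structure_factor_2d",
    "structure_factor",
    "domain_length",
    "ojk_correlation",
    "growth_exponent",
    "scaling_collapse",
    "porod_tail_slope",
    "magnetization_curve",
]


@dataclass
class CorrelationProfile:
    """Spherically averaged C(r, t): unit-width radial bins (or exact shells)."""

    r: np.ndarray
    C: np.ndarray
    counts: np.ndarray
    t: int | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class StructureProfile:
    """Spherically averaged S(k, t); k in radians per lattice unit (2*pi/L_s grid)."""

    k: np.ndarray
    S: np.ndarray
    counts: np.ndarray
    t: int | None = None
    parseval_sum: float | None = None  # sum of the full 2D spectrum, = N * C(0)
    meta: dict = field(default_factory=dict)


@dataclass
class GrowthSeries:
    """L(t) from one quench ensemble, with the fitted growth exponent phi."""

    times: np.ndarray
    lengths: np.ndarray
    meta: dict = field(default_factory=dict)
    phi: float | None = None
    phi_stderr: float | None = None
    prefactor: float | None = None


def _as_spin_arrays(snapshots) -> list[np.ndarray]:
    arrays = []
    for snap in snapshots:
        arrays.append(snap.spins if isinstance(snap, SpinLattice) else np.asarray(snap))
    L = arrays[0].shape[0]
    for a in arrays:
        if a.shape != (L, L):
            raise ValueError("all snapshots must share the same linear size")
    return arrays


def correlation_field_2d(snapshots) -> np.ndarray:
    """Full 2D correlation field, ensemble averaged and normalized to C(0) = 1.

    <s_i s_{i+r}> is computed per snapshot by FFT autocorrelation under
    periodic wrap; the ensemble-and-volume mean magnetization squared is
    subtracted (the system is translationally invariant, so one scalar
    suffices); normalization divides by the r = 0 value, the spin variance.
    """
    arrays = _as_spin_arrays(snapshots)
    N = arrays[0].size
    acc = np.zeros(arrays[0].shape)
    m_acc = 0.0
    for a in arrays:
        s = a.astype(np.float64)
        f = np.fft.fft2(s)
        acc += np.fft.ifft2(f * np.conj(f)).real / N
        m_acc += s.mean()
    g = acc / len(arrays)
    m = m_acc / len(arrays)
    c2d = g - m * m
    var = c2d[0, 0]
    if var <= 1e-12:
        raise ValueError(
            "degenerate ensemble: zero spin variance (uniform lattices); "
            "correlation normalization undefined"
        )
    return c2d / var


def _min_image_radii(L: int) -> np.ndarray:
    idx = np.arange(L)
    d = np.minimum(idx, L - idx)
    return np.hypot(d[:, None], d[None, :])


def _radial_average(field2d: np.ndarray, radii: np.ndarray, r_max: float, bins: str):
    """Spherical average of a 2D field over shells of |r| (or |k| in grid units)."""
    if bins == "unit":
        shell = np.rint(radii).astype(np.int64)
        keep = radii <= r_max
        labels = shell[keep]
        values = field2d[keep]
        n_bins = labels.max() + 1
        counts = np.bincount(labels, minlength=n_bins)
        sums = np.bincount(labels, weights=values, minlength=n_bins)
        nonzero = counts > 0
        centers = np.arange(n_bins, dtype=np.float64)[nonzero]
        return centers, sums[nonzero] / counts[nonzero], counts[nonzero]
    if bins == "exact":
        keep = radii <= r_max
        r_flat = np.round(radii[keep], 9)
        values = field2d[keep]
        centers, inverse = np.unique(r_flat, return_inverse=True)
        counts = np.bincount(inverse)
        sums = np.bincount(inverse, weights=values)
        return centers, sums / counts, counts
    raise ValueError(f"bins must be 'unit' or 'exact', got {bins!r}")


def correlation_function(
    snapshots, t: int | None = None, bins: str = "unit", meta: dict | None = None
) -> CorrelationProfile:
    """Spherically averaged correlation profile of an equal-time ensemble.

    ``bins='unit'`` (default) uses width-1 radial bins centered on integers;
    ``bins='exact'`` resolves every distinct shell radius (useful for exact
    checks on ordered patterns such as the checkerboard).  Bins beyond
    L_s/2 are dropped (partial shells in the periodic corners).
    """
    c2d = correlation_field_2d(snapshots)
    L = c2d.shape[0]
    radii = _min_image_radii(L)
    r, C, counts = _radial_average(c2d, radii, L / 2, bins)
    return CorrelationProfile(r=r, C=C, counts=counts, t=t, meta=dict(meta or {}))


def structure_factor_2d(snapshots) -> np.ndarray:
    """Full 2D structure factor: DFT of the normalized correlation field."""
    c2d = correlation_field_2d(snapshots)
    s2d = np.fft.fft2(c2d)
    return s2d.real


def structure_factor(
    snapshots, t: int | None = None, meta: dict | None = None
) -> StructureProfile:
    """Spherically averaged S(k, t) over k-shells of width one grid mode.

    k magnitudes are (2*pi/L_s) * |mode vector| with min-image mode numbers;
    shell j collects modes with round(|m|) = j and is reported at
    k = 2*pi*j/L_s.  ``parseval_sum`` stores the total 2D spectral weight,
    which equals N * C(0) = N exactly under this convention.
    """
    s2d = structure_factor_2d(snapshots)
    L = s2d.shape[0]
    radii = _min_image_radii(L)  # mode-number magnitudes, same geometry as r
    idx, S, counts = _radial_average(s2d, radii, L / 2, "unit")
    return StructureProfile(
        k=2.0 * np.pi * idx / L,
        S=S,
        counts=counts,
        t=t,
        parseval_sum=float(s2d.sum()),
        meta=dict(meta or {}),
    )


def domain_length(profile: CorrelationProfile, level: float = 0.5) -> float:
    """Characteristic size L(t): first downward crossing of C(r) = level.

    Linear interpolation between the adjacent bins.  Raises if the profile
    never reaches the level within the available r range (domains comparable
    to the box; enlarge L_s).
    """
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    r, C = profile.r, profile.C
    if abs(C[0] - 1.0) > 1e-6:
        raise ValueError("profile must be normalized with C = 1 at r = 0")
    below = np.nonzero(C < level)[0]
    if below.size == 0:
        raise ValueError(
            f"C(r) never drops below {level} within r <= {r[-1]:g}: "
            "domain size comparable to the box; enlarge the lattice"
        )
    j = below[0]
    if j == 0:
        raise ValueError("profile drops below the level at r = 0; not a valid profile")
    r0, r1, c0, c1 = r[j - 1], r[j], C[j - 1], C[j]
    return float(r0 + (c0 - level) * (r1 - r0) / (c0 - c1))


def ojk_correlation(x):
    """OJK scaling function g(x) = (2/pi) arcsin(exp(-x^2)), x = r/L >= 0."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    out = (2.0 / np.pi) * np.arcsin(np.exp(-(x**2)))
    return float(out) if out.ndim == 0 else out


def growth_exponent(
    series: GrowthSeries, fit_window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """OLS slope (and stderr) of log L(t) vs log t; stores the fit in ``series``."""
    t = np.asarray(series.times, dtype=np.float64)
    length = np.asarray(series.lengths, dtype=np.float64)
    if np.any(t <= 0) or np.any(length <= 0):
        raise ValueError("times and lengths must be positive for a log-log fit")
    if fit_window is not None:
        lo, hi = fit_window
        keep = (t >= lo) & (t <= hi)
        t, length = t[keep], length[keep]
    if t.size < 4:
        raise ValueError(f"need >= 4 points in the fit window, got {t.size}")
    res = stats.linregress(np.log(t), np.log(length))
    series.phi = float(res.slope)
    series.phi_stderr = float(res.stderr)
    series.prefactor = float(math.exp(res.intercept))
    return series.phi, series.phi_stderr


@dataclass
class CollapseReport:
    """Rescaled curves on a common grid with pairwise and OJK deviation metrics."""

    x: np.ndarray
    curves: np.ndarray  # shape (n_profiles, len(x))
    lengths: np.ndarray
    max_pairwise_dev: float
    rms_pairwise_dev: float
    rms_vs_ojk: float | None = None  # worst per-curve RMS against OJK (correlation only)


# Half-height crossing of the OJK function: OJK(x) = 1/2 at x = sqrt(ln(2)/2).
# Data scaled by the half-height length L cross 1/2 at x = 1, so the OJK
# reference in those units is OJK(OJK_HALF_X * x).
OJK_HALF_X = math.sqrt(0.5 * math.log(2.0))

_DEFAULT_X_CORR = np.linspace(0.0, 2.0, 81)
_DEFAULT_X_STRUCT = np.linspace(0.5, 8.0, 76)


def scaling_collapse(
    profiles,
    lengths=None,
    x_grid: np.ndarray | None = None,
    kind: str | None = None,
) -> CollapseReport:
    """Collapse profiles onto (x, value) with x = r/L (C) or kL (S, value S/L^2).

    Each profile is rescaled by its own characteristic length: for correlation
    profiles L defaults to the half-height length; for structure profiles the
    lengths must be supplied.  Curves are linearly interpolated onto a common
    grid (x in [0, 2] for C, [0.5, 8] for scaled S by default); the report
    carries the maximum and RMS pairwise deviation between curves, and for
    correlation profiles the worst per-curve RMS deviation from the OJK form.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to assess a collapse")
    if kind is None:
        kind = "correlation" if isinstance(profiles[0], CorrelationProfile) else "structure"

    if lengths is None:
        if kind != "correlation":
            raise ValueError("structure-factor collapse requires explicit lengths L(t)")
        lengths = [domain_length(p) for p in profiles]
    lengths = np.asarray(lengths, dtype=np.float64)
    if lengths.size != len(profiles) or np.any(lengths <= 0):
        raise ValueError("one positive length per profile is required")

    if x_grid is None:
        x_grid = _DEFAULT_X_CORR if kind == "correlation" else _DEFAULT_X_STRUCT
    x_grid = np.asarray(x_grid, dtype=np.float64)

    curves = np.empty((len(profiles), x_grid.size))
    for row, (p, L) in enumerate(zip(profiles, lengths)):
        if kind == "correlation":
            curves[row] = np.interp(x_grid, p.r / L, p.C)
        else:
            curves[row] = np.interp(x_grid, p.k * L, p.S / L**2)

    diffs = []
    for a in range(len(profiles)):
        for b in range(a + 1, len(profiles)):
            diffs.append(curves[a] - curves[b])
    diffs = np.abs(np.array(diffs))
    report = CollapseReport(
        x=x_grid,
        curves=curves,
        lengths=lengths,
        max_pairwise_dev=float(diffs.max()),
        rms_pairwise_dev=float(np.sqrt(np.mean(diffs**2))),
    )
    if kind == "correlation":
        # lengths are half-height based, so the OJK curve is evaluated in
        # half-height units (both curves then cross 1/2 at x = 1)
        ojk = ojk_correlation(OJK_HALF_X * x_grid)
        per_curve = np.sqrt(np.mean((curves - ojk) ** 2, axis=1))
        report.rms_vs_ojk = float(per_curve.max())
    return report


def porod_tail_slope(
    profile: StructureProfile, tail_window: tuple[float, float]
) -> tuple[float, float]:
    """OLS slope of log S vs log k in the window; ~ -(d+1) = -3 for sharp interfaces."""
    lo, hi = tail_window
    keep = (profile.k >= lo) & (profile.k <= hi) & (profile.k > 0)
    k, S = profile.k[keep], profile.S[keep]
    if k.size < 4:
        raise ValueError(f"need >= 4 k-bins in the tail window, got {k.size}")
    if np.any(S <= 0):
        raise ValueError("structure factor must be positive in the fit window")
    res = stats.linregress(np.log(k), np.log(S))
    return float(res.slope), float(res.stderr)


def magnetization_curve(temperatures, m_samples, n_sites: int):
    """Per-temperature <|m|>, susceptibility, and the susceptibility-peak T_c.

    ``m_samples[j]`` holds the equilibrium magnetization samples at
    ``temperatures[j]``; |m| is used (finite systems break symmetry between
    +-m branches).  chi = N * beta * (<m^2> - <|m|>^2); the empirical T_c is
    the temperature of the chi maximum.
    """
    T = np.asarray(temperatures, dtype=np.float64)
    if T.size != len(m_samples):
        raise ValueError("one sample block per temperature is required")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be sorted strictly increasing")
    mean_abs = np.empty(T.size)
    chi = np.empty(T.size)
    for j, block in enumerate(m_samples):
        m = np.abs(np.asarray(block, dtype=np.float64))
        if m.size == 0:
            raise ValueError(f"no samples at T = {T[j]}")
        mean_abs[j] = m.mean()
        chi[j] = n_sites / T[j] * (np.mean(m**2) - mean_abs[j] ** 2)
    t_c = float(T[int(np.argmax(chi))])
    return T, mean_abs, chi, t_c
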