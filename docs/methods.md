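# Methods

## Model

A periodic L_s × L_s square lattice of spins s_i = ±1 with ferromagnetic
power-law couplings,

    H = − Σ_<ij> J(r_ij, n) s_i s_j,    J(r, n) = J / r^n,

r_ij the Euclidean pair separation in lattice units under the minimum-image
convention.  The exponent n = d + σ = 2 + σ separates a long-range regime
(0 < σ < 2, i.e. n < 4), where the per-site interaction energy grows with
system size, from an effectively short-range regime (n > 4).  There is no
external field and no antiferromagnetic term.

Interactions are truncated at a cutoff r_c = 2.5^(6/n) (n = 6 → 2.5,
n = 3 → 6.25, n = 2 → 15.625), boundary inclusive: the r = √5 shell is kept
at n = 6 and the r = √2 shell at n = 12.  The kernel is the full offset star
{(Δi, Δj) : 0 < |Δ| ≤ r_c}, closed under inversion and quarter turns, with
weights computed as J·(Δi²+Δj²)^(−n/2) so that power-of-two shells carry
exactly representable weights.  Energy sums run over the full star and are
halved, which is algebraically the unordered-pair sum.  Energy operations
require r_c < L_s/2; ambiguous periodic configurations raise instead of
silently double-counting.

## Dynamics

Nonconserved (Glauber) spin-flip kinetics with the Metropolis rule: one
Monte Carlo step (MCS) is N = L_s² attempts, each at an independently
uniformly chosen site; a flip with energy change ΔH = 2 s_i h_i (h_i the
local field over the kernel) is accepted with probability min(1, e^(−βΔH)).
ΔH ≤ 0, including exactly 0, is always accepted.  Attempts are sequential;
each sees all previously accepted flips.  Units: k_B = 1, temperatures in
J/k_B.

Two engines share one randomness contract (per sweep: N site indices, then
N uniforms, from one numpy Generator): a direct engine recomputing h_i from
the offset list per attempt, and the production engine, which maintains the
full field array and updates the |kernel| affected entries on each accepted
flip.  The cached engine makes the cost per attempt O(1) and per accepted
flip O(|kernel|) — the difference between hours and seconds for the n = 2
kernel (~750 offsets) — and is verified in tests to produce trajectories
identical to the direct engine.  Incremental field updates accumulate float
error of order 1e−13 per long run; this can only change a decision when a
uniform falls within that distance of the acceptance threshold, and the
cache is additionally cross-checked against a fresh field computation.
Accepted-flip ΔH increments also maintain the energy series, verified
against a full recomputation at the final time.

Quench protocol: each run starts from an exact N/2-up/N/2-down random
shuffle (magnetization 0 exactly, not just in expectation).  Per-run
streams are the children of `numpy.random.SeedSequence(master_seed)`
(spawn index = run index), so ensembles are reproducible and
embarrassingly parallel in principle.

## Observables

**Correlation function.** C2d(r) = ⟨s_i s_{i+r}⟩ − m², computed per
snapshot by FFT autocorrelation, averaged over the run ensemble, with m the
ensemble-and-volume mean magnetization (one scalar — the system is
translationally invariant, and per-site means over ~5–10 runs would be
noise).  Normalization divides by the r = 0 value (the spin variance), so
C(0) = 1 identically; a uniform ensemble has zero variance and raises a
degenerate-configuration error.  Spherical averaging uses unit-width radial
bins centered on integers, truncated at r = L_s/2 (corner shells are
partial); an exact-shell mode resolves every distinct radius for analytic
checks on ordered patterns.

**Structure factor.** S2d = DFT of the normalized correlation field, real
by symmetry, spherically averaged over k-shells of one grid mode and
reported at k = 2πj/L_s.  Under this convention Parseval's identity is
exact: Σ_k S = N·C(0) = N (asserted to 1e−9).

**Domain length.** L(t) is the first downward crossing of C(r, t) = ½,
linearly interpolated between adjacent bins.  A profile that never crosses
(domains comparable to the box) raises with guidance to enlarge L_s; the
measurement is treated as well-posed only when L(t) is comfortably below
L_s/2, which sets the lattice sizes used in the tests (n = 2 and n = 3
reach L ≈ 50–70 by t = 500–800 and therefore run on 256²).

**Growth exponent.** Ordinary least squares of log L on log t inside a fit
window; the reported standard error is the OLS slope error, which
understates ensemble-to-ensemble scatter at small run counts (about ±0.05
on φ for 5-run ensembles) — comparisons between independent ensembles
should use that scatter, not the OLS error.

**Scaling collapse.** Correlation profiles are rescaled to x = r/L with
each profile's own half-height length and interpolated onto a fixed grid
x ∈ [0, 2] (structure profiles: S/L² vs x = kL on [0.5, 8]); the report
carries the maximum and RMS pairwise deviation and, for correlations, the
worst per-curve RMS against the OJK function
g(x) = (2/π) arcsin(e^(−x²)).  Because the data are scaled by the
half-height length while OJK crosses ½ at x* = √(ln2/2) ≈ 0.5887, the OJK
reference is evaluated at x·x* — both curves then cross ½ at x = 1.  Beyond
a profile's last bin the interpolation clamps to the final value; at the
recommended lattice sizes that region contributes negligibly.

**Porod tail.** log-log OLS slope of S(k) over a window chosen in the
scaling regime kL ∈ [3, 12], capped at k ≤ 1 rad/unit to stay below lattice
discreteness; sharp interfaces give ≈ −(d+1) = −3.

**Magnetization curve.** Annealed temperature sweep: starting disordered at
the highest temperature, each temperature runs a fixed number of MCS, the
first half discarded, |m| sampled every 5 MCS thereafter, and the final
state reused at the next lower temperature.  ⟨|m|⟩ (not ⟨m⟩) handles finite
size symmetry breaking; χ = Nβ(⟨m²⟩ − ⟨|m|⟩²) and the empirical T_c is the
χ-peak temperature.  This estimator is grid-quantized: resolution is the
grid spacing, which is why the short-range Onsager comparison uses a 0.2
step.

## Closed-form theory

The per-site potential U(n) = (1/N) Σ_{i≠j} J/r^n is approximated by the
continuum integral 2∫_1^√N r^(3−n) dr (pair distribution ≈ 1), giving the
three branches (ln N)/2, (1 − N^(2−n/2))/(n−4), and N^(2−n/2)/(4−n) for
n = 4, n > 4, and n < 4, with N the site count and √N the linear size.  The
leading-order critical temperature is T_c ≈ U(n, N)/k_B: finite for n > 4
(J/(k_B(n−4)) as N → ∞), diverging as N^(2−n/2) for n < 4 and as (ln N)/2
at n = 4; divergence at N = ∞ is returned as a flag, not a number.  The
second-moment sum f₂ = Σ w² is computed for diagnostics but not propagated.
Two caveats are deliberate: the n < 4 branch drops a lower-limit constant
−1/(4−n) (restored when checking branch continuity at n = 4 and when
comparing with quadrature at small N), and these asymptotic formulas are
not expected to match the empirical, cutoff-regularized simulation T_c —
the truncation removes the long-range divergence, so the simulated
T_c(n = 2, 64²) ≈ 19 reflects the kernel weight sum, not N^(2−n/2).

## What the tests establish (and what they do not)

The deep-quench suites run at 128²–256² with 5 runs and t ≤ 800 MCS rather
than the 512²/10-run scale of the full protocol (shipped as
`configs/paper_scale.yaml`).  At this scale: φ(n = 6) and φ(n = 3) land in
0.5 ± 0.1/0.12 — consistent with Cahn-Allen growth on both sides of the
n = 4 boundary, but not capable of excluding slow crossovers or logarithmic
corrections; the OJK and cross-n collapses hold to RMS < 0.07; the Porod
slope sits in [−3.5, −2.5].  Near-critical quenches use T = 0.95 × the
same-size susceptibility-peak estimate (a sweep on a smaller lattice
overestimates T_c for long-range kernels, because with r_c comparable to
the box the system is nearly mean-field).  Empirical critical temperatures
are validated only by their ordering in n and by the n = 12 kernel landing
within 15% of the Onsager value 2/ln(1+√2) ≈ 2.269 — the χ-peak location on
a 64² lattice carries finite-size bias of a few percent by itself.

The synthetic fixtures (balanced random, checkerboard, slab, uniform)
exercise exact limits of the estimators; they contain no quenched disorder,
no dilution, and no realistic neural connectivity, so green tests establish
the statistical mechanics of the homogeneous model only.

## Numerical choices

- Cutoff boundary inclusive (with a 1e−12 slack on r² against float error).
- Radial and k-shell bins of width 1 (lattice unit / grid mode); bin 0 is
  the exact r = 0 (k = 0) value.
- Half-height level 0.5 for L(t); alternative definitions (first zero,
  first moment of S) differ by constant factors in the scaling regime and
  are not implemented.
- ΔH = 0 accepted; β = 0 allowed in the sweep engines (accept everything),
  rejected in the scalar `metropolis_accept` contract.
- Energy series from accepted-ΔH increments (exact bookkeeping up to float
  accumulation ~1e−10 relative).
- Experiment outputs are byte-deterministic: no timestamps, provenance is
  (parameter hash, seed, code version).
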