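# Methods

## The estimator

A dihedral series θ(t) (degrees, uniform frame spacing dt, principal
branch (−180, +180]) is first reduced to fluctuations: the circular mean
is removed and each deviation wrapped back to the principal branch
(minimal image).  The wrapped deviations are then arithmetically
re-centred — a sub-degree correction for unimodal angle distributions —
so that the zero-lag autocorrelation is exactly 1 and the Cauchy–Schwarz
bound |C(0)| ≤ 1 holds exactly.  For series that wind through the branch
cut repeatedly an `unwrap` policy (np.unwrap, then arithmetic mean) is
available; the wrapped-deviation default is parameter-free.

The lagged cross-correlation of two fluctuation series on a common grid is

    C(Δt_l) = Σ_{t} δθ_i(t) δθ′_j(t + Δt_l) / (N_l √(var_i var_j)),

with N_l = N − l pairs at lag l and the *full-series* variances in the
normalization (a per-window variance option exists; the full-series form
is the default because it keeps the curve a rescaled covariance).  The sum
is evaluated by FFT (zero-padded, exact to rounding; verified against the
direct sum in tests).  The forward curve has series i at the earlier
time; both directions come from the same correlation at positive and
negative lags.  Because the normalization uses full-series variances,
|C| at positive lags may exceed 1 by O(1/N_l); values are reported as
computed, never clipped.  The default lag window is 25% of the series
span — beyond that N_l is small and the estimator variance dominates —
and lags with fewer than `min_count` (default 10) pairs are dropped.

## Laplace-domain summaries

F(s) = ∫₀^{Δt_max} C(Δt) e^{−sΔt} dΔt is computed by composite trapezoid
on the native lag grid, on 200 log-spaced frequencies spanning
[1/(2Δt_max), 10/dt].  Two error sources are tracked:

- truncation: |F_trunc(s)| ≤ |C(Δt_max)|/s, reported as a per-curve bound;
- quadrature: the trapezoid rule resolves e^{−sΔt} only for s·h ≲ 1
  (relative error (sh)²/12, h the lag spacing).

The *strength* is the interior extremum of F — a maximum when the low-s
end of F is positive (net-correlated pair), a minimum when negative —
with τ = 1/s_peak.  Extrema on the grid boundary are flagged as such (for
the analytic reference model F is extremal in the s → 0 limit, so the
boundary case is the rule there, and τ is then only a bound).  Ties
resolve to the smallest s (longest timescale) and are flagged.

The *tail exponent* κ is the negative least-squares slope of ln|F| vs
ln s over the highest decade of the grid where |F| exceeds 5× the
truncation bound **and** s ≤ 0.5/h (quadrature validity; without this cap
the flattening of the trapezoid estimate at s ≳ 1/h biases κ toward 0).
Sign changes of F inside the window shrink it to the sign-constant upper
part, with a warning.  κ ≈ 1 whenever the equal-time correlation is
nonzero, because F → C(0)/s; with C(0) = 0 the next resolvent term gives
κ = 2.  Note the finite-window fit systematically reads slightly below
the asymptotic exponent (e.g. fitting 1/(s+a) over [10a, 100a] gives
0.96); the fit window sits one to two decades above the relaxation rates,
where the residual bias is a few percent.

## The reference model

Two overdamped harmonic oscillators with drags γ and couplings α′ (j on
i) and β′ (i on j) relax linearly, dθ = Aθ dt + noise with

    A = [[−ω_i²/γ_i,  α′/γ_i], [β′/γ_j,  −ω_j²/γ_j]].

Stability requires all eigenvalues of A in the left half-plane
(violated when α′β′ > ω_i²ω_j²).  Two variants share every formula: the
stochastic variant with noise matrix D and stationary covariance Σ from
AΣ + ΣAᵀ + D = 0 (convention: noise increments with covariance D·dt, so
a decoupled variable has σ² = Dγ/2ω²), and the deterministic-relaxation
variant averaged over initial conditions with covariance Σ₀.  Closed
forms: C(Δt) = [Σ e^{AᵀΔt}]_ij / √(Σ_ii Σ_jj) and F(s) =
[Σ (sI − Aᵀ)⁻¹]_ij / √(Σ_ii Σ_jj).  Consequences used as oracles:
sign F(s→0) = sign of the Pearson coefficient; F_ij ≡ F_ji iff the system
is exchange-symmetric, with the sup-norm asymmetry growing monotonically
with |α′ − β′|; large-s expansion F = Σ_k P_k/s^k with P_1 = C(0).

The simulator integrates the linear SDE either by Euler–Maruyama (dt must
resolve the fastest mode; enforced) or by the exact one-step OU
discretization (distributionally exact at any dt); both are evaluated per
eigenmode with an IIR filter, so multi-million-step runs are vectorized.
A run starts at the origin and discards ten times the slowest relaxation
time.  Output is rescaled to a stationary standard deviation of 10° by
default — the small-angle regime in which circular wrapping is inert.

## Synthetic proteins

No reference trajectory accompanies the study conditions, so the
generator emulates their statistical structure: each residue carries
φ/ψ/χ₁ degrees of freedom relaxing as stationary OU processes with
relaxation times drawn log-uniformly (map/path experiments: 2–6 ns,
frames every 250 ps, 2.5 μs of trajectory — several hundred correlation
times, comparable averaging quality to a ~1 μs trajectory with tens-of-ns
correlation times), a planted directed coupling network (edge strength =
0.8 of the target's relaxation rate by default, assembled block-wise on
the diagonal of single-dof relaxers and rescaled if assembly ever turns
unstable), and coarse helical Cα positions (0.38 nm consecutive spacing)
with per-frame Gaussian positional jitter.  Cβ sites are fixed 0.15 nm
offsets from Cα.  Ground truth (edges, expected path) is retained and
exported beside the generated series.

What the generator does *not* emulate: multimodal rotamer hopping,
non-Markovian memory, correlated positional dynamics (jitter is white in
time), secondary-structure geometry beyond the coarse helix, and any
force-field realism.  Passing tests therefore show that the estimator and
the map/path logic recover planted linear-response structure at realistic
signal-to-noise — not that real proteins satisfy the linear model.

## Map, significance and path

For each residue pair the best dof pair is the argmax of the peak
magnitude max_s |F(s)| over ≤ 9 dof pairs × 2 directions; residue j is
*downstream* of i when the forward direction (i earlier) wins.  A cell is
*correlated* when its best magnitude exceeds the 95th percentile of a
block-shuffle null: 200 circular shifts of residue j's series by random
offsets of at least one lag window, recomputing the same max statistic.
(The null uses the circular-correlation identity — a circular shift of
one series is an index shift of the circular cross-correlation — so the
200 shuffles cost one FFT per dof pair; the circular and zero-padded
estimators differ only in O(n_lags/N) seam terms, which under the null
are ordinary samples.)  Per-cell shuffle draws are seeded by (seed, i, j),
making maps byte-reproducible and order-independent.  The path walk picks,
among the unvisited downstream residues of the current residue, the one
with smallest mean Cα–Cα distance; distance and argmax ties resolve to
the lower residue index and are flagged; a cycle guard stops after N_res
steps.

The false-positive rate of the threshold is the nominal 5% per cell by
construction (the null statistic is the same max over dof pairs and
directions as the real one), verified empirically on fully independent
systems.

## Transfer entropy

The cross-check module uses deliberately simple plug-in histogram
estimators (8 uniform bins per axis by default, all knobs exposed):
Kennel false-nearest-neighbours (R_tol = 15, A_tol = 2, Theiler window =
the embedding delay) for the embedding dimension; delayed mutual
information for the embedding interval; TE(x→y) = H(y⁺|Y) − H(y⁺|Y,X)
with m-component τ-spaced pasts and the future one embedding interval
ahead.  Plug-in TE is non-negative and carries a positive small-sample
bias; a circular-shift null reports the bias level, and a mean-occupancy
warning fires below 5 samples per occupied cell.  Published TE values of
either sign from bias-corrected estimators are therefore not directly
comparable to these plug-in values; only directional *comparisons* (which
of TE(x→y), TE(y→x) is larger) are used.

## Numerical and test-design choices

- Angles: degrees on (−180, +180] everywhere; −180 maps to +180.
- Dihedral sign: the clockwise-positive IUPAC convention, matching
  MDAnalysis, mdtraj and biotite bit-for-bit on random geometries
  (cross-checked in a test against MDAnalysis as the independent oracle).
- χ₁ terminal atom per residue type: Cγ, with Cγ1 (Ile/Val), Oγ (Ser),
  Oγ1 (Thr), Sγ (Cys); undefined for Gly/Ala — requesting it raises,
  never silently omits.
- Burn-in: moving-window saturation of the superposed backbone RMSD
  (windows are non-overlapping; the result is the start of the first
  window after the last above-tolerance change); a never-saturating
  profile warns and falls back to the trajectory start.  When RMSD
  detection is not requested, a fixed leading fraction (default 5%) is
  dropped.
- Resolvent-vs-quadrature agreement is asserted at < 0.5% relative with
  the relative scale floored at 1% of the curve maximum: pointwise
  relative error is ill-posed where F crosses zero, while the absolute
  quadrature error there is ~10⁻⁵ of the curve scale.
- Estimator-recovery checks compare replicate means against analytic
  values at 3 Monte-Carlo standard errors (standard error across
  independent replicate simulations); the low-s extremum sign is read off
  the replicate-mean curve, since a single replicate of a weakly
  correlated system can flip sign at finite length.
- Problem sizes: tail/estimator experiments use 2–4 × 10⁶ steps at 5 ps
  (10–20 μs) for two-variable systems; map/path experiments use 10⁴
  frames for 5–10 residue systems, 50 seeds for recovery rates.  These
  sizes put Monte-Carlo error well inside every asserted tolerance while
  a full multi-seed study completes in minutes on one core.

## Known limitations

- The linear OU model has no interior Laplace peak: its F(s) is extremal
  at s → 0.  Interior peaks arise for estimated curves (finite window,
  noise) and for dynamics richer than the model; τ from a boundary
  extremum is reported as a bound with a flag.
- The analytic large-s exponent of the reference model equals 1 for every
  correlated parameter set (resolvent expansion); the quasi-universality
  seen in estimated curves is reproduced, but the model cannot by itself
  explain exponents different from 1.
- Transfer entropy is estimated with plug-in histograms only (no KSG
  estimator, no multivariate conditioning); m > 2 with 8 bins is
  undersampled for typical series lengths and triggers the occupancy
  warning.
- The significance threshold controls the per-cell false-positive rate;
  no across-cell multiplicity correction is applied, matching the
  map-level usage where cells are read individually.
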