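# tdca — time-dependent dihedral cross-correlation analysis

`tdca` quantifies how conformational information travels between residues
of a protein.  Instead of the usual equal-time (Pearson) covariance
between dihedral angles, it estimates the full *time-dependent dihedral
cross-correlation function* (TDCF) between every pair of backbone
(φ, ψ) and side-chain (χ₁) dihedrals,

```
C_ij(θθ′; Δt) = Σ_l δθ_i(t₁) δθ′_j(t₁+Δt)  /  ( N_l · sqrt(var θ_i · var θ′_j) ),
```

where δθ are deviations from the circular mean, N_l = N − l is the number
of observation pairs at lag Δt_l, and the *forward* curve puts residue i's
dihedral at the earlier time (swapping the roles gives the generally
different *reverse* curve — the asymmetry that carries directional
information).  Each curve is condensed in the Laplace domain,
F(s) = ∫ C(Δt) e^(−sΔt) dΔt, into three numbers: the extremum strength
F_max (a maximum for net-correlated, a minimum for anti-correlated pairs),
a characteristic timescale τ = 1/s_peak, and the algebraic tail exponent κ
of |F| ~ s^(−κ) at large s (κ ≈ 1 whenever the equal-time correlation is
nonzero).

From the per-pair summaries the package builds a directional N×N residue
map — residue j is *downstream* of i when the forward curve wins over all
dof pairs — and walks the *downstream-correlated path*: from a starting
residue, repeatedly step to the spatially closest (mean Cα–Cα distance)
downstream residue.  Significance is decided against a block-shuffle null
(circular shifts of one series, 95th percentile of the max-peak statistic).

Everything is validated against an analytically solvable reference model:
two overdamped harmonic oscillators θ_i, θ_j coupled with strengths α′, β′
(relaxation matrix A, stationary covariance from the Lyapunov equation,
F(s) from the resolvent (sI − A)⁻¹).  A transfer-entropy module (false
nearest neighbours → delayed mutual information → plug-in histogram TE)
provides the information-theoretic cross-check of direction assignments.

Intended users: people analysing MD trajectories (PDB + DCD/XTC, read via
MDAnalysis) or any pre-extracted angular time series who want causal
ordering of residue motions on nanosecond timescales, not just covariance.

## Layout

- `src/tdca/` — the library: `trajio` (structures, dihedral series,
  RMSD burn-in, distances), `tdcf` (estimator + Laplace summaries),
  `pathmap` (directional map and path), `model` (coupled-oscillator
  closed forms), `synthdata` (synthetic proteins with planted coupling
  networks), `tentropy` (FNN / MI / transfer entropy),
  `experiments` (canonical study configurations).
- `analysis/01…05_*.py` — narrative drivers that run the study and write
  tables under `results/`.
- `docs/methods.md` — model assumptions, estimator conventions, numerical
  choices, limitations.

## Worked example

Simulate a coupled pair (relaxation times 5 and 8 ns, asymmetric
couplings: variable 1 drives variable 2), estimate the TDCF both ways and
summarize it in the Laplace domain:

```python
from tdca import model, tdcf
from tdca.trajio import AngleSeries

sys_ = model.OscillatorSystem.from_relaxation_times(
    5.0, 8.0, coupling_ij=0.03, coupling_ji=0.12)
t, x = model.simulate(sys_, 500_000, 0.02, seed=1)   # 10 us at 20 ps frames
fi = tdcf.fluctuations(AngleSeries(1, "phi", t, x[:, 0]))
fj = tdcf.fluctuations(AngleSeries(2, "phi", t, x[:, 1]))
fwd, rev = tdcf.tdcf_pair(fi, fj, max_lag=100.0)
lc_f, lc_r = tdcf.laplace_transform(fwd), tdcf.laplace_transform(rev)
print(f"Pearson C(0)       = {tdcf.pearson(fi, fj):+.3f}")
print(f"forward peak F_max = {tdcf.extremum(lc_f).F_ext:+.2f} ns")
print(f"reverse peak F_max = {tdcf.extremum(lc_r).F_ext:+.2f} ns")
print(f"tail exponent      = {tdcf.tail_exponent(lc_f).kappa:.3f}")
```

prints

```
Pearson C(0)       = +0.400
forward peak F_max = +5.01 ns
reverse peak F_max = +2.68 ns
tail exponent      = 1.003
```

The equal-time correlation (+0.40, analytic value +0.392) says the two
dihedrals co-fluctuate; the forward peak being almost twice the reverse
peak says variable 1 leads — variable 2 is downstream of the variable that
drives it, as planted.  The tail exponent sits at the universal κ ≈ 1.

The analysis drivers chain this into the full study, e.g.
`python analysis/04_map_and_path.py` builds the directional map of a
7-residue synthetic protein with a planted 1→2→3→4→5 φ-coupling chain and
prints the recovered path `1 -> 2 -> 3 -> 4 -> 5` plus the
amplitude-versus-distance-variance and peak-versus-Pearson tables.

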