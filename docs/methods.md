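# Methods

This note records the model equations, parameter choices, numerical
methods, and deliberate simplifications behind `topobind`.

## 1. Binding model

Neighbor-exclusion intercalation is described by the McGhee–von Hippel
isotherm with binding density `γ` (dyes per base pair), site size `n`, and
dissociation constant `K_d`. We solve it at finite concentrations, with
free-dye depletion:

```
γ · K_d = (c_total − γ · c_DNA,bp) · (1 − nγ)^n / (1 − nγ + γ)^(n−1)
```

The residual is strictly monotone in `γ` on `[0, min(1/n, c_total/c_DNA,bp))`,
giving a unique bracketed root (Brent's method, xtol 1e-15).

An alternative dialect that normalizes the exclusion factor by total dye
rather than DNA — numerator `(1 − n·c_bound/c_total)^n` — appears in parts
of the literature. It is available behind `solve_mvh(..., printed_variant=True)`
for comparison, but it is not used anywhere in the package: in the dilute-DNA
regime (`c_DNA ≪ c_total`) its residual has no root at all (the solver raises
a clear error), and where a root exists it disagrees strongly with the
standard form. We treat the DNA-normalized form as the physically meaningful
one: exclusion is a property of lattice occupancy, not of the dye pool.

## 2. Topology bookkeeping

Conventions, for closed (torsionally constrained) DNA:

- `Lk_0 = N_bp / 10.5` (relaxed helical repeat 10.5 bp/turn).
- Native supercoiling enters as `ΔLk_0 = σ_0 · Lk_0`.
- Each bound dye unwinds the duplex by `Δθ` degrees, so relative to the
  dye-adjusted relaxed state the effective linking difference is
  `ΔLk_eff = ΔLk_0 + N_bound · Δθ / 360` (bound dye drives the molecule
  toward positive `ΔLk_eff`; a negatively supercoiled substrate is first
  brought to zero, then overwound).
- `σ_eff = ΔLk_eff / Lk_0`.

**Twist/writhe partition.** A fixed fraction `f_Tw = 0.2` of `ΔLk_eff` is
stored as twist; the remaining 80% buckles into writhe. This is a standard
coarse approximation for stretched/plectonemic DNA at low force; the torque
that feeds back on binding is then

```
Γ = (2π · C · k_B T / L_c) · f_Tw · ΔLk_eff
```

with `C` the torsional persistence length (nm) and
`L_c = 0.34·N_bp + N_bound·Δz` the dye-extended contour length. (The
association-constant sweep `ka_vs_sigma` uses the bare contour, since there
it characterizes the substrate rather than a self-consistent state.)

**Torque and force in the binding constant.**

```
K_d_eff = K_d · exp(+Γ · Δθ_rad / k_B T) · exp(−F · Δz / k_B T)
```

Sign convention: positive (overwinding) torque penalizes intercalation,
because binding would unwind further against the torque; stretching force
favors it through the length gain `Δz`. `k_B = 0.01380649 pN·nm/K`;
default `T = 297 K` gives `k_B T = 4.1005 pN·nm`.

## 3. Self-consistent solver

On closed DNA, `γ` determines `Γ` which determines `K_d_eff` which
determines `γ`. We iterate the damped fixed-point map
`γ_{k+1} = (1−ω)·γ_k + ω·G(γ_k)` with `ω = 0.5`, halving `ω` when updates
alternate in sign, to tolerance `1e-10` in `Δγ` (cap 10 000 iterations).
Because the feedback is strictly negative (more binding → more overwinding →
weaker binding), `G` is monotone decreasing in `γ` and the fixed point is
unique; the tests verify this against an independent dense-grid bisection
oracle on randomized parameter sets.

## 4. Protocols

**Two-stage single-molecule protocol** (`single_molecule_protocol`):
stage 1 solves the open (zero-torque) isotherm at the attachment
concentration, giving `N_lock` bound dyes; tethering then locks the linking
number, recorded as `σ_lock = (N_lock·Δθ/360)/Lk_0` (reported as a
magnitude — it quantifies how far from relaxed the molecule is locked) and
internally as `ΔLk_0 = −N_lock·Δθ/360`. Stage 2 re-solves self-consistently
at the imaging concentration; the deliverable is `σ_final` (signed) and the
constrained/nicked bound-dye ratio, in which any intensity scale factor
cancels.

**TMP crosslinking curve** (`tmp_relative_binding`): closed/open binding
ratio versus native `σ_0`; `normalize=True` rescales by the `σ_0 = 0` ratio
so the curve reads as a relative crosslinking signal.

**Association-constant sweep** (`ka_vs_sigma`): relative `1/K_d_eff` versus
`σ`, exact and linearized (`1 − Γ·Δθ_rad/k_BT`). Since `exp(−x) ≥ 1−x`, the
exact curve bounds the linearization from above everywhere; the linear
supercoiling–crosslinking relation is only trustworthy at small `|σ|`.

**Bulk intensity table** (`bulk_intensity_table`): Cartesian sweep over dye
and DNA concentrations for closed and open substrates, intensity
`I = α·c_bound` with an optional gel staining correction factor applied to
`c_total`.

## 5. Kinetics

Post-nicking intensity relaxation is a delayed single-exponential step.
Fitting: bounded `scipy.optimize.least_squares` (`xtol=ftol=gtol=1e-14`),
initialized from the extremum of a 5-frame moving-average derivative of the
trace; `k ≥ 1e-9`, `t_0` within the sampled span. Standard errors come from
the Gauss–Newton covariance `(JᵀJ)^{-1} · RSS/dof`. Fits require ≥ 10
samples and a step exceeding 3× the noise estimate. Validation in the test
suite: on 120 simulated traces (20 ms frames, 5% relative noise) the rate
bias is < 2% and the nominal 95% confidence interval covers truth with
frequency in [0.88, 0.995].

`simulate_trace` adds i.i.d. Gaussian noise to the ideal step
(`numpy.random.default_rng(seed)`); it emulates shot-noise-limited
fluorescence traces only — no photobleaching, blinking, drift, or frame
integration.

## 6. Calibration fitting

`fit_alpha` recovers the intensity scale `α` as a slope-through-origin OLS
fit of measured intensity against model-predicted `c_bound` over a tidy
table of (DNA, concentration, topology) rows, with optional 1/σ² weighting.
`generate_gel_fixture` produces synthetic tables with multiplicative
Gaussian noise (clipped at zero); it emulates band densitometry with a
known staining correction, not gel-to-gel transfer or background
subtraction variability.

## 7. Parameters and presets

| Preset | n (bp) | K_d | Δz (nm) | Δθ (°) | recommended C (nm) |
|---|---|---|---|---|---|
| EtBr | 1.9 | 7.7 µM | 0.34 | 27 | 50 |
| SYBR_Gold | 1.6 | 0.2 µM | 0.34 | 19.1 | 100 |
| SYTOX_Orange | 3.0 | 0.4 µM | 0.30 | 19.1 | 100 |
| TMP | 2 | 100 µM | 0.34 | 28 | 100 |

Other defaults: base-pair rise 0.34 nm; helical repeat 10.5 bp/turn;
`T = 297 K`; force 0 pN; twist fraction 0.2. The headline single-molecule
numbers in the README use a 42 000 bp construct with `C = 100 nm` at
`c_DNA,bp = 10 pM`.

Condition choices made where an experiment-like context was needed:

- Bulk-assay DNA concentration for SYBR Gold comparisons:
  `c_DNA,bp = 15 µM` (≈ 10 ng/µl), a typical gel-loading density. At such
  densities dye depletion caps binding and closed/open staining of an
  initially relaxed substrate is near-unbiased (< 3% here); at
  single-molecule dilutions the same substrate can self-overwind
  substantially — the flat-response claim is a bulk statement.
- Gel-emulation EtBr concentrations (0.05/0.5/5 µM effective) are
  post-staining-correction values, i.e. stain concentrations of 0.5/5/50 µM
  with a 10× correction already applied.

## 8. Numerical and I/O choices

- Unique-root bracketing everywhere; no unbracketed Newton steps.
- The acceptance/regression oracles in the tests use an independent
  dense-grid + bisection path that shares no solver code with the package.
- TSV output carries a provenance header (version, SHA-256 config hash
  truncated to 12 hex digits, seed) and `%.17g` floats for byte-identical
  reruns.
- YAML configs are validated up front; unknown keys in any section raise a
  `ConfigError` naming the key.

## 9. Limitations

- The twist/writhe partition is a fixed constant, not force- or
  salt-dependent; no buckling transition is modeled.
- Binding parameters are torque-independent apart from the Boltzmann factor;
  cooperative or structure-specific (e.g. denatured-region) binding modes
  are out of scope.
- Kinetics assumes a single well-mixed rate; sequential plectoneme removal
  and dye transport are summarized by one apparent `k`. The helper
  `plectoneme_diffusion_time(L, D) = L²/D` gives an order-of-magnitude check
  that torsional relaxation is much faster than binding under typical
  imaging conditions.
- All noise models are Gaussian; detector nonlinearity and bleaching are not
  emulated.
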