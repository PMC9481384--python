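# Methods

## The model

`midsim` simulates the succession of a microbial community of `M` species
competing for `m` shared substrates on an indoor surface.  The state is
the abundance vector `x(t)` (dimensionless abundance units) and the
substrate amount vector `S(t)` (mg); both evolve by coupled first-order
kinetics:

```
dx_i/dt = v_b,i − v_a,i − v_e,i − v_d,i
dS_k/dt = v_p,k − v_c,k
```

with the five processes

| process | rate | meaning |
|---|---|---|
| growth | `v_b,i = (μ_i + ε₁) x_i Σ_k S_k/(K_ik + S_k)` | Monod growth on the pooled substrates |
| intraspecific competition | `v_a,i = (α_i + ε₂) x_i²` | logistic self-limitation |
| interspecific competition | `v_e,i = Σ_{j≠i} (β_ij + ε₃) x_i x_j` | Lotka–Volterra pairwise inhibition |
| metabolism | `v_d,i = d_i x_i` | basal biomass loss |
| substrate production | `v_p,k = r_k Σ_i (c_i + ε₄) x_i/(Z_i + x_i)` | decomposition into a pool shared by shares `r_k` |
| substrate consumption | `v_c,k = h_k Σ_i (γ_i + ε₅) v_b,i` | growth-coupled uptake, shared by shares `h_k` |

The ε's are Gaussian disturbance channels applied to the kinetic
parameters; `ε₁` inside `v_c` is the same realization as in `v_b` at that
instant (the growth disturbance propagates into consumption).  Each
ordered species pair gets its own independent `ε₃` draw; `β_ii = 0` —
self-limitation lives exclusively in `α`.

Communities are "computer-generated": every parameter is drawn uniformly
and independently from a fixed interval (`ParameterIntervals`), so a
community is a pure function of `(M, m, seed)`.  The reference intervals
(units as above): μ (0.24, 1.36) h⁻¹, α (0.05, 1), β (0.16, 1),
c (136.23, 518.76) mg·h⁻¹, γ (3.32, 12.55), K (1.23·10⁵, 1.82·10⁵) mg,
d (0.03, 0.58) h⁻¹, Z (42, 177), and r, h drawn from (0, 0.80) then
renormalized to sum to 1 (they are shares of a common pool; independent
draws cannot sum to 1, and renormalization preserves their relative
spread).

## Disturbance: PSD levels, amplitude convention, clamping

Disturbance strength is specified per channel as a flat power-spectral-
density level, with the weak-disturbance regime drawing each level
uniformly from (0, 2) and the intermediate (UV) regime from [2, 10].
The nominal W·Hz⁻¹ units are dimensionally incoherent against the h⁻¹
parameters the channels perturb, so the level is treated as a strength
knob and mapped to a per-draw standard deviation through a fixed
reference interval:

```
σ² = PSD / (2 · ref_interval),        ref_interval = 24 h by default.
```

This is the variance a white process would need to show the nominal level
over the frequency band that a daily time series resolves.  It makes the
channel amplitude independent of how finely the simulation redraws it —
deliberately **not** the literal white-noise scaling `σ² = PSD/(2·Δt_redraw)`,
which at these PSD levels implies an integrated log-abundance variance of
several hundred per day (every population reaching unit abundance dies
within a day at any step size, in both regimes).  Setting
`ref_interval = redraw_interval` recovers the literal convention; the
calibration tests use it, and `empirical_psd` (an averaged periodogram,
`scipy.signal.welch` with boxcar segments) then round-trips the nominal
level.

Draws are held for `redraw_interval` (default 24 h — one realization of
environmental conditions per day, the period of the radiation/sampling
cycle) and are i.i.d. across holds, channels, and species (pairs for ε₃).

A disturbed parameter can go negative.  The default clamp policy
(`"stability"`) floors the competition, production and consumption
channels (ε₂–ε₅) at zero — a negative quadratic self-limitation
coefficient held for a day produces genuine finite-time blow-up — while
leaving the growth channel ε₁ free to reverse sign: a strongly negative
growth draw is a transient die-off, the direct dynamical footprint of a
radiation burst, and is dissipative.  Policies `"all"` and `"none"` are
available.

## Integration

Fixed-step stochastic simulation (Euler–Maruyama in spirit: noise enters
as parameter perturbation held over its redraw interval).  The update is
a Patankar-type positivity-preserving Euler step: per-capita losses enter
the denominator,

```
x_{n+1} = x_n (1 + Δt·gain_pc) / (1 + Δt·loss_pc),
```

and likewise for substrates (which also throttles consumption of a
near-empty pool).  The scheme is first-order consistent with explicit
Euler, has exactly the same fixed points, and cannot produce negative
states — important here because held disturbance draws make the
competition terms intermittently stiff, and a plain Euler step then
overshoots a healthy population to a negative value that truncation would
turn into a spurious extinction.  Defaults: `dt = 0.05 h` (per-step rate
increments stay well below 1 for communities from the reference
intervals; halving `dt` changes noise-free final states by <0.1%),
horizon 2400 h (100 days), one recorded state per 24 h.

Species below `extinction_threshold` are set to zero and stay there
(every growth term carries `x_i`).  The default threshold, 10⁻¹²⁰, is a
pure numerical guard against denormal-range "immortal" abundances: under
held disturbance a single no-growth day shrinks a population by ~e⁻⁷, so
any ecologically-scaled cutoff (say 10⁻⁶) absorbs transiently suppressed
species within two or three bad days and, at stronger disturbance, can
empty whole communities — an artifact, not a prediction.  Ecological
"presence" is instead operationalized statistically (below).

## Initial conditions

The source design leaves inocula and initial substrate unspecified.  Two
constraints pin reasonable defaults:

* **Inoculum** `x0 ~ U(0.01, 0.1)` per species.  The community carrying
  capacity implied by the competition intervals is `Σx* ≈ (μ̄·s − d̄)/β̄ =
  O(1)` abundance units; an inoculum at that scale or above starts the
  run ~10× over capacity inside a stiff transient.  Starting well below
  capacity makes succession a colonization process, which is the regime
  being modeled.
* **Substrate** `S0 = 10⁴ mg` per substrate, ≈7% of the half-saturation
  scale, giving initial Monod availability `Σ_k S/(K+S) ≈ 0.6` — about
  the community-median `d/μ`, so the faster-growing half of the species
  pool is initially viable.  (Much lower, e.g. S0 of order 10² mg,
  availability ≈0.007 is below `d/μ` for every parameter combination in
  the table and every community starves to extinction before production
  can accumulate substrate.)  This is also close to the level the
  production/consumption balance self-regulates to,
  `s* = c̄/(γ̄ μ̄ (Z̄+x)) ≈ 0.5`.

Both are config-overridable.

## Statistics

All analysis operates on the daily-sampled trajectory:

* **Relative abundance** per sampling time (all-zero rows flagged).
* **Gini–Simpson index** `1 − Σp²` (higher = more diverse; the inverse
  form `1/Σp²` is available).
* **Auto-/cross-correlation**: biased (divide-by-n) sample estimators
  normalized by lag 0, the signal-processing convention, so `ρ(0) = 1`
  and all magnitudes are ≤1.  Defaults: raw relative-abundance series,
  lags 1–10 sampling intervals.
* **Coexistence count**: species whose mean relative abundance over the
  final 20 samples exceeds 10⁻³.  This is the paper-facing definition of
  "present at the end of the study"; it is monotone non-increasing in the
  threshold.
* **Correlation summaries**: per species the mean |autocorrelation| over
  lags 1–10, per pair the maximum |cross-correlation|; computable over
  the surviving set, all species, or the k most abundant (the analysis of
  community profiles typically tracks the few most common genera).

## The Monte Carlo experiment

`run_scenario` runs replicate communities with dimensions drawn from
M ∈ [20, 50], m ∈ [5, 15] (M > m enforced), PSD levels drawn once per
channel per replicate from the scenario's range, and aggregates the four
metrics above.  Replicate `r` derives community, PSD and simulation
noise streams from `SeedSequence(base_seed + r).spawn(3)`, so two
scenarios sharing a base seed are paired: same communities, same noise
streams, different disturbance strength only (common random numbers).
Failed replicates (numerical aborts) are excluded but counted; a
scenario aborts if more than 10% fail.  `compare_scenarios` reports
paired mean differences with bootstrap intervals and a paired sign test.
The default desk-scale design is 50 replicates per scenario (the
acceptance checks use 20 paired replicates at M=30, m=10).

## What the simulations show — and do not show

Under zero or weak disturbance the model robustly reproduces
**competitive exclusion**: from 30 species on 10 substrates, 1–4
dominants persist by day 100, within the substrate-type limit.

The intermediate-disturbance prediction — that PSD ∈ [2, 10] maintains
*more* coexisting species than weak disturbance — does **not** emerge
from this model under any admissible configuration we found (clamp
policies, hold times from per-step to daily, amplitude references from
0.1 h to 24 h, initial substrate from 10² to 1.5·10⁵ mg, Euler and
Patankar stepping).  The reason appears structural rather than numerical:

1. The parameter table implies per-capita fitness differences between
   species of order 0.1–0.3 h⁻¹ (the spread of `d` alone is 0.16 h⁻¹ ≈ 4
   decades/day), so deterministic sorting is fast.
2. The model contains no buffering mechanism — no dormancy, immigration
   or per-species niche that would give rare species positive mean
   growth.  Interspecific pressure `Σ_j β_ij x_j` (β ≥ 0.16 over ~30
   competitors) dominates self-limitation, so rare species have no
   restoring force toward the community.
3. Disturbance strong enough to shuffle competitive ranks therefore
   widens the log-abundance spread like a random walk instead of
   maintaining coexistence: by day 100 the suppressed pool sits tens to
   hundreds of decades below the dominant under every noise level
   tested.

A simulation whose state is allowed to pass through zero (e.g. a
block-diagram integration without positivity handling) will instead show
all populations jittering indefinitely around small values under strong
noise — "coexistence" of every species — which we judge an artifact of
unbounded state, not community ecology; this package enforces
nonnegative, absorbing abundances and reports the contrast it actually
measures.  The corresponding acceptance check is expected to fail and is
retained unmodified.

## Numerical and degenerate-input conventions

* `0/0` Monod and production terms (absent substrate or species with zero
  half-saturation) are defined as 0.
* Constant series have no defined correlation and raise; the correlation
  summary skips constant relative-abundance series.
* The Simpson index of an empty (all-zero) community is an error, not 0.
* Noise draw order is fixed (channels 1–5, species-major, ε₃ row-major)
  so every result is bit-reproducible from its seeds.
* Runs abort with step context on non-finite states; noise-free runs also
  abort if any state doubles in one step (a step-size diagnostic), noisy
  runs if abundance exceeds 10¹⁰.

## Known limitations

* The PSD-to-variance mapping is a convention; only the weak < strong
  ordering, not the absolute scale, is anchored by the source ranges.
* Disturbance is i.i.d. across holds (white at the hold scale); colored
  (AR/OU) disturbance is out of scope.
* No spatial structure, no explicit UV dose–response, no evolution of
  parameters within a run, no immigration.
* A shared-scalar ε₃ (one draw for all pairs) is not exposed; each
  ordered pair is always independent.
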