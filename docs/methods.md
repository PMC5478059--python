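# Methods

## Models

### Logseries metacommunity

The regional pool is a fixed, static rank-abundance vector following
Fisher's logseries: the expected number of species with abundance `n` is
`Φ_n = α x^n / n`, `x = N/(N+α)`.  Summing over `n` gives
`S = α ln(1 + N/α)`, solved for `α` by bracketed Brent iteration
(forward evaluation reproduces `S` to < 1e−9 relative).  There is no
speciation inside the pool; it only supplies immigrants.

**Ranked construction.**  The pool is materialized as integer abundances
from the most dominant species down.  Rank `r` receives the largest
integer `a` with `T(a) = Σ_{k≥a} α x^k / k ≥ r − ½` — a midpoint rule:
the construction procedure in the literature specifies left-tail-first
assignment but no rounding convention, and the midpoint is symmetric and
deterministic.  For pools of 10⁹–10¹⁰ individuals `x` sits within 1e−8
of 1 and the tail extends over ~`N/α` terms, so `T(a)` is evaluated as
the exponential integral `E1(aδ)` (with `δ = −ln x`) plus Euler–Maclaurin
corrections, with the first 2,048 terms summed explicitly; the
approximation is accurate to ~1e−10 relative where it takes over.  Any
integer deficit or surplus against `N` is absorbed starting at rank 1
without breaking monotonicity (in practice only rank 1 is touched, by
~1e−4 of its abundance).  Individuals and species are conserved exactly.

**Sampling** is multinomial on relative abundances (with replacement):
every pool exceeds every sample by ≥ 4 orders of magnitude.  A
hypergeometric (without-replacement) option exists for small test pools.

### Zero-sum dynamics

Both simulators hold every plot at exactly `J` individuals.  One
*generation* is `J` replacement events per plot; plots advance in
lock-step, one event per plot per sweep.

*Implicit model*: each event kills a uniformly random individual and
recruits from the metacommunity with probability `m`, otherwise copies
one of the `J−1` survivors uniformly (equivalently,
abundance-proportionally).  Plots are independent, which the
implementation exploits by batching plots — including whole replicate
grids at different `m` — into one vectorized run.

*Lattice model*: plots form a `rows × cols` grid (default 20×20,
`J = 500`).  The recruitment source is drawn from
{local: `1−m.adj−m.meta`, adjacent: `m.adj`, metacommunity: `m.meta`};
an adjacent recruit first picks one of the 8 Moore neighbours uniformly,
then a parent abundance-proportionally within that plot.  Individuals
have no positions within plots.  Choices that the model statement leaves
open, fixed here:

- **Edges**: torus by default, so every plot is statistically identical;
  a truncated mode (3–8 neighbours) exists for sensitivity checks.
- **Synchronous sweeps**: all parents are drawn from the start-of-sweep
  state and the one-death-per-plot scatter is applied at the end, so a
  neighbour's individual can reproduce in the sweep in which it dies.
  At `J = 500` the distinction from sequential updating is negligible,
  but it makes sweeps order-independent and fully vectorizable.
- **Local parents exclude the dying individual** (drawn from the `J−1`
  survivors) — the standard Moran convention, and the one that makes the
  exact `J = 2` chain enumeration in the tests come out in closed form.

**Run length.**  The default is 200 generations.  Stationarity traces
(pooled richness and mean within-plot identity every few generations)
show all configurations exercised here plateau by ~50 generations; the
within-plot identity plateau matches the moment prediction
`(I F_meta + 1)/(I + 1)` within sampling error.  The published lattice
table quotes a runtime of 1e8 events (≈ 500 generations at 400×500
individuals); runs at 500 generations give the same estimates as 200 to
three decimals, so the shorter default stands.

## Estimators

All estimators report per-plot values, their mean and cross-plot SD.
Per-plot `m̂` is clamped to [0,1] in the headline field with a diagnostic
flag; the unclamped value is preserved (`m_raw`), because under full
mixing the differentiation statistic legitimately lands just above 1 by
sampling noise.  Migration and immigration number convert by
`m = I/(I + J − 1)`.

**Differentiation statistic.**  Within-plot and pooled probabilities of
identity use the unbiased estimator `Σ n_i(n_i−1)/(J(J−1))` — at
`J = 500–625` the plug-in version visibly distorts `I`.  At equilibrium
of the implicit model `F_k = (I F_T + 1)/(I + 1)`, i.e.
`F_ST = 1/(I+1)`, inverted as `Î_k = (1−F_k)/(F_k−F_T)`.  Plots with
`F_k ≤ F_T` (no detectable differentiation) are flagged and capped at
`m̂ = 1`.  The exact mapping used by the original untb-based analysis is
not published in full; this moment form recovers `m` on the implicit
model itself, which is the testable contract.  Two limitations are
documented by the tests: the method is noise-limited when the pool is
low-diversity (per-plot identity noise exceeds the `1/(J−1)`
differentiation scale once `Σp³` is large), and per-plot inversion under
spatial correlation carries a small upward offset (~3% relative at the
lattice scenario `m.adj=.01, m.meta=.20`).

**Compound-multinomial likelihood ("Inference" family).**  The
stationary implicit local community is Dirichlet-multinomial with
concentrations `I p_i`; `p` is estimated from the pooled sample (a
leave-one-plot-out option exists).  `I` is maximized per plot on a
log-grid of 45 points over [1e−4, 1e7] refined by bounded Brent; hitting
a bound flags the plot.  Rising factorials `(a)_k` are computed as exact
sums of logs, not `gammaln` differences, which lose ~`ε·|ln Γ(a)|`
(catastrophic for `a ≳ 1e8`, exactly the `I → ∞` regime the tests probe).

**Genealogical sampling formula.**  `P[D|θ, I]` sums over the number of
immigrant ancestors `A`: per species, the coefficient of `a` ancestors
for `n` conspecifics is `s̄(n, a)(a−1)!` (unsigned Stirling numbers,
first kind), combined across species by log-space convolution into
`K(D, A)`; the formula then weights `K(D, A) I^A / (θ)_A`.  Stirling
rows are built by the log-space recurrence and cached; everything stays
in log space, so no overflow is possible at any `J` used here (≤ 625;
coefficient magnitudes near `J log J`).  Correctness anchors: exhaustive
partition sums equal 1 at `J ≤ 6` to 1e−9, and the `I → ∞` limit equals
the Ewens sampling formula.  The one-stage fit (nested scalar
optimization over `log θ`, `log I`) is known-unstable near `m → 1`: the
surface is a ridge (any `θ` fits once `I → ∞`) and is often *bimodal*,
with a spurious finite-`I`, inflated-`θ` global mode even for data drawn
from the `I = ∞` boundary.  Fits within 0.5 log-likelihood units of the
`I` cap are flagged as ridges; the tests assert the MLE-dominance
property rather than parameter recovery in that regime.  The two-stage
variant solves `θ` from the pooled `(N, S)` via the Ewens expectation
`S = θ[ψ(θ+N) − ψ(θ)]` and then profiles only `I` per plot, which
removes the ridge.

**Plot geometry.**  `m̂` is the probability that the parent of a recruit
uniformly located in a `w × w` square lies outside the square.  The
default kernel is an isotropic bivariate Gaussian displacement scaled so
the mean displacement distance equals `d` (Rayleigh mean,
`σ = d / √(π/2)`); the kernel family is not stated in the source
analyses, and the Gaussian is the one that reproduces the published
values (w = 100 m, d = 15–25 m → .237, interval .182–.293).  Gaussian
components separate, so only a 1-D Gauss–Legendre integral is needed;
the exponential-distance alternative integrates the distance-to-boundary
survival over a position × direction grid.  The `(low, high)` dispersal
range maps to interval endpoints; the linearized form `4wd/(πw²)` is the
`d/w → 0` perimeter approximation (within 2% of the exact integral at
`d/w = .02`).  A published *corrected* variant rescales the estimate by
a constant derived in material not available here; it is exposed as the
multiplicative `correction` parameter, default 1 (≈ 0.30 reproduces the
corrected published row).

**Singleton diagnostic.**  Observed pooled singletons divided by the
logseries expectation `α̂ N/(N+α̂)` at the pooled `(N, S)`.  Well-mixed
samples give ≈ 1; dispersal-limited communities fall below 1.

## Experiments and the synthetic field generator

*Recovery*: implicit simulations across a migration grid, 3 replicates
per point (the source tables are single runs; replication quantifies the
Monte-Carlo spread), scored as mean |m̂ − m| per estimator.

*Additivity*: one lattice run per `(m.adj, m.meta)` scenario; outputs
pooled species/singletons and each estimator's joint-`m̂` with the raw
(unclamped) mean as a diagnostic.

*Field emulation*: the implicit model run at a migration rate previously
estimated from a real inventory, e.g. 67 plots × 625 stems from the
low-diversity pool at `m = .046`.  This doubles as the synthetic
field-data generator: it emits plot×species matrices with the inventory
shapes (67/63/72 plots; uniform `J = 625`, the published simulation
convention — real plots have unequal stem counts, which the generator
deliberately ignores).  Reported Fisher's alpha comes in two versions,
because the published table's caption and its numbers disagree: the
*pooled* alpha (solved from pooled `N, S`; this is what the printed
values equal) and the mean of per-plot alphas (plots with `S = 1` or
`S = J` are excluded — a logseries fit cannot represent them).

What the emulation does **not** reproduce about real data: unequal plot
sizes, taxonomic standardization noise, habitat heterogeneity, distance
decay within a region, and any non-neutral process.  Passing tests
therefore show the estimation machinery is faithful to the neutral
models, not that the models describe the forests; indeed the emulated
inventories systematically hold fewer species and singletons than their
field counterparts, which is itself one of the reproduced findings.

## Problem sizes and determinism

Test-suite and acceptance runs use the study's plot geometry (20×20 ×
J=500 lattices; 67 × J=625 implicit emulations) with recovery suites
reduced to 20 plots × 3 replicates per grid point, and 200-generation
runs throughout; at these sizes the full pipeline completes in minutes
on one CPU.  Noisy scalar outputs (pooled singleton counts have a
cross-run SD of ~13) are averaged over replicate simulations rather than
widened in tolerance.  Every simulation consumes a single
`numpy.random.default_rng` stream from an explicit seed; reruns with the
same configuration are bit-identical, and the CLI writes a manifest
(resolved config, seed, output checksums) next to every output file.

## Known limitations

- The exact published differentiation-statistic and Inference-method
  likelihood variants (appendix material not available here) may include
  finite-`θ` corrections absent from the moment form; recovery on the
  models themselves is the implemented contract.
- The one-stage sampling-formula fit inherits the genuine bimodality of
  its likelihood; it is provided with diagnostics, not repaired.
- Whether the original analysis applied the one-stage formula per plot
  or to pooled samples is unstated; per-plot is implemented (pooling is
  a one-liner on the pooled counts).
- `m̂` near 0 or 1 sits on parameter boundaries where all
  composition-based estimators degrade; flags mark capped or
  boundary-bound plots.
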