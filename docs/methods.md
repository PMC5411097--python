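# Methods

## The model

`crisprdyn` simulates the early population dynamics of a well-mixed culture of
bacteria defending against a lytic phage with CRISPR adaptive immunity, on
timescales short enough that each cell acquires at most one spacer and the
phage does not yet escape by mutation.

### Single spacer type

Five compartments: healthy wild-type bacteria `n0`, healthy spacer-enhanced
bacteria `n1`, the corresponding infected compartments `I0` and `I1`, and free
phage `v`. The dynamics are

    dn0/dt = f0 (1 - n/K) n0 + kappa n1 - g v n0
    dn1/dt = f1 (1 - n/K) n1 - kappa n1 - eta g v n1 + alpha mu I0
    dI0/dt = g v n0 - mu I0
    dI1/dt = eta g v n1 - mu I1
    dv/dt  = b (1 - alpha) mu I0 + b mu I1 - g v (n0 + n1)

with `n = n0 + n1 + I0 + I1`. Healthy bacteria grow logistically toward the
carrying capacity `K`; infected cells do not divide but still occupy capacity.
Phage encounter bacteria at rate `g` per phage; a spacer blocks the infection
except with failure probability `eta` (so `1 - eta` is its effectiveness).
Infected cells lyse at rate `mu` — the latent period is approximated as
exponentially distributed with mean `1/mu` rather than a fixed delay — and
release `b` phage, unless a wild-type cell survives the infection and
integrates a spacer (probability `alpha`, feeding `I0 -> n1`). Spacers are
lost at rate `kappa`, reverting carriers to wild type.

Two modelling conventions are taken exactly as the equations are written and
deliberately not "corrected":

* infected cells occupy carrying capacity but do **not** adsorb phage in the
  `dv/dt` loss term (only healthy `n0 + n1` do);
* acquisition of a second spacer by an infected spacer-enhanced cell is
  neglected (`I1` always lyses), justified when `alpha << 1` and `eta << 1`.

Summing the four bacterial equations gives the total-bacteria equation

    dn/dt = f0 (n0 + r n1)(1 - n/K) - mu (1 - alpha) I0 - mu I1,

with `r = f1/f0`; `total_derivative_single/multi` implement it and the test
suite checks the sum identity on random states to machine precision of the
summed terms.

### N spacer types

With `N` protospacers, spacer type `i` has acquisition probability `alpha_i`
and failure probability `eta_i`; acquisitions are disjoint events so
`alpha = sum_i alpha_i < 1`. All bacteria grow at the common rate `f` (the
single-spacer model's `r != 1` option has no multi-spacer counterpart here).
The state is `[n0, n_1..n_N, I0, I_1..I_N, v]` and the equations generalize
compartment-wise. At `N = 1` the system is arithmetically identical to the
single-spacer model with `r = 1`; the reduction is exact to the last bit and
is used as a cross-check of both code paths.

### Optional extensions

`dilution` subtracts `d * x` from every compartment and `phage_decay` an
additional `delta * v` from the phage equation; both default to 0. They exist
to test robustness of the qualitative picture, not as calibrated chemostat
terms. The closed-form steady-state theory below assumes both are zero and
refuses to run otherwise; `steady_state_numeric` covers the extended system.

## Steady-state theory

Units: all rates are quoted relative to the wild-type growth rate; the
defaults set `f0 = f = 1` so `kappa = 1e-2` means "one spacer loss per hundred
wild-type doublings". Config files use the same convention (`units: relative`,
the default) and rescale by `f0` internally.

### Coexistence, single spacer

At a coexistence fixed point the bacteria stop short of capacity. Writing
`F = 1 - n/K` for the fraction of unused capacity, equal growth rates
(`r = 1`) give the closed forms

    F      = (kappa/f0) (b(1-alpha) - 1) / ((b-1)(1 - b eta))
    n1/n0  = (b(1-alpha) - 1) / (1 - b eta)
    g v*   = b f0 F

The ratio `n1/n0` is independent of the growth rates. Coexistence requires
spacer loss (`kappa > 0` — otherwise wild type is not regenerated and the
phage starve or win outright) and `F < 1`, i.e. a failure probability below

    eta_c = (1/b) (1 - (kappa/f0)(b(1-alpha)-1)/(b-1)),

slightly below the interference threshold `1/b` at which the expected phage
yield per encounter with a spacer-carrying cell, `b eta - 1`, turns positive.
The `O((r-1)/b^2)` correction for unequal growth rates is dropped; for
`r != 1` the package locates fixed points numerically instead
(`steady_state_numeric`, a modified-Powell root finder on the full RHS with a
scaled-residual acceptance test, default `1e-9`).

The full fixed point (`coexistence_state_single`) follows from stationarity of
the infected equations, `I0 = g v n0 / mu` and `I1 = eta g v n1 / mu`, with
the absolute scale set by `n = K(1-F)`. Note that while `n`, `v*` and `n1/n0`
are independent of the lysis rate `mu`, the healthy/infected split is not
(`I0` scales as `1/mu`); robustness tests therefore assert `mu`-invariance of
the former three observables.

### Coexistence, N spacers

The same forms hold with `eta` replaced by the abundance-weighted mean failure
probability `eta_bar = sum_i eta_i n_i / sum_i n_i`, and per-spacer ratios

    n_i/n0 = alpha_i b f F / (kappa - f F (1 - eta_i b)).

Because `eta_bar` depends on the `n_i` and `F` depends on `eta_bar`, this is a
one-dimensional self-consistency problem. `solve_coexistence_multi` solves it
by bracketed root finding on `h(eta_bar) = eta_bar - weighted_mean(eta;
n(eta_bar))`:

* the root must lie in `[min eta_i, max eta_i]` (a weighted mean), and below
  the value at which the smallest-`eta` denominator
  `kappa - f F (1 - b eta_min)` hits zero; the bracket is the intersection,
  on which `h` changes sign;
* Brent's method at machine precision (`xtol = 1e-15`), so the recomputed
  weighted mean reproduces the solved `eta_bar` to ~1e-15;
* a 100-point sign scan over the bracket flags multiple crossings (none have
  been observed) via a `RuntimeWarning` and the diagnostics dict;
* the assembled full state (including infected compartments and
  `v* = b f F / g`) is checked by evaluating the full RHS; `valid=False` (not
  an exception) marks solutions violating positivity (`F >= 1` or a
  non-positive denominator).

Degenerate cases: all-equal `eta_i` short-circuits to `eta_bar = eta` (the
ratios then reduce to `n_i ∝ alpha_i` exactly); `kappa = 0` raises, since
coexistence requires spacer loss.

### Regime classification

`classify_regime` maps parameters to one of three asymptotic labels:
coexistence (`kappa > 0`, `eta < eta_c`), phage extinction with bacteria at
capacity (`kappa = 0`, `eta < 1/b`), or bacterial extinction otherwise.
Boundary values (`eta` exactly at `eta_c` or `1/b`) are labelled bacterial
extinction because the coexistence formulas diverge there — a conservative
tie-break. For `r != 1` the label is decided by numerically probing for an
interior all-positive fixed point seeded from the `r = 1` assembly.
`classify_outcome` makes the same call from an integrated trajectory endpoint
using an extinction threshold, default `1e-6 K` (an ODE never reaches exactly
zero; the threshold operationalizes "extinct" at far below one cell for any
realistic `K`).

## Numerics

* **Integrator**: LSODA via `scipy.integrate.solve_ivp`, `rel_tol = 1e-8`,
  `abs_tol = 1e-10`. Populations traverse ≥ 9 orders of magnitude during
  near-extinction transients and the post-peak phage decay is stiff.
* **Non-negativity**: the RHS is evaluated as written, without clamping — the
  flow preserves the non-negative orthant analytically. A trajectory dipping
  below `-100 * abs_tol` is treated as solver failure and raises.
* **Output grid**: logarithmic in time by default (7 decades up to `t_max`,
  with `t = 0` prepended); the transient structure spans decades.
* **Horizons**: default `t_max = 1e4` growth times, which reaches the fixed
  point to ~1e-6 for the single-spacer regimes exercised here (damped
  oscillations at `kappa/f0 >= 1e-3` settle well before). The winner-take-all
  multi-spacer runs relax at a rate set by the smallest ratio denominator
  `kappa - f F (1 - b eta_min)` (~5e-5 for the reference grids), so
  steady-state comparisons for those use `t_max = 1e5`; each such run still
  takes well under a second.
* **Steady-state detection**: the scaled derivative norm
  `||rhs|| / (||y|| + 1)` must stay below `steady_tol` (default `1e-6`) over
  the last 5% of the grid.
* **Transient summary**: phage peak, post-peak minimum, bacterial bottleneck,
  and oscillation count as strict local maxima of `v` on the raw output grid
  after the main peak — no smoothing, so the count is grid-resolution
  dependent by construction.

## Scenario generators

The generators make every regime reproducible without external data.

* `single_invasion_scenario(eta, r)`: `K = 1e5`, `alpha = 1e-4`, `b = 100`,
  `g = 1e-5`, `mu = 1`, `kappa = 2e-3` (all relative to `f0`), starting from
  `n(0) = 1000` all-wild-type cells and `v(0) = 1e4` phage — the
  coexistence/damped-oscillation showcase regime; `eta` and `r` select the
  regime.
* `unused_capacity_sweep()`: `kappa = 1e-2`, `b = 100`, `r = 1`, `eta b` on
  `[0, 0.95]` for `alpha in {0, 1e-4, 1e-2}` — the family on which the
  `F(eta b)` curve rises and diverges toward `eta b -> 1` and decreases
  linearly in `alpha`.
* `multi_spacer_scenario(mode, N=20, alpha_total=0.0972)`: `b = 100`,
  `K = 1e5`, `mu = 1`, `g = 1e-4`, `kappa = 1e-2`. The per-spacer grids are
  not uniquely determined by the regime being emulated, so the package fixes
  documented defaults: `eta_i` linear on `[0.0005, 0.0095]` (kept below
  `1/b = 0.01` so every spacer can sustain coexistence) and, where `alpha_i`
  varies, a linear ramp proportional to `1..N` normalized to `alpha_total`.
  Correlated/anticorrelated modes pair the two grids by rank (same/opposite
  order). Initial condition mirrors the single-spacer invasion (all wild
  type, `v(0) = 1e4`).

One initial-condition subtlety: with `alpha = 0` the spacer compartment has no
source, so an all-wild-type start can never reach the coexistence state. The
steady-state agreement checks therefore start `alpha = 0` runs from a
pre-mixed population (`n0 = n1 = 500`) — the same preparation one would use
experimentally to measure spacer effectiveness with acquisition disabled.

## Diversity metrics

`spacer_fractions` normalizes the healthy spacer-carrier abundances
(infected cells excluded). Two summaries operationalize the
diversity-vs-specialization axis: Shannon entropy (nats, 0 to `ln N`) and the
winner share (top-1 fraction). Established consequences of the ratio formula,
all covered by tests:

* equal `eta_i`: fractions are exactly `alpha_i / alpha_total` (acquisition
  differences act linearly);
* equal `alpha_i`: the minimum-`eta` spacer wins, overwhelmingly so at small
  `alpha_total` (winner share > 0.99 at `alpha_total = 1e-3`), because
  `eta_i` sits in a near-singular denominator;
* raising `alpha_total` flattens the distribution: entropy is non-decreasing
  across `alpha_total in {0.001, 0.01, 0.0972, 0.5}`.

Pairing acquisition with effectiveness (anticorrelated mode) shifts the
distribution further toward effective spacers: the self-consistent `eta_bar`
drops and the cumulative mass on the more-effective half rises relative to
the constant-`alpha` control. Counterintuitively, the top-1 winner share
*decreases*: the lower `eta_bar` lowers `F`, which weakens the denominator
amplification of the single best spacer more than its larger `alpha_i` helps.
Both metrics are reported so either reading of "skew" can be checked; the
property test asserts the mass-shift formulation.

## What the generators do and do not emulate

The scenarios reproduce parameter regimes (rates, sizes, grids), not measured
data: passing tests show the implementation agrees with the model's own
analytic theory and qualitative regime structure, not that the model fits any
particular bacteria-phage experiment. Real systems add demographic noise
(extinctions at small counts that the ODE cannot produce), phage escape
mutants, priming, multi-spacer cassettes, and spatial structure — all outside
scope here.

## Known limitations

* Deterministic ODEs only; "extinction" is a thresholded asymptote.
* No formal stability or bifurcation analysis of the fixed points; stability
  is probed only by integration.
* The `r != 1` critical failure probability has no closed form here; the
  numeric probe in `classify_regime` brackets validity by root-finding
  success, which is slower and less sharp than the `r = 1` formula.
* Oscillation counting is grid-based and will undercount under-resolved
  ringing.
* The multi-spacer model assumes a common growth rate; spacer-dependent
  growth costs exist only in the single-spacer model via `r`.
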