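# Methods

## Model family

The package simulates a three-gene feed-forward loop: a transcription
factor (TF) gene, a miRNA gene and a target gene. Five molecule counts are
tracked — TF mRNA `w`, TF protein `q`, miRNA `s`, target mRNA `r`, target
protein `p`. The TF subsystem is linear,

    dw/dt = k_w − g_w w,        dq/dt = k_q w − g_q q,

and decouples from the rest; its fixed point is `w* = k_w/g_w`,
`q* = k_q w*/g_q`, and its full time course has a closed form (with the
confluent `t·e^{−gt}` branch when `g_w = g_q`, detected at relative
difference below 1e−12). That closed form is used as an independent oracle
for every numerical trajectory.

Transcription of the miRNA and target genes follows Hill kinetics in `q`
with coefficient `c = 2` (configurable, even): activation
`k_max q^c/(h^c + q^c)`, repression `k_max h^c/(h^c + q^c)`. The four
topologies `1In (+,+)`, `1C (+,−)`, `2In (−,−)`, `2C (−,+)` are the sign
choices for (miRNA gene, target gene). The three miRNA mechanisms modify
only the `r` and `p` equations:

| mechanism | dr/dt | dp/dt |
| --- | --- | --- |
| Stop | `k_r(q) − g_r r` | `k_p h_p^c/(h_p^c+s^c) · r − g_p p` |
| Target degradation | `k_r(q) − [g_r + g_max s^c/(h_g^c+s^c)] r` | `k_p r − g_p p` |
| Dual degradation | `k_r(q) − g_r r − k_rs r s` (and `−k_rs r s` in ds/dt) | `k_p r − g_p p` |

The dual-degradation protein equation uses the protein degradation rate
`g_p`; with the default coefficients `g_s = g_p = 0.002 s⁻¹` this choice is
numerically indistinguishable from the alternative reading, and it keeps
the protein equation identical across mechanisms.

## Default coefficients

`default_parameters()` returns the reference set used everywhere unless
overridden:

    k_w=0.06, g_w=0.004, k_q=0.04, g_q=0.002, k_s=0.5, h_s=h_r=200,
    g_s=0.002, k_r=0.08, g_r=0.004, k_p=0.8, g_p=0.002, h_p=60,
    g_max=0.004, h_g=60, k_rs=2e−5, c=2

(synthesis maxima in molecules/s, first-order rates in 1/s, half-constants
in molecules, `k_rs` in 1/(molecule·s)). Under this set `q* = 300` and the
slowest relaxation times are 250–500 s, so one 5000 s cell cycle reaches
(or closely approaches) steady state. `k_rs = g_r/200` ties the complex
degradation to the basal mRNA turnover.

Degenerate half-constants are resolved by continuity from `x > 0`:
activation with `h = 0` returns `k_max` everywhere (including the 0/0
point at `x = 0`); repression returns 0 for `x > 0` and `k_max` at
`x = 0`. This keeps sweep grids that start at 0 well defined.

## Steady states

Fixed points are computed algebraically, not by long integration, so that
the "half of steady state" initialization is exact per mechanism:

* Stop / target degradation: substitute `q*` into the production Hills,
  then `s* = k_s(q*)/g_s`, `r* = k_r(q*)/g_r` (Stop) or
  `r* = k_r(q*)/[g_r + g_max s*²/(h_g²+s*²)]`, and the protein balance.
* Dual degradation: eliminating `s = k_s(q*)/(g_s + k_rs r)` leaves
  `g_r k_rs r² + [g_r g_s + k_rs(k_s(q*) − k_r(q*))] r − k_r(q*) g_s = 0`,
  whose constant term is ≤ 0, so exactly one root is nonnegative; it is
  evaluated in the cancellation-safe form and recorded in the result's
  `branch` field. A damped fixed-point iteration serves as the brute-force
  cross-check in the tests.

Every returned fixed point carries a certificate: the maximum absolute
derivative of the full system evaluated at it (required < 1e−9).
Uniqueness is exercised numerically: integrating to 1e6 s from 0×, ¼×, ½×,
2× and 4× the fixed point converges to the same state to 1e−6 relative in
all 12 variants.

`calibrate_parameter_for_protein_ss` solves the inverse problem of placing
`p*` at a requested level by varying one of `g_r, g_p, k_p, k_rs, g_max`
(each monotone in `p*`), via geometric bracket expansion and Brent's
method, with a post-check at 1e−8 relative. This supports the
matched-steady-state comparisons where mechanisms share both initial
conditions and endpoint but differ in transient shape.

## Time integration

The default solver is adaptive RK45 (`scipy.integrate.solve_ivp`) at
`rel_tol = 1e−8`, `abs_tol = 1e−10`, sampled on a 1 s output grid over
5000 s; the system is non-stiff at the default rates. A fixed-step RK4
mode on the same grid exists for the noise experiment, where perturbed and
unperturbed runs must be comparable step by step. Initial conditions
default to half the mechanism-specific steady state (molecule counts halve
at cell division); initial-value studies scale a single species to
{0, ¼, ½, 2, 4}× its steady-state count. Nonnegativity of the solution is
monitored, not enforced — a projection could mask model errors. Inside
derivative evaluations, Hill inputs are clamped at 0 so that transient
solver undershoot (within `abs_tol`) cannot leave the functions' domain.

## Noise experiment

The TF perturbation is a stationary Gaussian AR(1) sequence

    z_i = e^{−0.1} z_{i−1} + sqrt(1 − e^{−0.2}) ξ_i,   z_0 ~ N(0, 1),

the discretization of an Ornstein–Uhlenbeck process with unit stationary
variance and lag-1 autocorrelation e^{−0.1} ≈ 0.905. The square-root
innovation scaling is the reading under which the process actually has
unit variance; the linear alternative `(1 − e^{−0.2}) ξ` is available as
`innovation="linear"` for sensitivity analysis. On the default 1 s grid
the correlation time is 10 s.

In the perturbed run the quantity `max(0, q(t_i) + A·z_i)` replaces `q`
inside the miRNA and target production Hills only (zero-order hold within
each RK4 step, clamping events logged); the TF's own equations are never
perturbed, so `w` and `q` coincide bitwise between the pair. The default
amplitude is `A = 0.10·q*` — a 10% disturbance, small enough not to
overwhelm the signal. For each replicate

    NA = max_t |q − (q + A z)| / q*,   NB = max_t |p − p_n| / p*,
    ε = (NB − NA)/NA,

i.e. deviations are normalized per species by its steady-state count so NA
and NB are relative noise powers; `normalization="raw"` compares plain
molecule counts instead. An ensemble (default 100 replicates, seeds
derived deterministically from one master seed via `SeedSequence`) yields
the mean ε and the count of replicates with ε > 0; ensembles are
integrated as one vectorized RK4 batch against a single shared clean run,
which keeps a 100-replicate cell near one second of CPU. Ensembles are
compared with a two-sided Wilcoxon test — signed-rank when the two share a
seed list (paired noise), rank-sum otherwise.

## Sweeps and tables

The one-at-a-time grids are `h_s ∈ {1,100,200,400}`,
`k_q ∈ {0.02,0.04,0.08,0.16}`, `k_s ∈ {0.01,0.25,0.50,0.75}` and a
mechanism-specific strength coefficient `h_p` or `h_g ∈ {30,60,120,240}`,
`k_rs ∈ {1,2,4,8}·10⁻⁵`. Each cell of a noise table re-derives its own
steady state (hence its initial condition) under the swept value, and its
seed is a stable hash of (master seed, loop, mechanism, coefficient,
value), so tables are reproducible and independent of evaluation order.
Monotonicity facts checked by the suite: `h_p↑ ⇒ p*↑` (Stop, 1In),
`k_rs↑ ⇒ p*↓` (Dual, 1In), `h_s↑ ⇒ p*↑` in 1In and `p*↓` in 2C for all
mechanisms.

## What the simulations do and do not show

All experiments are self-contained simulations of the deterministic ODE
family plus the injected OU disturbance; no external data are read. The
generator therefore emulates *extrinsic* TF fluctuations of a chosen
amplitude and correlation time — it does not model intrinsic birth–death
noise, bursting, delays, multiple miRNA binding sites or competition among
targets, so a negative ε here demonstrates filtering of slow extrinsic
input noise, not total noise rejection in a real cell.

The ε statistic is sensitive to the ratio of the noise correlation time to
the loop's relaxation times (hundreds of seconds). With the default 10 s
correlation time the loops filter strongly (1In means around −0.9 across
mechanisms); stretching the correlation time toward the system time scale
(e.g. decay e^{−0.01} per second, correlation time 100 s) weakens
buffering substantially (means around −0.8 at small `k_q`, approaching
−0.5 at 500 s). Reported ε values should always be read together with the
grid step and decay recorded in their config block. The amplitude, by
contrast, matters little in the 5–15% range (ε is nearly
amplitude-invariant in the small-perturbation regime, a property the suite
checks).

## Numerical conventions

* Hill `sign=+1/−1` pair always sums to `k_max` (tested property).
* Dual-degradation quadratic: stable root form `2(−c₀)/(b + √disc)` when
  `b ≥ 0` avoids cancellation at small `k_rs`.
* Confluent linear solution switch at `|g_w − g_q| < 1e−12` relative.
* Trajectory CSVs store shortest round-trip float representations, so
  write-then-read is bit-exact; every artifact embeds its resolved
  configuration and seeds.
* Problem sizes used by the standard protocols: 5000 s horizon at 1 s
  output, 100 replicates per noise cell, 1e6-step series for OU
  statistics, 1e6 s horizon for the convergence certificates.
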