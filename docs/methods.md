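# Methods

## The model behind the connectivity estimate

Each recorded channel is treated as a point process on a common session
clock. For a chosen *target* train, the hazard of its next spike at age
`u` (backward recurrence time, the time since the target last fired) is a
modulated renewal process

    lambda(t) = lambda0(u) * exp( sum_j beta_j Z_j(t) ),

where `lambda0` is an arbitrary, unmodelled baseline hazard and each
simultaneously recorded *reference* train `j` contributes an influence
covariate

    Z_j(t) = exp( -(t - s_j(t)) / tau ),        Z_j = 0 before j's first spike,

with `s_j(t)` the reference's latest spike at or before `t`. `Z_j` spikes
to 1 whenever the reference fires and decays with time constant `tau`
(default 10 ms, configurable), so `beta_j > 0` means "the target is more
likely to fire shortly after train j fires", i.e. a directed functional
influence `j -> target`.

`beta` is estimated by Cox partial likelihood, which eliminates
`lambda0`: each inter-spike interval of the target is one observation
whose survival time is the ISI length; the leading and trailing partial
intervals are right-censored; the risk set at elapsed time `u` is every
observation still "alive" at that age, with covariates evaluated at the
observation's own absolute time (interval start + `u`). Ties use the
Breslow convention (they have measure zero at floating-point resolution).
Because all references enter one joint fit, each coefficient is
conditioned on every other recorded train, unlike pairwise
cross-correlation; a `pairwise` mode exists for comparison.

Fitting is Newton–Raphson from `beta = 0` with monotone step halving
(the partial likelihood is concave up to ties), convergence when the full
Newton step falls below 1e-8, standard errors from the inverse observed
information, and two-sided Wald intervals at level `1 - alpha` (default
alpha 0.05). An edge `j -> target` is called when the interval excludes
zero. By default no multiple-testing correction is applied; Bonferroni
and Benjamini–Hochberg are available by configuration. References with no
spikes or a constant covariate are dropped with a warning; targets with
fewer than `min_events` ISIs (default 30) or a non-converged fit yield an
empty column, never a crash.

Implementation note: risk-set membership and the covariate matrix do not
depend on `beta`, so the design is materialized once per target
(vectorized over all event x at-risk pairs) and every Newton iteration is
dense linear algebra. The design grows as (number of ISIs)^2 / 2 rows; a
guard refuses fits beyond ~2 GB and suggests shortening the record.

## Preprocessing conventions

A stimulus's recording is the concatenation of its trial intervals onto a
gapless axis (half-open intervals, 0-based origin); spikes between trials
are discarded and ISIs spanning a trial boundary are kept as-is, treating
the selected intervals as one continuous record. The alternative —
censoring boundary-spanning ISIs at the boundary — is available as
`split_isis_at_boundaries` because such ISIs are statistically suspect;
the censored remainder is discarded rather than left-truncated, since the
renewal age origin is undefined mid-interval.

Channel screening: a channel is excluded when its rate exceeds a ceiling
(default 20 Hz, the upper edge of the "medium" cortical band) under any
stimulus, or stays below a floor under all stimuli. On the published
32-channel rate table this flags exactly channels 4, 5, and 29. Remaining
channels keep their original labels.

## Graph measures

On the binary directed graph (rows = sources, columns = targets, zero
diagonal):

* density `m / n(n-1)`;
* characteristic path length: mean BFS distance over *reachable* ordered
  pairs — real connectivity graphs contain nodes with no in-edges, so
  unreachable pairs must be excluded for the measure to exist (choice
  documented: alternatives penalize or include infinities);
* global efficiency: mean of `1/d` over all ordered pairs, `1/inf = 0`;
* clustering: the directed (Fagiolo) coefficient
  `C_i = [(A+A^T)^3]_ii / (2[d_tot(d_tot-1) - 2 d_bidir])`, which counts
  all directed triangle orientations and attains 1 on fully bidirectional
  triangles; nodes with a zero denominator are undefined and excluded
  from the global mean. Which directed clustering variant produced the
  published per-stimulus values is not stated; this one is used because
  the published node values reach 1.0, which the undirected projection
  does not force;
* betweenness: Brandes directed shortest-path betweenness with fractional
  counting, normalized by `(n-1)(n-2)` (computed via networkx, verified
  against exhaustive path enumeration);
* high-degree rule: total degree above mean + 1 SD, with the *population*
  SD (divide by n) — the convention is arbitrary but fixed; hubs are the
  high-degree nodes ordered by degree, then betweenness, then label.

## Motif census and null ensemble

A structural motif is the isomorphism class of the induced subgraph on a
weakly connected triple; 13 classes exist, numbered by the classical
triad-census order (021D, 021U, 021C, 111D, 111U, 030T, 030C, 201, 120D,
120U, 120C, 210, 300) so that IDs match the ordering used in the
brain-connectivity structural-motif literature. The 64-configuration
lookup is built at import by canonical-form enumeration and verified
permutation-invariant in tests. Counting is structural (each triple once,
by its full induced subgraph); a functional mode also credits connected
sub-patterns.

Significance: `n_null` (default 1000) randomizations by edge switching —
swap (a→b, c→d) to (a→d, c→b), rejecting self-loops and duplicates —
preserve every in- and out-degree exactly; `swap_factor * m` attempts
(default 100, a standard mixing heuristic). For each class
`z = (count - null mean) / null SD` (undefined when SD = 0) and the
one-sided enrichment p-value is `(1 + #{null >= observed}) / (n_null+1)`;
"significant" means p < 0.05. The original analysis did not state its
significance rule; z-scores are reported alongside so either reading is
available.

## P1 model

Holland–Leinhardt dyad-independent model: each unordered pair is in one
of four states with probabilities proportional to `1`,
`exp(theta + alpha_i + beta_j)` (i→j), the mirror term, and
`exp(2 theta + rho + alpha_i + alpha_j + beta_i + beta_j)` (mutual).
`alpha` is expansiveness (propensity to send), `beta` attractiveness
(propensity to receive), `theta` density, `rho` reciprocity. The MLE
solves the moment conditions (expected in/out degrees, edge total, mutual
count) by damped (0.5) iterative proportional scaling, tolerance 1e-6,
at most 500 iterations; identification fixes finite `alpha` and `beta`
to sum to zero.

Degenerate degrees (0 or n−1) have infinite MLEs; they are held at ±40 on
the log scale during iteration (numerically exact 0/1 probabilities),
reported as ±inf sentinels, and excluded from the zero-sum constraint and
from rankings. A node that nothing points at therefore fits cleanly. A
*saturated* sender (out-degree n−1) additionally forces its recipients'
in-degree moments and can push other parameters to the likelihood
boundary; such fits may report non-convergence, which is the honest
answer. The reciprocity term is included (whether the original fit had
one is unstated); with zero mutual dyads `rho = -inf` is handled the same
way.

## Synthetic generator

The generator exists so that every estimator in the package has a
parameter-recovery surface with known truth; it deliberately matches the
Cox estimator's assumed intensity,

    lambda_i(t) = lambda0_i(u_i) * exp( sum_{j->i} w_ji Z_j(t) ),

so recovery is a well-posed test of the estimator rather than of model
mismatch. Baselines are renewal processes: Poisson (constant hazard) or
gamma ISIs with shape >= 1 (hazard increasing to the finite asymptote
`shape * rate`); default gamma with shape 2 and 8 Hz, inside the 2–20 Hz
band of the retained channels in the study design this emulates. The
default session layout is that study's: 29 channels, 6 stimuli, 20 trials
of 6 s each (120 s per stimulus), randomized order, 1 s silent gaps,
coupling graphs at density ~0.10 with weights in [0.8, 1.5].

Simulation is exact Ogata-style thinning: each node's intensity is
dominated by the constant bound `hazard_sup * exp(sum of positive
incoming weights)` (valid because `Z <= 1` and the gamma hazard is
increasing), candidates come from the bounding Poisson superposition, and
rejections advance time without changing state. The origin is a virtual
renewal epoch for every node; influence covariates stay zero until the
reference actually fires. A bound whose log exceeds 30 raises an error
naming the offending node. Trials are independent realizations and gaps
are silent.

What the generator does *not* emulate: refractory structure beyond the
renewal baseline, rate nonstationarity within trials, common-input
latent drive, conduction delays, or spike-sorting artifacts. Passing
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not robustness of the method on real cortical
data.

## Problem sizes used in tests and the acceptance script

Simulation-based checks are sized to be informative yet quick, as this
package's own choice of test design: type-I calibration uses 40 sessions
of 6 independent 8 Hz Poisson trains over 120 s (200 intervals in total;
measured call rate 0.050); interval coverage uses 100 two-train sessions
with a planted coupling of 1.0 (measured 0.96); the full 29-train
recovery at density 0.10 runs once in the acceptance script (measured
sensitivity 1.00, specificity 0.95 at seed 1); P1 recovery pools fitted
against generating effects on eight 60-node networks (mean r 0.91);
census and metric brute-force oracles are exhaustive for n <= 4 and
sampled at n = 12. All random checks are seeded and the 3-sigma bands
come from the binomial/multinomial sampling distributions.

## Known limitations

* The influence kernel form (exponential decay on the backward recurrence
  time) and its 10 ms default are conventions; the kernel is pluggable
  but only `exp_decay` ships.
* The Cox design materialization is memory-quadratic in the number of
  target ISIs; multi-hour recordings need chunking or boundary splitting.
* The P1 fit provides point estimates only (no standard errors), matching
  how the coefficients are used downstream.
* Motif IDs follow the documented triad-census key; comparisons against
  reports using a different key require re-mapping.
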