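# Methods

## Scope and model class

`stochpn` simulates discrete place/transition (P/T) Petri nets. A net is a
bipartite graph of places (species, complexes, states) and transitions
(reactions) with positive integer arc weights; a marking assigns a
non-negative integer token count to each place. A transition is enabled when
every pre-place holds at least the arc weight in tokens; firing consumes and
produces tokens accordingly. Zero tokens are a legal count — an initial
concentration of zero is routine in kinetic models.

The formalism is extended with **constant places**: their count is set by a
user expression (of `Time` in seconds and the non-constant place names, bound
to token counts) and is never changed by firing, although it still counts
toward enablement and propensities. Constant places model boundary
conditions, e.g. an externally regulated hormone level. Expressions are
(re-)evaluated after every simulation step; with very long waiting times and
fast-varying expressions this post-step discretization can lag the expression
between events. That artifact is inherent to evaluating a non-homogeneous
input on the event grid and is negligible when event rates are fast relative
to the expression's variation, as in the insulin-receptor model; a rejection
sampler for non-homogeneous event times is out of scope.

Colored, timed-arc and inhibitor-arc nets, capacity constraints, and the
SBML/KGML import matrix of general-purpose Petri-net suites are non-goals;
model I/O is the P/T subset of PNML plus this package's own setup XML.

## Firing engines

* **Asynchronous** — one uniformly chosen enabled transition per step; no
  time. A step with no enabled transition terminates the run with status
  `dead marking` (a legitimate outcome, not an error).
* **Synchronous** — per step, a uniformly random subset of
  `ceil(fraction * |enabled|)` enabled transitions is selected and fired in a
  uniformly random order, each re-checked against the evolving marking.
  Conflicting transitions over a shared token pool are thereby resolved
  randomly with equal probability; transitions disabled mid-step are skipped,
  not re-drawn (re-drawing would bias toward non-conflicting transitions).
* **Stochastic (constant rate)** — each enabled transition waits an
  Exp(λ) time with a per-transition constant rate λ supplied by the modeler;
  the minimum waiting time fires, ties broken uniformly. Scheduled times are
  stored as absolute clock values and re-drawn lazily: only for transitions
  whose pre-place counts changed (sound by the memorylessness of the
  exponential), plus the post-transitions of constant places every step.
  Marking-dependent kinetics belong to the SSA engines.
* **Exact SSA** — Gillespie's direct method. Propensities are
  r(T) = c(T) · ∏_{p∈•T} C(m(p), f(p,T)) (distinct reactant combinations;
  empty product 1 for source transitions), waiting times are drawn by
  inversion dt = −ln(1−U₁)/a₀, and the reaction index satisfies the
  cumulative-sum inequality Σ_{j<i} r_j < U₂·a₀ ≤ Σ_{j≤i} r_j in the fixed
  net-definition transition order. A dependency graph (after Gibson & Bruck)
  restricts propensity recomputation to the transitions sharing an affected
  place; it is a pure optimization and leaves trajectories bitwise unchanged
  for a given RNG stream (tested).
* **Tau-leaping** — reactions that cannot fire at least
  `critical_threshold` (default 20) more times are *critical* and handled
  exactly; the rest leap. The non-critical leap τ₁ bounds the expected
  relative propensity change by `epsilon` (default 0.03) through the
  mean/variance step-size criterion with highest-order-reaction factors; the
  critical time τ₂ is Exp(sum of critical propensities), re-drawn each step.
  If τ₁ < τ₂ every non-critical reaction fires Poisson(r·τ₁) times; otherwise
  one critical reaction is chosen by the direct method and non-critical
  reactions fire Poisson(r·τ₂) times (a tie τ₁ = τ₂ takes this branch). A
  leap that would drive any count negative is rejected, the leap halved and
  the Poisson counts re-drawn (the critical firing is dropped once the leap
  shrinks below τ₂); after 10 rejections one exact step is taken. When every
  active reaction is critical the engine consumes the identical RNG stream
  as the exact method, so the two are bitwise interchangeable there.

The RNG is NumPy's PCG64; seed-reproducibility is a contract of this
implementation (same seed + setup ⇒ bitwise-identical trajectory), not a
claim about any specific generator.

## Unit conversion

With reaction volume V (liters) and Avogadro constant N_A, concentrations
convert as n = round(N_A·[X]·V) (ties to even — unbiased, and the choice is
otherwise arbitrary) and a mass-action constant k of order x (units
M^−(x−1)·s^−1, x = sum of pre-arc weights) converts to the stochastic
constant c = k·∏f!/(V·N_A)^(x−1). N_A defaults to 6·10²³ — two significant
figures, matching the convention of the model this package packages as its
case study — and is configurable (CODATA 6.022·10²³ changes the IR initial
counts by ~0.4%). Rate constants given as expressions or conditionals are
interpreted in mass-action units and multiplied by the same conversion
factor at every evaluation. The binomial propensity convention together with
the ∏f! factor reproduces deterministic mass action in the large-count
limit (tested to relative error < 10⁻⁵ at n = 10⁶).

## Expression grammar

The printed sources for this expression dialect describe only the semantics
(first satisfied case wins, default 0, comparison operators `= < > <= >=`),
so the concrete grammar is defined here:

* arithmetic: `+ − * / ^ %`, unary sign, parentheses, scientific notation,
  functions `abs acos asin atan cbrt ceil cos cosh exp floor log sin sinh
  sqrt tan tanh div(x,y)`, constant `pi`. Multiplication is always explicit.
* `div` is floor division (so `div(28,24) = 1` and negative arguments are
  well defined); `%` is `fmod` (remainder with the dividend's sign);
  `=` compares with absolute tolerance 10⁻⁹ since both sides are reals.
* conditionals: cases separated by `;`, each case being zero or more
  `;`-separated conditions `expr OP expr` followed by `cond : value`; a
  segment with no comparison operator is an unconditional case. Conditions
  within a case are conjunctive. Example:
  `Time < 5*60 : 1000 ; Time < 10*60 : 100 ; 0`.

Constant-place values are rounded to the nearest integer; negative values
clamp to zero with a logged warning.

## The insulin-receptor (IR) recycling model

Six places (constant `Insulin`; `IR`, `IR_I`, `IR_I_P`, `IR_I_P_Int`,
`IR_Int`) and eleven unit-weight transitions: binding/dissociation,
(de)phosphorylation at the membrane and in the cytosol, internalization and
recycling of free and phosphorylated receptor, degradation of the internal
pool, and zero-order synthesis. V = 10⁻⁹ l; initial [IR] = 9·10⁻¹³ M
(540 molecules), [IR_Int] = 10⁻¹³ M (60), the rest 0. Synthesis runs at
2.78·10⁻¹⁹ M·s⁻¹ while IR_Int + IR_I_P_Int ≥ 10⁻¹³ M (60 molecules) and at
1.67·10⁻¹⁸ M·s⁻¹ below it; the comparison is on molecule counts because
expression variables bind to counts. The two rate constants printed without
units (`Dephos_IR_I_P_Int`, `Degradation`) are unimolecular steps and are
taken as s⁻¹.

Two structural choices were genuinely open: membrane dephosphorylation is
modeled as IR_I_P → IR_I (keeping insulin bound; the alternative reading
releases insulin directly to IR), and no return arcs to the constant
`Insulin` place are drawn (they would be dynamically inert since constant
places ignore firing).

The external insulin profile has four conditional cases — three meal windows
(09:00, 13:00, 18:00) and a final condition-free basal case. Basal is
6·10⁻¹¹ M (36 000 molecules), the postprandial peak 3.6·10⁻¹⁰ M (216 000),
decaying as basal + (peak−basal)·exp(−(t−t_meal)/τ). τ is fixed by the
requirement that the excess over basal has fallen to 5% of the basal level
when the 3-hour return duration has elapsed: τ = 10 800/ln((peak−basal)/
(0.05·basal)) ≈ 2 345 s. The profile repeats daily via `Time % 86400`; the
window boundary at 3 h introduces a ≤5%-of-basal downward step, accepted for
simplicity. A 48-hour exact-SSA run executes ≈3·10⁵ events in a few seconds
and records once per simulated minute by default.

## Replicates and persistence

Replicate streams derive from `SeedSequence(master_seed).spawn(n)`, so each
trajectory is a pure function of (setup, master seed, index), independent of
any execution order; replicates run sequentially. Up to 500 replicates per
invocation are supported. Trajectories export as TSV (header `time`, `fired`,
one column per place; every event by default, optional fixed-interval
down-sampling). Setups round-trip through the package's own XML schema
(documented in `stochpn/io.py`); nets round-trip through the PNML P/T
subset, with constant-place flags and expressions in a
`<toolspecific tool="stochpn">` annotation. Unknown setup elements are
errors, never silently ignored.

## What the test fixtures do and do not show

The synthetic nets used in testing (immigration–death, pure death, races of
self-loop transitions, a stiff dimerization cascade) have closed-form
stationary means, extinction times and selection probabilities, which makes
them sharp oracles for the samplers. They are deliberately small and
well-mixed; passing them demonstrates correctness of the sampling
machinery, not performance or identifiability on large, stiff or multiscale
biological networks. Statistical assertions use 3-standard-error bands
(batch means for autocorrelated time averages) at sample sizes of 10⁴–10⁵
events, so each has a per-test false-failure probability well below 1%, with
fixed seeds making the suite deterministic in practice. Simulation lengths
in the suite (10⁵-event long runs, 100–500 replicate batches, 1–6 h IR
horizons) were chosen to keep the whole suite in the minutes range while
leaving the statistical bands meaningful.

## Known limitations

* Tau-leaping uses the explicit leap formula; stiff systems fall back to
  many small leaps rather than an implicit scheme.
* The constant-rate stochastic mode deliberately ignores the marking in its
  rates; users wanting mass-action kinetics should use the SSA modes.
* Expression-valued rates are re-evaluated only at event boundaries (see the
  discretization note above).
* PNML graphics annotations are dropped on read and not written.
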