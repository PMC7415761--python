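# Methods

This note documents the conventions, models and numerical choices behind
`canishow`, and what the synthetic generator does and does not emulate.

## Event model and time grid

All behavior occurrences are half-open intervals `[onset, offset)` in
seconds from phase start, on a 0.20 s grid (the coding resolution of the
frame-based timetables the package ingests). Half-open intervals make
abutting events non-overlapping, which is the natural reading of
frame-wise coding: an event ending on frame *k* and one starting on frame
*k* do not share a frame. Point-like events (a single bark) occupy one
frame, so every event has extent and both frequency and duration are
defined. `snap_to_grid` rounds to the nearest grid multiple with ties
rounding half up, and is idempotent.

Owner behaviors are collapsed into one composite `owner_behavior` code and
enter the analysis only as a per-cell frequency; the original sub-behavior
can ride along in a free-text annotation. A `retrieve` event (the dog gets
the toy itself) ends the analyzable window at its onset: from that moment
the trial outcome is fixed, so later events are dropped and straddling
events truncated before any pairing or counting.

## Showing detection

A showing is a pair of one directional event (gaze/move/near/jump/open at
a box, with box referent) and one attention-getting event (gaze/move at
owner, vocalize). A pair qualifies if the intervals intersect
(**overlap**) or if the gap from the earlier offset to the later onset is
at most the window (**alternation**), default 2.0 s. Decisions taken where
the operational definition leaves room:

* **Inclusive bound.** A gap of exactly 2.0 s qualifies. The bound is a
  succession criterion ("within two seconds"), and on a 0.20 s grid an
  exclusive bound would silently shift the criterion by one frame.
* **Order-agnostic.** Directional-then-attention and the reverse are
  equivalent; the relation is symmetric by construction.
* **All-pairs counting.** Every qualifying (directional, attention) event
  pair counts exactly once; there is no greedy one-to-one matching. A
  long near-box state overlapped by three owner-gazes yields three
  showings. This matches the high observed frequencies of state-based
  showing types in this paradigm and makes the count independent of scan
  order.
* **Overlap wins.** A pair that qualifies both ways (possible because the
  gap of intersecting intervals is non-positive) is reported once, as
  overlap — the stronger temporal relation; nothing is double counted.
* **No intervening-event rule.** "Followed directly" is operationalized
  purely by the 2 s bound. Any rule about events occurring in between
  would need thresholds the operational definition does not supply.

Output order is canonical (anchor, type id, referent, source ids), so
detection is deterministic and serializations are stable. The production
detector is a sweep over attention events sorted by onset with bisected
candidate windows; a literal quadratic all-pairs scan is kept as an
independent oracle and the two are asserted equivalent on thousands of
seeded random logs.

Types are numbered row-major over the 5 × 3 component grid (directional
outer, attention inner): 1 = gaze alternation, …, 15 = open box +
vocalize. Effort classes: **low** = type 1 only (the least effortful
strategy); **high** = the three jumping types (10–12) plus
move-box + move-owner (type 5), the second most effortful strategy,
included because many dogs never jump at all. Everything else is
**other** and does not enter the effort ratio.

## Scores

Per observation cell (pair × session × trial × phase):

* `prop_correct_showing` = showings at the target box / all showings;
  **missing** when the cell has no showings — a ratio of nothing is not
  evidence of incorrect showing.
* `effort` = high / (high + low); missing when neither occurs.
* `success` = phase choice equals target. Phase 1's choice is the
  questionnaire mark (0 = no mark, scored incorrect); phase 2's the
  opened box. If the dog retrieved in phase 1, both choices are the
  retrieved box.
* Type summaries report mean frequency per cell plus per-type accuracy
  (share at target) and choice rate (share at the chosen box). Choice
  rate uses the phase-matched choice by default; a switch selects the
  phase 2 choice for both phases, since the convention is ambiguous.
  Never-occurring types are flagged and rendered as a dash.
* The accuracy–time correlation uses each showing's anchor (earlier
  onset) on a within-trial clock: phase 2 anchors are offset by the
  phase 1 duration.

Missing ratios propagate as missing into the models; rows with a missing
value in any used variable are excluded listwise per model, and the
pipeline logs the exclusion counts because they change the fitted n.

## Statistical models

**t-tests.** Per-pair percent correct is tested against the 25 % chance
level (four boxes) with a classical one-sample t; phases are compared
with a paired t. Cohen's *d* for the one-sample test is
`(mean − chance)/SD`. For the paired test both conventions are computed —
mean difference over SD of differences, and over the pooled SD of the two
phases — with the pooled form as the default headline, matching the
convention in which a small between-phase shift against large
between-pair spread yields a small *d*. 95 % CIs for *d* invert the
noncentral-t distribution (treating `d√n` as noncentral-t with `n−1` df);
the method is stated because *d*-CI conventions differ. Degenerate
inputs: zero variance raises, except the exact null (all values at
chance; identical samples), which returns the limit t = 0, d = 0.

**Success GLMM.** Binomial-logit mixed model with a random intercept per
pair — the pair is the repeated unit, and nothing in the design motivates
random slopes. The marginal likelihood integrates the scalar random
effect by Gauss–Hermite quadrature (default 25 nodes; Laplace is the
1-node special case, and at this scale 25 nodes is effectively exact).
Fixed effects are maximum likelihood; Wald z and p per coefficient; AIC =
2k − 2logL with k counting β's plus the variance parameter. The primary
optimizer is L-BFGS-B on (β, log σ); on failure the model is refitted
with a derivative-free fallback (Nelder–Mead) and flagged. The fit is
validated against frozen `lme4::glmer` (nAGQ = 25) values on a
deterministic fixture and collapses to ordinary logistic regression when
σ is pinned at zero.

**Effort / correct-showing LMMs.** Gaussian random-intercept models,
REML by default via closed-form profiling (β and σe² are profiled out;
the search is one-dimensional in log λ = log σu²/σe², with the boundary
σu² = 0 checked explicitly). t-statistics carry Satterthwaite
denominator df: for coefficient *j*, df = 2f²/(g'Ag) with f the
coefficient's variance, g its gradient in (σu², σe²) and A the inverse
observed information of the (RE)ML likelihood — the same construction
lmerTest uses, validated against frozen lmerTest values (df agree to
< 0.05). Model comparisons refit with ML, since REML likelihoods are not
comparable across fixed-effect sets.

**Model selection.** Candidates fitted on identical rows are compared by
AIC (smallest wins, ties to declaration order); declared nested pairs get
a likelihood-ratio chi-square with df equal to the parameter-count
difference. Fits on differing row sets are refused rather than silently
compared.

**Nested time coding.** Session main effect, a trial slope within each
session (trial centered at 2.5 so the session contrast is evaluated
mid-session), and a phase contrast within each session. This yields the
interpretable per-session "effect of trial" and "effect of phase"
contrasts the analysis reports, with 5 parameters rather than the 15 of a
fully saturated nested factor; the coding is exposed as a plain
column-builder so alternatives are one dataframe away.

A note on the chance-level t-test: a published phase-1 test in this
paradigm reports M = 53.75, SD = 24.82, t(29) = 11.81, d = 2.16, which is
arithmetically a test against 0 ((53.75−25)/(24.82/√30) ≈ 6.34, d ≈ 1.16
against 25). This package always tests against the stated chance level;
with the same summary statistics it therefore prints t ≈ 6.34, not 11.81.

## Synthetic generator

The generator emulates the *statistical structure* the analysis assumes,
not dog behavior: 30 pairs, condition order (close/far) counterbalanced
across pairs, one condition per session, 4 trials × 2 phases of 60 s,
target boxes as a fresh permutation of the four boxes per session (each
box target twice per pair, never twice in a row within a session — the
study's design constraints are satisfied by construction).

Event streams are homogeneous Poisson onsets per behavior code with
exponential durations, snapped to the grid with a one-frame minimum and
clipped to the phase window. Default rates (events/min: gazes at boxes
6.0, near-box 3.0, moves 2.5, owner-gazes 5.0, vocalizing 0.8, jumping
0.4, box-opening 0.05, owner behavior 4.0) are chosen once so that the
emergent per-cell showing-type frequencies sit in the observed range for
this paradigm — frequent gaze/move/near showings, rare jump/open
showings, a realistic share of cells with zero low+high-effort showings.
Overlapping draws of the same state at the same box are resolved by
truncation at the next onset, since two simultaneous occurrences of one
state cannot be coded. Box-directed events point at the target with
probability `p_correct` (default 0.35, chance 0.25) and uniformly at a
wrong box otherwise.

Success is generated as Bernoulli with
`logit p = β₀ + β_c · prop_realized + u_pair`, where `prop_realized` is
the correct-showing proportion *detected in the generated log* — not a
latent tendency — so the success GLMM is fitted to data whose estimand is
exactly the generator slope (default β₀ = −2.2, β_c = 6.8, giving overall
success near 55 %). A pair-level intercept `u_pair ~ N(0, 0.5²)` is
included so the random-intercept variance the model estimates is not
degenerate at zero; setting `sigma_pair = 0` recovers the pure logistic
link, which is what the chance-level null check uses (β_c = 0,
β₀ = logit 0.25 must reproduce 25 % success). Cells with no showings draw
success from intercept + random effect alone; they are missing for the
models regardless. On failure the choice is a uniform wrong box, with a
small fraction (2 %) of phase-1 failures left blank (choice 0), as
happens with real questionnaires.

Because the effort ratio is an emergent quantity of the event streams,
there is no closed-form mapping from rates to a phase effect on effort;
the LMM recovery target is therefore generated directly at the
observation-row level (`simulate_effort_rows`: effort = 0.35 − 0.05 ·
[phase 2] + u_pair + ε, σ_pair = 0.06, σ_resid = 0.12), where the truth
is exact.

What the generator does **not** emulate: bout structure and behavioral
autocorrelation, dog-state dynamics (fatigue, frustration), owner–dog
feedback loops (owner behavior is an independent rate, optionally
condition-coupled), retrievals, and any true condition or time effect on
success beyond what the rate multipliers induce. Passing recovery tests
therefore show that *the estimators recover the data-generating
parameters under the design's sample sizes*, not that real dogs behave
like Poisson processes.

## Problem sizes and tolerances

The test suite runs the detector-oracle equivalence on 1,000 random logs
of up to 300 events, GLMM slope recovery on 100 generated studies
(estimates within ±0.7 of β_c = 6.8 on average, 95 % Wald coverage ≥
90/100), LMM phase-effect recovery on 100 replicates (mean within ±0.01
of −0.05), and the chance-level null on 200 replicates (success within 3
binomial SE of 25 %; LRT p-values for a pure-noise predictor uniform by
KS test). The acceptance script uses 20–40 replicate blocks for its
summary numbers. Closed-form checks (t, d, r, ρ) are at 1e−12; frozen
lme4/lmerTest comparisons at 1e−3 (GLMM, different quadrature/optimizer
stacks) and 1e−6 (LMM, same closed-form algebra).

## Known limitations

* Only random intercepts; crossed or slope random effects are out of
  scope for a single-random-factor design.
* The GLMM's quadrature is specialized to one scalar random effect.
* Satterthwaite df rely on numerically differentiated information; for
  boundary fits (σu² ≈ 0) the df are clipped to a sane range rather than
  trusted blindly.
* The XLSX reader expects the long-table layout (one header row); it does
  not parse arbitrary multi-sheet coding exports.
* No plotting: outputs are tables and a text report.
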