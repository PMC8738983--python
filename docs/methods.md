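# Methods

## The adherence rules

Every sex event at time `t` receives exactly one of three labels from the
participant's pill log (times at minute resolution; all windows in hours,
closed unless noted):

* **Correct daily use** — total pills in `[t − 168h, t)` is at least 4. The
  4-pills-per-week threshold is the level associated with protective drug
  concentrations under daily dosing. The left boundary is included, the
  event instant itself is not ("pills taken before the event").
* **Correct event-driven use** — there exists a pre-sex dose at `T_pre` with
  `X = t − T_pre ∈ [2, 24]` hours such that (a) the dose covers two pills, or
  one pill when at least one other pill lies in `(t − 168h, t − 24h]` (a
  recent prior dose means drug is already on board, so one pre-sex pill
  suffices); (b) a distinct pill log lies in `[T_pre + 22h, T_pre + 26h]`;
  and (c) another distinct pill log lies in `[T_pre + 46h, T_pre + 50h]`.
  The nominal follow-up times are 24h and 48h after the pre-sex dose; the
  ±2h widths absorb the delay between taking a pill and logging it. The
  search over `T_pre` is existential: any candidate that completes the
  sequence suffices.
* **Incorrect use** — neither rule holds.

Design choices a user should know:

* **Interval closure.** All integer window bounds are read as closed
  (`[2, 24]`, `[22, 26]`, `[46, 50]`, lookback includes `t − 168h`): the
  permissive reading of "2 to 24 hours". Boundary behaviour is pinned by
  tests at 1h59m/2h00m and 24h00m/24h01m. The single-pre backup window is
  implemented as `t − 168h < s ≤ t − 24h`.
* **Double-dose merging.** App users sometimes log one 2-pill dose as two
  taps; 1-pill logs within 60 minutes of one another merge into a single
  dose at the earliest timestamp when evaluating the 2-pill pre-dose
  requirement. 2-pill logs stand alone. A merged cluster covering more than
  two pills still satisfies the two-pill requirement.
* **Both rules passing.** The rules are not mutually exclusive. By default
  the event is labelled by the regimen declared on the most recent dose at
  or before the event; an UNKNOWN declaration falls back to
  `correct_daily`, whose coverage condition is the stronger claim. The
  precedence is configurable (`both_pass_precedence = "daily" | "ed"`).
* **Shared pills.** A pill may serve roles for several distinct sex events
  (e.g. the post-sex pill of one event can be the pre-sex dose of the
  next); within one event's sequence, the pre-dose and the two follow-up
  pills must be distinct logs.
* **Doses at exactly the event time** do not count as pre-sex doses
  (`X ≥ 2h` strictly per the stated range).

## The latent class model

Indicators per event: adherence label (3 levels), positioning (3), partner
HIV status (4 after dropping the never-observed positive-unknown-viral-load
level; dropping unobserved partner-HIV levels is the default and is what the
free-parameter accounting below assumes), and age comparison (3). The model
is the standard conditional-independence finite mixture of multinomials with
`K · Σ_j (C_j − 1) + (K − 1)` free parameters; for `K = 3` and levels
(3, 3, 4, 3) that is 29.

Estimation: EM from `n_starts = 10` Dirichlet(1,…,1) random initializations,
`max_iter = 500`, absolute log-likelihood tolerance `1e−10`; the start with
the largest final log-likelihood wins. The log-likelihood is asserted
non-decreasing at every iteration and the implementation collapses duplicate
response patterns (≤ 108 for these indicators), so fits cost the same at
N = 500 and N = 50 000. Response probabilities may converge to exact 0/1
(boundary estimates are legitimate MLEs here); an optional ridge pseudocount
(`ridge ≈ 1e−6`) is available but off by default. At `K` in the 3–5 range
and N ≈ 5000, 500 iterations typically ends short of the `1e−10` tolerance;
the parameter estimates are stable well before that (verified by running to
full convergence), so the reported `converged` flag is informational.

Model choice: AIC `= −2ℓ + 2p`, BIC `= −2ℓ + p ln N` with N the number of
**events** (not participants — the event-level analysis deliberately ignores
within-participant correlation at this stage, exactly as in event-level LCA
practice; the correlation is addressed downstream by the mixed model).
Selection is argmin BIC with ties to the smaller K; disagreeing AIC/entropy
optima are flagged in the report. The entropy diagnostic is the relative
entropy `1 − Σ_i Σ_k (−p_ik ln p_ik) / (N ln K)`, fixed at 1.00 for `K = 1`
(the diagnostic is undefined there; one class classifies trivially). When
the report compares entropies across K it excludes the K = 1 convention row.

Label switching is resolved by exhaustive search over class permutations
(K ≤ 6) minimizing the total absolute difference between fitted and
reference response probabilities.

## Association analysis

Condomless anal sex versus class, reference = largest usable class:

* 2×2 Wald odds ratio `ad/bc` with CI `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`
  and a two-sided Wald p-value. Wald (rather than profile likelihood) is
  used throughout for determinism; on one published table the two differ
  only in the last digit of the upper bound (3.75 vs 3.76).
* Logistic regression (statsmodels Newton ML). On a single binary contrast
  it reproduces the closed-form 2×2 OR and SE to ~1e−12 (tested at 1e−8).
* Random-intercept logistic regression: `logit P(y_ij = 1) = x_ij'β + u_i`,
  `u_i ~ N(0, σ²)` per participant. The marginal likelihood is maximized
  over `(β, log σ)` with per-cluster adaptive Gauss–Hermite quadrature
  (default 15 nodes; each cluster's nodes are centred and scaled at its
  Laplace mode, so accuracy holds even for large clusters). Wald CIs come
  from the numerically differentiated observed information; when the
  variance component sits at its boundary the β block is used. `σ` is
  optimized as `log σ` bounded in `[1e−6, 50]`; `fix_sd = 0` constrains the
  variance away and reduces exactly to the plain logit (contract tested at
  1e−6, and cross-checked against lme4::glmer with nAGQ = 15 on clustered
  data). A class with 0% or 100% outcome raises a separation error naming
  the class and is excluded from regression rather than
  continuity-corrected.

## The synthetic-data generator

The generator emulates a 4-month mobile-app diary study of 32 MSM PrEP
users: zero-truncated Poisson event counts (mean 17.2, cap 70), event times
≥ 24h apart in a 120-day window, classes from mixing (0.42, 0.52, 0.06),
four indicators drawn independently given class, condomless probability per
class (0.85, 0.69, 1.00) optionally shifted by a participant random
intercept on the logit scale (sd 0 by default, so the marginal equals the
conditional and the 2×2 odds-ratio target can be checked directly), and
participant ages massed on the 21–30/31–40 bins (study mean age ≈ 29) so
every age comparison is reachable; a participant whose drawn bin cannot
realize a drawn comparison has the bin re-drawn from the admissible bins.
Rows of the response table are normalized (one printed column sums to
0.999).

The adherence indicator is drawn from ρ like the others and then *realized*
as pill timestamps, because the recovery targets need the indicator
distribution to be exact; simulating pill-taking behaviour would not give
that. Realization is non-local — the daily rule sees every pill in a
168-hour lookback, so neighbouring events share pill history. Three
mechanisms make the round trip exact:

1. INCORRECT events are scheduled at the *start* of each participant's
   follow-up, before pill history accumulates, so their "< 4 pills in 168h,
   no event-driven sequence" requirement is satisfiable; since labels and
   indicators are attached to events (not to time slots), permuting event
   order leaves the joint class/indicator distribution untouched. Within
   the block, near-miss variants (2-pill dose at 25h; 3 pills per week; a
   valid pre-dose missing its second follow-up pill) are used only while the
   weekly pill budget allows, with a pill-free variant as fallback, and
   completion windows of deliberately broken sequences are embargoed for
   later pill placement.
2. Doses are declared with the regimen they realize (daily pills DAILY,
   event-driven pills EVENT_DRIVEN), so an event-driven event whose weekly
   pill total incidentally satisfies the daily rule still resolves to
   `correct_ed` under declared-regimen precedence. The isolated
   `generate_dose_pattern` (used for per-event tests) is stricter: its
   patterns satisfy exactly one rule.
3. Every participant is verified by running the actual classifier over the
   assembled dose log; on any mismatch the times/doses are re-drawn (labels
   kept), with increasingly conservative pattern choices. In practice the
   first attempt almost always verifies; fidelity is asserted at 100% in
   the tests across configurations, including dense (45 events/participant)
   and clustered (sd = 1) settings.

What the generator does **not** emulate: behavioural time structure (the
INCORRECT-first scheduling is visible in the event timeline), partner
networks, steady vs casual partners, weekday or chemsex effects, within-
participant indicator correlation beyond the shared class mixture, and any
participant-level covariate joint distribution. Passing tests show the
estimators recover the generating event-level mixture; they say nothing
about those unmodelled features of real diaries.

## Problem sizes and statistical behaviour

* The pipeline demonstration uses the study scale (32 participants,
  ~550 events). At that scale BIC selects the generating K = 3 in roughly
  13/15 seeds; in the minority of draws the 6% class is too thinly sampled
  and BIC conservatively stops at K = 2 (the bundled `analysis/` run with
  its default seed is one such draw — a useful reminder that a 6% class at
  N ≈ 550 sits near the edge of detectability).
* The recovery experiment uses ~5000 events (291 participants). The aligned
  MLE is consistent but classes 1 and 2 are separated mainly by positioning
  and class 3 holds only ~300 events, so visible sampling spread remains at
  this N: aligned mixing is typically within 2–4 percentage points, and the
  small-class response probabilities (e.g. the probability of an
  undetectable-viral-load-positive partner in class 3) carry errors of
  0.02–0.08 with a mild downward bias from class-2 leakage. The unit suite
  therefore asserts tight recovery at N = 20 000 (mixing ±0.03, all response
  probabilities ±0.05), where the spread has concentrated; the acceptance
  suite keeps the N ≈ 5000 experiment at its stated ±3-point / ±0.03
  tolerances.
* Runtime: pattern collapse makes every LCA fit sub-second; the full test
  suite runs in a few minutes on one CPU, dominated by the mixed-model
  recovery simulation (50 seeds × 30 clusters) and the N = 20 000 recovery
  fits.

## Known limitations

* The CSV schema is a reconstruction adequate for this analysis; real diary
  apps export richer (and messier) records, and no missing-data handling is
  provided — events with missing indicators are rejected upstream.
* The adherence classifier is purely rule-based; it does not model drug
  pharmacokinetics, and its windows, while configurable, encode one
  published reading of the 2-1-1 regimen.
* Covariate-conditional LCA (latent class regression), ordinal-indicator
  models, bootstrap likelihood-ratio tests, and GEE marginal models are out
  of scope.
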