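# Methods

`lottotraj` implements a two-step longitudinal classification of early
online-lottery gambling behavior from account-level transaction streams,
together with a synthetic cohort generator that makes the full pipeline
testable without access to operator data.

## 1. Data reduction

Raw input is an event stream: one record per bet, deposit, win, promotional
credit or voluntary self-exclusion, with timestamp, amount (EUR), and — for
bets — a game identifier and type (deferred vs instant lottery).  Each
player is observed for six months from account creation, divided into 12
half-open 15-day bins `[15t, 15(t+1))`, t = 0..11, with bin 0 starting on
the creation day; events on or after day 180 are discarded.  Bins with no
activity are observed zeros, not missing values: inactivity is behavior, and
near-zero trajectory tails carry information.

Four indicators per (player, bin):

* **wagered** — sum of stakes (EUR); modeled on the `ln(x+1)` scale, which
  compresses the heavy right tail while fixing zero (on that scale 1 ≈ €2,
  2 ≈ €6, 3 ≈ €19, 4 ≈ €54, 5 ≈ €147);
* **gambling days** — distinct calendar days with ≥1 bet (the stream has no
  session markers, so a "session day" is operationalized at day resolution);
* **chasing episodes** — deposits flagged by a within-session proxy: a
  deposit counts when it is the third-or-later deposit inside a rolling
  12-hour window (inclusive at exactly 12 h), or when it falls strictly less
  than one hour after a bet (a gap of exactly 1 h does not flag).  Each
  qualifying deposit is counted once; an alternative convention that flags
  every member of a ≥3-deposit burst is available via `count_all_burst`;
* **involvement** — distinct games bet on (breadth of involvement).

Six-month covariates: age, gender, cumulative deposits, largest single-day
deposit, % of bets on instant lotteries (by bet count; an amount-weighted
variant would be a one-line change), net loss = wagers − winnings −
promotional credits (negative values = net winning), voluntary
self-exclusion (yes/no), and the highest risk tag over the window.
Cohort descriptives aggregate bins to months (pairs of bins) and decompose
each indicator's SD into between-subject (SD of player means) and
within-subject (SD of player-mean-centered values) components.

## 2. Step 1 — growth mixture models

For each indicator, the 12-point series y_i follows a finite mixture of
polynomial growth curves with Gaussian random effects:

    y_i | class k ~ N(X β_k, Z Ψ Zᵀ + σ² I₁₂)

X is the polynomial design over time (degree ≤ 3), Z its random-effects
columns (intercept, or intercept + slope), Ψ and σ² shared across
trajectories.  Time is standardized internally to condition the cubic
design; coefficients are reported back on the 0..11 bin scale.  Count
indicators go through the same Gaussian machinery (a sqrt transform is
available as a variance-stabilizing option); wagered is ln(x+1)-transformed.

Estimation is EM with class labels and random effects as missing data; all
M-step updates are closed-form (weighted OLS on partial residuals for β_k,
posterior means for weights, expected outer products for Ψ and σ²), so the
marginal log-likelihood is nondecreasing by construction and the suite
asserts this on every fit.  Degeneracy guards: σ² ≥ 1e-6·var(y), Ψ projected
to the PSD cone after each update, trajectory weights floored at 1e-6 with a
warning.

**Multistart protocol.**  400 random starts × 10 short EM iterations, full
EM on the 50 best (defaults; reducible for small cohorts).  Half the starts
perturb a K-means-on-curves solution, half are fully random.  A solution is
*stable* when at least two finalists replicate the best final
log-likelihood within |ΔLL| ≤ 0.01 (exact equality being meaningless in
floating point).  Candidate K are compared by BIC = −2LL + k·ln(n) among
converged, stable fits; the full fit table is always emitted because
interpretability of trajectories cannot be automated.

**Numerical choices.**  Full EM stops at |ΔLL| < 1e-4 (absolute) or 2000
iterations.  The tolerance is deliberately coarser than machine precision:
zero-inflated indicators (chasing series are all-zero for most players)
produce long near-degenerate ridges where the likelihood gains ~1e-4 per
iteration while parameters barely move; the replication tolerance absorbs
the residual drift, and BIC differences at that scale are irrelevant to
selection.

## 3. Step 2 — latent profile analysis

Each player is represented by the concatenation of their per-indicator
posterior membership vectors (J columns; for trajectory models of sizes
7+3+3+4, J = 17).  Membership probabilities enter untransformed (a logit
option exists but is off by default).  Players are clustered with a mixture
of diagonal Gaussians with class-specific means and variances and free
weights, so a C-class model on J indicators has C·2J + (C−1) free
parameters — 35C − 1 at J = 17, which reproduces 34, 69, …, 279 for
C = 1..8.  The same multistart/stability machinery as step 1 applies, and
the classification error E = 1 − mean_i max_c q_ic summarizes crispness.

**Variance floor.**  Membership columns are frequently near 0/1, so
near-degenerate variances are the rule.  Without regularization the
likelihood rewards classes that split players on hairline (<1e-3)
differences in near-constant columns — partitions with no behavioral
content (the same mechanism that makes BIC decrease monotonically in C on
such data).  Column variances are floored at max(1e-6·var_j, 1e-4); the
absolute part corresponds to SD 0.01 on the probability scale, below which
membership differences carry no trajectory information.

**Model choice.**  The selector emits the full fit table (LL, BIC,
parameters, E, stability) and auto-chooses, among stable models, the
smallest C whose next stable neighbor adds no materially distinct class
profile (mean profiles within 0.10); if every step adds a distinct class it
falls back to best BIC, ties within 1 BIC point broken toward the smaller
C.  Human override from the table is the expected workflow.

## 4. Class description

Classes are described probabilistically, not by modal assignment: class
size is the mean posterior (in %), each trajectory cell is the
posterior-weighted mean membership probability, and covariate summaries are
posterior-weighted means/percentages.  Cells > .10 are highlighted as a
class's "main" trajectories.  Percentages therefore describe probability
mass, not head counts.  Currency stays in euros throughout.

## 5. Synthetic cohort generator

The generator emulates a cohort of newly registered online-lottery accounts
with five latent classes (weights 56.8/14.8/13.9/9.7/4.8 %): casual
low-stake players; steady medium-high-wager players; a declining class;
a broadly involved class favoring instant lotteries; and a small high-risk
class with heavy, parabolic activity peaking near day 112, chasing deposit
bursts, and a self-exclusion hazard calibrated so ~10.8 % self-exclude
within the window (self-exclusion exists only in this class).

Events are generated at the timestamp level.  Per day, a session occurs
with a class- and time-varying Bernoulli rate (a quadratic through rates at
days 0/90/180, so stable, declining and parabolic shapes share one
parameterization); sessions hold 1+Poisson bets with log-normal stakes on
games drawn from a class-specific pool.  Deposits are balance-driven
top-ups at session start; sessions are confined to 09:00–21:00 and span
≤ ~2 h, which *guarantees* funding deposits never satisfy the chasing proxy
— chasing classes emit explicit post-bet deposits and 3-in-12 h bursts
instead, so a class with chasing propensity 0 has an identically zero
chasing indicator.  Wins apply a class payout ratio; occasional promotional
credits exercise the net-loss subtraction.  A per-player RNG stream derived
from (seed, player index) makes cohorts byte-reproducible and players
independent of cohort size.

The risk tag is a *declared heuristic* (monotone in cumulative deposits and
chasing count), documented as not being the operator's proprietary
classifier; its distribution is reported, never asserted against published
values.

**What the generator does not emulate.**  Real marketing calendars and game
catalogs; between-session chasing; deposit habits not driven by play;
population heterogeneity within classes beyond lognormal stakes and
Bernoulli sessions.  Consequently, passing recovery tests shows the
*pipeline* can recover a known class structure of this shape — not that the
published real-data classes are correct.  One structural consequence worth
noting: players who self-exclude in their first days leave almost no
trajectory, so self-exclusion mass cannot concentrate *exclusively* in the
recovered high-risk class; tests assert concentration (maximum share),
which is what the mechanism supports.

## 6. Problem sizes used in the test suite

Unit and property tests run on cohorts of 100–300 players with reduced
multistart protocols (≈10–40 starts).  The recovery studies use n = 500
players simulated directly from a 2-trajectory growth mixture (intercepts
10 residual SDs apart) and an n = 1200 five-class event-stream cohort
pushed through the full two-step pipeline with the study-sized trajectory
blocks (7/3/3/4) and a 50-start profile-model multistart; recovery there is
ARI ≈ 0.97 against the generator's labels with modal shares within ±3
points of the class weights.  The `analysis/` drivers default to a 600
player cohort with a 40-start trajectory stage and a full 400-start profile
stage.

## 7. Known limitations

* Count indicators are modeled as Gaussians (after optional transforms);
  zero-inflated series are handled by variance floors and coarse stopping
  rules rather than by count likelihoods.
* Shared Ψ and σ² across trajectories only; class-specific covariances are
  rejected rather than silently approximated.
* Covariates are descriptive only — they never enter either mixture model.
* The automatic class-count rule is a reproducible stand-in for a judgment
  call; the emitted fit tables are the real interface.
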