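# Methods

## The analysis

`wagertrack` studies how the *structural characteristics* of online casino
games — how fast they play, how often and how much they pay back — relate to
in-session gambling behaviour. The unit of analysis is the **session**: a
maximal run of one player's wagers in which no two consecutive wagers are
separated by more than 15 minutes. The pipeline is

1. **simulate** a wager/win transaction log for a player population,
2. **sessionize** it by the inactivity-gap rule,
3. discard sessions in which more than one game was played (their outcomes
   cannot be attributed to one game's characteristics),
4. estimate **game-level characteristics** across all transactions of each
   sufficiently played game,
5. compute **session-level metrics**, including theoretical loss,
6. model session outcomes (number of bets; theoretical loss) with **OLS**
   and a **CART regression tree**.

Real operator logs of this kind are proprietary, so the package ships a
generative simulator whose defaults encode the structure of a typical
mid-size European online-casino portfolio; every downstream stage is tested
by parameter recovery against the simulator's known truth.

## Sessionization

A new session starts exactly when the gap to the player's previous wager is
*strictly greater* than 900 s; a gap of exactly 900 s stays within the
session. Both directions are asserted in tests, and the implementation is
checked against an exhaustive pairwise-chaining oracle (connected components
of the "same player, within gap" graph) on random logs. Duplicate
timestamps are kept in input order (stable sort); a single-wager session has
duration 0. Game *type* means `game_id` (characteristics are computed per
game), not game group.

## Game characteristics

Computed across **all** transactions of each game with at least
`min_wagers` (default 100,000) wagers:

* `rtp` = Σwin / Σbet; `hit_frequency` = wagers / wins (missing if no wins);
* `avg_bet`, `sd_bet` across all wagers; `avg_win` = Σwin / n wagers
  (zeros included); `sd_win` across **winning** wagers only;
* `event_freq_mean`/`sd` over within-session gaps between consecutive
  wagers on the same game (never across a session boundary, so idle time
  cannot inflate the speed-of-play measure);
* `continuity` = mean duration in minutes of the game's retained
  single-game sessions.

`avg_win` is deliberately per-wager so the identity
`avg_win = rtp × avg_bet` holds to machine precision; the asymmetry with
`sd_win` (per winning wager) mirrors how portfolio win-dispersion figures
are usually quoted. All SDs are population SDs (denominator *n*) — with the
intended sample sizes the choice is immaterial, but it must be fixed for
reproducibility.

## Session metrics and theoretical loss

Thirteen per-session metrics (length in minutes, bet/win counts and
amounts, averages, maxima, realized RTP, hit frequency) plus the
session-level bet and win SDs used as model predictors. **Theoretical
loss** is

    theoretical_loss = amount_bet × (1 − RTP_game)

with the *game-level* RTP, not the session's realized return: it is the
expected cost of the observed staking, independent of win/loss luck, which
makes it a preferable gambling-intensity measure. Sessions with zero wins
carry a missing hit frequency and leave model fits that use that predictor
(counted and logged); they remain in every other computation.

## The simulator

Per game, one wager is generated as:

* **bet** ~ lognormal, moment-matched to (`avg_bet`, `sd_bet`). Lognormal
  gives positive support and the right skew for portfolios where the bet SD
  exceeds the mean severalfold. `sd_bet = 0` degenerates to a point mass.
* **win** = `bet × M` with probability `1/hit_frequency`, else 0. The
  multiplier `M` is lognormal with mean `rtp × hit_frequency`, which makes
  `E[win | bet] = rtp × bet` exactly for *any* bet distribution; the RTP
  identity is structural, not asymptotic. `M`'s dispersion is solved from
  the target win SD; for high-stake table games the bet dispersion alone
  exceeds the target, in which case `M` degenerates to its mean (the
  closest attainable configuration).
* **inter-wager gap** ~ lognormal truncated at 900 s. Naive truncation
  biases the mean low (≈6% for a fast, heavy-tailed game), so the location
  parameter is root-solved until the truncated population mean equals the
  target event frequency exactly; draws above the threshold are resampled.
  This also guarantees every within-session gap respects the threshold.

Population structure: ages Normal(43, 13.11) clipped to [18, 99]; 17.4%
female; per-player weekly session rates gamma-distributed (shape 1) around
0.873/week over a 140-day horizon, so an average player opens ≈17.5
sessions; wagers per session geometric with a per-player lognormal mean
around 145 (CV 0.5). Session start times are uniform over the horizon;
each session plays exactly one game drawn from the player's preference
weights (Dirichlet jitter around volume-proportional defaults in which
slots carry ≈96.7% of bets). Currency is unitless.

The default portfolio expands the six group profiles into 34 games
(24 slots, standalone table games) by multiplicative lognormal jitter
(CV 0.10) of each parameter on a scale that preserves the invariants
(house edge and excess hit frequency are jittered, keeping RTP ≤ 1 and hit
frequency ≥ 1). Distinct games are what give the game-level design matrix
full rank — with one game per group the nine characteristics are confounded
with group identity and OLS correctly refuses to fit.

**Planted effects** (`plant_effect`) override the session wager-count mean
as a function of the chosen game's true characteristics — a step at an
event-frequency threshold, or a linear function floored at 1 — so that
recovery of known truth can be tested end to end through sessionization,
characteristic estimation and the models.

What the simulator does **not** emulate: deposits/withdrawals, bonuses and
jackpots, within-player autocorrelation of session behaviour over time
(sessions are exchangeable given the player), player churn, and any
dependence of bet size on recent outcomes. Passing recovery tests therefore
show the estimators and models are correct for data with this structure,
not that real operator data satisfy it.

## Models

* **OLS** (`OLSRegression`): intercept always included, predictors on their
  raw scale, classical homoscedastic standard errors, two-sided t
  p-values, 95% CIs. Rank-deficient designs raise an error naming the
  collinear terms (QR with column pivoting). Rendered tables floor
  p-values at "<0.001"; stored values keep full precision.
* **Nested F-test**: `F = ((RSS_s − RSS_f)/Δdf) / (RSS_f/(n − df_f − 1))`
  with p from `F(Δdf, n − df_f − 1)`; inputs must be strictly nested and
  fitted on the same rows.
* **Regression tree** (`RegressionTreeModel`): CART with variance-reduction
  splitting on a uniformly random 80% training split; report carries the
  held-out R², the root split (feature, threshold), the mean outcome in
  each root branch, and normalized total-impurity-reduction importances.
  Defaults `max_depth = 4` and `min_samples_leaf = 1%` of training rows
  keep root splits interpretable; both are exposed. Importance ties are
  broken alphabetically in the ranking.

Predictor vocabulary: nine game characteristics
(`game_avg_bet … game_event_freq_sd`), optionally seven session metrics
(`session_hit_frequency`, maxima, averages, SDs of bet and win) plus `age`
and a `female` indicator — 18 predictors in the full model.

## Numerical and design choices

* Timestamps are generated at microsecond resolution so CSV round trips
  are exact; logs are written as ISO-8601 UTC.
* The train/test split and all simulation randomness derive from single
  integer seeds (`numpy.random.default_rng`); identical (config, seed)
  reproduce byte-identical CSVs.
* The tree requires ≥100 rows and a non-degenerate outcome; the geometric
  wager-count floor (≥1 wager per session) is the only censoring in the
  generator.
* Planted-truth experiments for the tree use portfolios in which event
  frequency varies *independently* of the monetary characteristics. With
  the confounded default portfolio, several characteristics separate the
  fast from the slow groups equally well and the root-split feature is not
  identified — an instance of the general caveat that tree importances
  spread arbitrarily over perfectly collinear predictors.

## Problem sizes

Tests and the reproduction script use deliberately small populations —
30–100 players and 10⁵–5×10⁵ wagers per experiment, against the defaults'
43,731 players — with tolerances computed from the realized standard errors
(3 SE for recovery checks, 3 binomial SE for rates). The full-size
demographic check simulates all 43,731 players with a reduced behavioural
scale, since only the player table enters that measurement.

## Known limitations

* Recovered `sd_win`/`event_freq_sd` are attenuated relative to their
  targets (truncation at 900 s; multiplier floor) — only the means and
  ratio statistics are moment-exact.
* Session hit-frequency handling (zero-win exclusion) is one defensible
  convention among several; alternatives change the average session hit
  frequency at the second decimal.
* The OLS coverage guarantee is exact under homoscedastic noise; under the
  generator's geometric outcomes the classical intervals are only
  asymptotically calibrated.
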