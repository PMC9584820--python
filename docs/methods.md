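# Methods

## The investment game

Four players repeatedly (10 rounds per block) split an integer endowment
`e_i` between a private account and a public fund. The fund `C = Σ c_i` is
multiplied by a growth factor `r = 1.6` and redistributed, so each round's
return to player `i` is `y_i + e_i − c_i`. With `k = 4` the marginal per
capita return of a contributed coin under equal division is `r/k = 0.4 < 1`,
which makes the equal-split game a social dilemma: free riding dominates
individually while full contribution maximizes the group surplus. Endowments
are head-first vectors `(10, t, t, t)` with tail values `t ∈ {2,…,10}`,
constant across a session. A session is three 10-round blocks (a no-referee
tutorial under equal split, then two rival mechanisms in counterbalanced
order), a group vote, and a 4-round bonus block under a mechanism drawn with
probability equal to the vote fraction.

Group welfare is summarized by the Gini coefficient of a value vector
(mean absolute pairwise difference over `2 n² μ`) and by surplus, the sum of
returns over the sum of endowments across players and rounds (1 when nobody
contributes, `r` under universal full contribution with any conserving
mechanism).

## The mechanism family

A redistribution mechanism maps one round's `(e, c)` to nonnegative weights
summing to 1; payouts are `y_i = weight_i · r · C`, so every mechanism in
the package conserves the fund exactly (asserted to 1e-9 by the engine).
The closed-form family mixes an absolute component
`y_abs_i = r[w·c_i + (1−w)·c̄_{−i}]` and a relative component
`y_rel_i = r(C/P)[w·ρ_i + (1−w)·ρ̄_{−i}]` (with `ρ_i = c_i/e_i`,
`P = Σ ρ_i`) through `y_i = v·y_rel + (1−v)·y_abs`. Both components sum to
`r·C` algebraically, so conservation holds at every `(v, w)`. Canonical
points: libertarian `(v=0, w=1)`, liberal egalitarian `(v=1, w=1)`, strict
egalitarian `w = 1/k` (where the algebra makes `v` immaterial; the
constructor returns `v=0` by convention). Both parameters live on `[0, 1]`,
which contains all canonical points and keeps weights nonnegative.

**Empty fund.** `C = 0` makes `C/P` a 0/0; the family short-circuits to
zero payouts with uniform weights — an empty fund has nothing to split.

## Players

All neural players share one architecture: a 16-feature observation →
linear(64) + tanh → LSTM(16) → linear(11) head of unnormalized
log-probabilities over contributing 0–10 coins. Logits for contributions
above the focal endowment are additively masked with −1e9, so sampled
contributions always respect the budget; the 11-way head caps endowments at
10 coins. Observations are, per step: every player's endowment, previous
contribution, previous relative contribution and previous payout
(focal player first; endowments, contributions and payouts divided by 10;
round-1 history all zeros — the least informative prior, since what players
saw before the first decision is not modelled). Parameters are shared
across seats, with the focal seat designated by the observation ordering.

**Scripted synthetic agents.** Training corpora are generated by seeded
parametric archetypes rather than human data: full contributors (`c = e`),
free riders (at most 20% of endowment, default 10% ± Gaussian noise),
conditional cooperators (round 1 contributes half the endowment; thereafter
the target ratio reciprocates the other players' mean relative contribution
of the previous round, plus noise), and noisy uniform players. The default
mixture (0.5 conditional cooperators, 0.25 free riders, 0.15 full
contributors, 0.1 uniform) follows the well-replicated finding that roughly
half of public-goods players are conditional cooperators and a quarter free
riders. These agents emulate the *statistical texture* of human play
(conditional cooperation, heterogeneity, decay under the social dilemma)
but not framing effects, learning across sessions, inequality aversion in
voting, or platform artefacts — so passing tests demonstrate that the
pipeline works mechanically and recovers known equilibria, not that the
learned mechanism would win votes from real humans.

**Imitation training.** Behavioural cloning minimizes the cross-entropy of
the focal player's next contribution, minus an entropy bonus of the
predictive distribution (weight 0.1, which keeps the cloned policy from
collapsing to a point mass) plus an L2 penalty on parameters (1e-5), with
Adam (lr 4e-4, β₁ 0.9, β₂ 0.999, ε 1e-8), backpropagation through the full
10-round game, 30,000 updates of 512 samples by default. Ten percent of
games are held out, split by game so held-out games are fully unseen.

**Rational players.** The same network per seat is trained in self-play by
the plain score-function (REINFORCE) gradient on its own per-episode
cumulative return with a batch-mean baseline — the simplest estimator
consistent with a return-maximizing player. Defaults: 500 updates of 128
episodes, Adam lr 3e-3. Because the stage payoffs have dominant actions
(each contributed coin returns 1.6 under libertarian and 0.4 under strict
egalitarian), training converges cleanly to full contribution
(mean ρ ≈ 1.0) and free riding (mean ρ ≈ 0.0) respectively, matching the
game's two Nash benchmarks.

## Voting

A player's vote between two experienced mechanisms is logistic in the
difference of summed relative payouts `rpay^M = Σ_t y_i^t/e_i`:
`p(A) = 1/(1 + exp(−s·(rpay^A − rpay^B)))` with slope `s = 1.4`. The slope
multiplies the payout difference (making `s` a sensitivity scale); results
are insensitive to this reading over a wide range of `s`. Votes are
sampled independently per player given the traces — correlation within a
group enters only through shared experience, which is also why significance
testing flips whole groups.

## The mechanism designer

A memoryless policy maps one round's `(e_i, c_i, ρ_i)` per player — 12
scalars on a fully connected directed 4-vertex graph with empty edge and
global attributes — to redistribution weights. Two graph-network blocks run
in sequence (update order edges → vertices → global; vertex aggregation is
the sum of incoming updated edges): block 1 applies distinct linear+tanh
maps with 32 units for φe, φv, φu; block 2 applies a linear+tanh φe (32)
and a single-output linear φv, and a softmax across the four vertex outputs
yields the weights. Weight sharing across edges and vertices makes the
policy exactly slot equivariant; statelessness makes it memoryless, so the
learned mechanism is a two-dimensional surface over (head, tail) relative
contributions (the beach grid).

Design choices where the architecture left room:

* **Input scaling.** Endowments and contributions are divided by 10,
  matching the player networks (the scaling convention is only specified
  for players; using the same one keeps features in a common range).
* **Initialization.** Glorot uniform everywhere, with the output layer
  scaled by 0.01 so the initial policy is near-uniform — an unbiased start
  that keeps early score-function gradients small.
* **No gradient clipping and no designer entropy bonus** — the simplest
  faithful loop.

**Training.** Each update simulates two batches of 10-round games with the
imitation-trained players — one under the designer, one under a fixed
opponent (default: liberal egalitarian, the metagame winner) — partitioned
into equal groups over eight endowment conditions (head 10; tail 2–8 or
10). Paired episodes produce per-player logistic vote probabilities; the
per-episode objective `J` is the expected number of votes. The gradient
uses a stochastic-computation-graph surrogate
`S = J + ⊥(J)·Σ_i Σ_{t≥2} log p(⊥(c_i^t))`: payout arithmetic, player
log-probabilities (through the observed payout features) and the voting
logistic are differentiated exactly, while the players' discrete sampled
contributions enter through the score-function term. Round-1 contributions
are excluded (they cannot depend on the mechanism), `J` is mean-centred
within the batch before weighting the score term, and episode `i` of the
designer batch is paired with episode `i` of the opponent batch within the
same endowment group. RMSProp (lr 4e-4, ε 1e-5, decay 0.99, no momentum)
runs 10,000 updates of 2×512 games at full scale. Virtual-player recurrent
states are reset at the start of every episode in both batches.

Gradients come from the package's own reverse-mode automatic
differentiation layer over float64 numpy arrays; its correctness is pinned
by finite-difference tests, including a norm-relative comparison of the
full surrogate gradient on a one-round game (observed agreement ~1e-7,
asserted below 1e-2 to leave room for finite-difference noise).

**Freezing.** Trained designers export to a JSON container (architecture
descriptor plus parameter arrays; float64 `repr` round-trips exactly, so a
reloaded mechanism is bit-identical) and are addressable from configs as
`frozen:<path>` alongside `manifold:v=…,w=…` and `canonical:<name>`.

## Tournament and Nash solution

Mechanisms on an evenly spaced `(v, w)` grid (default 10×10) meet in
pairwise elections: each unordered pair is simulated for `n` independent
paired blocks with fresh agents, votes are sampled, and the mirror cell is
filled as the complement, making antisymmetry exact; diagonal cells are 0.5
analytically. A strategy is a pure symmetric equilibrium of the induced
two-player game when no deviation earns more than the diagonal payoff plus
a noise tolerance, defaulting to two binomial standard errors of a cell
estimate because cells are Monte-Carlo estimates; the finder is checked
against a brute-force best-response oracle.

## Statistical analyses

* **Group permutation test.** Observed statistic: total votes for A. Each
  of the 10,000 shuffles flips all votes of a group jointly with
  probability 0.5, preserving within-group covariance; one-tailed
  `p = max(b, 1)/n_shuffles`, so the attainable floor is 1/10,000 = 0.0001.
  (For a two-alternative vote, flipping preferences and swapping the
  group's mechanism labels are the same operation.)
* **Binomial standard error** `sqrt(p̂(1−p̂)/n)` for vote-share bars.
* **Beach grids** are computed by direct single-round evaluation of the
  (memoryless) mechanism at `c_head = round(ratio·e_head)`,
  `c_tail = round(ratio·e_tail)`; history-dependent mechanisms are rejected
  rather than silently averaged over rollouts.
* **Deposited data.** The released human dataset is loaded only from a
  local path, schema-validated in one adapter; vote-share summaries count
  one ballot per (session, player).

## Problem sizes used by the test suite

The package's tests run everything at desk scale: imitation recovery uses
200 deterministic conditional-cooperator games over five endowment
conditions and 2,000 updates of 256 samples; rational players train for
500 updates of 128 episodes; the designer trains for 500 updates of 64
games against strict egalitarian with players cloned (400 updates) from a
free-riding-prone mixture (0.6 free riders, 0.3 conditional cooperators,
0.1 uniform). These sizes are deliberate scaled-down study conditions: they
are large enough for the qualitative claims under test (rule recovery,
equilibrium convergence, vote-share improvement above 0.5) while keeping
the whole suite in the minutes range. Full-scale defaults (30,000 imitation
updates; 10,000 designer updates of 2×512 games) remain the library and
CLI defaults.

## Numerical conventions and degenerate inputs

* Everything is float64; fund conservation is asserted to 1e-9.
* Masked logits use an additive −1e9 (softmax mass ≈ 1e-434, exactly zero
  in float64 after normalization against unmasked classes).
* Log-softmax uses a constant max-shift, so its gradient is exact.
* RMSProp accumulates squared gradients with ε inside the square root.
* Gini is undefined (rejected) for all-zero vectors; relative payouts are
  rejected upstream for zero endowments; empty funds give uniform weights.
* One master seed is split into named CRC32-keyed substreams (game, votes,
  policies, …) so components are independently reproducible.

## Known limitations

* Virtual players imitate scripted archetypes, not humans; headline human
  percentages (e.g. observed vote shares against specific baselines) are
  not reproducible without the deposited dataset.
* The rational-player estimator is the plain REINFORCE gradient; it is
  adequate for this game's dominant-action structure but would need
  variance reduction for flatter payoff landscapes.
* Endowments are capped at 10 coins by the 11-way action head.
* Mixed-strategy metagame equilibria and the low-dimensional embedding of
  the manifold are out of scope.
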