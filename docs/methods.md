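# Methods

This note documents the model, the synthetic data that stands in for
undeposited platform data, the numerical choices, and the limits of what
the test suite demonstrates.

## Individual anxiety scores

A member's initial anxiety is `a0 = λ·p + (1−λ)·m` with both factors
normalized into [0, 1].

* **Profile factor p.**  A scorer maps profile features (gender, age,
  education, occupation, income band, location) to the SAS index scale
  (25–100) and the prediction is min–max normalized by the fixed scale
  bounds (25→0, 100→1).  The reference architecture is a linear base on
  the one-hot + numeric encoding plus a single-hidden-layer feed-forward
  residual stage (16 ReLU units, lbfgs, L2 penalty 10).  Two
  deliberate choices here:
  * the one-hot encoder drops one level per feature so the design is full
    rank and the base *interpolates* additive categorical effects exactly;
    on noise-free training data the scorer is therefore exact, and
    threefold cross-validation attains directional precision = recall = 1;
  * the residual stage is skipped when the base already interpolates
    (residual SD below 1e−6) and is heavily regularized otherwise — its
    job is real nonlinear structure, not questionnaire noise.  With noise
    at a quarter of the narrowest band width (2.5 SAS points) both CV
    metrics stay above 0.85; at the ceiling-level noise of 4 points they
    track the irreducible banding ceiling (~0.82).
  Any scorer with the same profile→[25,100] contract can be substituted.
* **Topical factor m.**  Per message, keywords are the top-5 content words
  by in-message term frequency (stopwords and hashtags removed, ties by
  first occurrence); the message score is the maximum weighted cosine
  between any keyword and any anxiety anchor word, clamped to [0, 1];
  m is the mean over the member's in-community messages.  The max captures
  the strongest anxiety cue in a message; the mean is robust to verbosity.
  Members with no messages raise a "no topical evidence" signal and fall
  back to λ = 1.  Embeddings are pluggable: a text word2vec reader,
  deterministic hashed vectors, or hand-built fixtures.
* λ defaults to 0.5 (symmetric prior; platform-dependent in general) and
  is exposed in `ContagionParams` for sensitivity runs.

## Contagion and the collective score

The cascade `Âk = Âk−1 + R·δ(Âk−1)` uses the symmetric binary relation
matrix built from follow plus repost/comment links (any directed edge sets
both entries; self-links dropped).  `δ(x) = ε·exp((x−UB)/UB)` with UB = 1
on the normalized scale and ε = 0.002 by default — small enough that a
member's per-round gain (≤ degree·ε) does not saturate typical members
within the iteration budget, while hubs still visibly accumulate.  Scores
are clipped to UB by default (UB is a stated maximum yet the update is
additive; clipping reconciles the two; the unclipped mode is kept for the
monotonicity properties).  K defaults to min(graph diameter, 6): the
diameter exhausts reachable influence, and influence from a node at graph
distance d provably first arrives at iteration d.

`A(C) = norm(Σ Âk[i])` keeps the sum, not the average — a community of
1,000 members with the same mean anxiety outranks one of 10.  The default
norm is saturating, `1 − exp(−s/τ)` with τ = (mean community size in the
run)·UB; a `global_max` mode (`s/(N_max·UB)`) is provided.  Both are
strictly increasing in the sum and preserve the size ordering.

Daily evaluation uses **cumulative snapshots**: at day t the membership,
messages and relation edges comprise all activity up to and including t
(deliberation accumulates; members do not leave).  The series starts at
the community's first active day.  Affective polarization is flagged when
the least-squares trend of the daily series is positive with p < 0.05;
fluctuation is the sample SD (ddof = 1) of the daily values, defined as 0
for a single-day series and reported as undefined below the minimum points
otherwise.

## Declarative knowledge

`DK(m) = a·credibility + b·similarity + c·readability` with equal default
weights (the source analysis never reports them).  Credibility is 1 iff
the origin of the repost/comment chain — resolved by following parent
links to the root, with cycles rejected and out-of-dataset parents treated
as unknown (credibility 0, logged) — is an institution-verified personal
account; comments inherit the origin of their thread.  Similarity is the
clamped cosine between the mean keyword vector and the community's topic
label vector.  The readability index
`4.53 + 0.01·dw − 0.86·ssr − 1.45·log_cwf + 0.02·pp` behaves like a
difficulty grade, so before entering DK it is z-scored within the corpus
and **negated** — higher scaled readability = easier text, consistent with
readable text as evidence of declarative knowledge.  This direction is an
interpretive choice and is the main caveat on the DK scale.  Feature
approximations are token-list based by design: difficult words are tokens
outside the top-5000 of the frequency lexicon; a "simple" sentence has no
subordinating/coordinating marker from a configurable list; content-word
frequency is the mean log10 lexicon count.

`DK(C,t)` sums message scores under the same cumulative snapshots.  The
community-level predictor `dk_level` used in the battery is the **mean DK
per message**, which removes the mechanical size dependence of the sum and
makes communities comparable.

## Community statistics

* Directional validation: tp = rating equals truth, fp = more severe,
  fn = less severe; tp+fp+fn always equals the number of rated
  communities; empty denominators are reported as NaN, never fabricated.
* Community ratings use equal quintiles on [0, 1] (no thresholds are
  published); band edges belong to the upper band.
* Graph metrics: edge density uses repost/comment edges only
  (2E/(n(n−1))); the diameter is the longest shortest path on the largest
  connected component of the full relation graph; interaction frequency is
  (reposts + comments)/members/day — the per-member, per-day reading of an
  otherwise ambiguous quantity, documented here as the package's
  definition.
* H1 uses Pearson r with familiar/proximate coded 1; H2 a simple OLS of
  collective anxiety on `dk_level` (β, R², F); H3 Spearman ρ of influencer
  ratio against the series SD; the full regression is OLS on ten
  predictors with collinear or constant columns rejected by name.
  p-values are reported raw, as in the original analysis; a Holm
  adjustment flag exists but defaults off.

## The synthetic generator

The generator emulates the study conditions at desk scale: 200 topic
communities (the scale of the original corpus) of 50–500 members over a
28-day window, with a questionnaire pool of 360 profile-linked SAS
records.  Its purpose is parameter and sign recovery, not realism per se.

* **Profiles and the latent link.**  Latent anxiety in [0, 1] is a linear
  link on profile features (documented coefficients; age dominates) plus
  community and member noise.  The SAS pool maps the same link to the
  index scale with a constant offset chosen so the noise-free index never
  touches the scale bounds (keeping the noiseless score exactly linear).
* **Sizes** are right-skewed (Beta(2.5, 4.5) over the range): many small
  communities, few large, echoing real hashtag-community size
  distributions.
* **Graph.**  Directed follower edges from fitness-weighted attachment;
  influencer accounts carry an 8× fitness multiplier and so accumulate
  systematically higher in-degree (non-reciprocal follows).  The cascade
  symmetrizes, as the relation matrix requires.
* **Messages.**  Every member posts once on day 0 (hashtag-burst
  onboarding) and the community's fixed message budget (4 per member on
  average) spreads uniformly over the window; reposts/comments attach to
  earlier messages, preferring verified-author posts in knowledge-rich
  communities.  Text is template pseudo-language: topic words (clustered
  around the field label in the shipped word vectors), neutral words,
  anxiety anchors with probability logistic in the author's latent level,
  plus rare words, pronouns and clause markers whose rates fall with the
  community's knowledge level — so the topical factor, topic similarity
  and readability features all carry learnable signal.
* **Wired effects.**  Proximity shifts *who joins*: members are selected
  toward a tilted latent-link target, so the effect is visible to the
  profile factor and, through the latent level, to the topical factor.
  The knowledge effect splits half composition / half topical expression.
  The influencer effect scales the step SD of a community mood random
  walk that modulates anchor emission day by day; with all members active
  from day 0 the daily series has no membership ramp, and its SD responds
  to the mood scale.
* **Null behavior.**  With all three effects zeroed the battery rejects at
  the nominal 5% rate (checked over 200 reduced-scale replicates).

What the generator does **not** emulate — and what passing tests therefore
do not show about real platforms: gradual member accretion (communities
are fully formed at the window start), natural language (pseudo-words,
whitespace tokenization, no Chinese morphology), users spanning multiple
communities, organizational-account traffic, inter-community contagion,
and the four-order-of-magnitude size range of real hashtag crowds.

One observed artifact worth knowing: under the saturating norm, edge
density (∝ 1/n) acts as a nonlinear size proxy and can come out
significant in the 10-predictor regression even though member, post,
comment and interaction-frequency coefficients are null; interpret the
network-structure coefficients accordingly.

## Problem sizes and numerics

The recovery study uses 20 seeded replicates of the full 200-community
condition; null calibration uses 200 replicates of 30 communities of
30–100 members — sizes chosen so the whole suite runs comfortably on one
CPU.  All randomness flows through explicit `numpy` generators seeded per
component (corpus, community index, scorer), making corpora, series and
reports byte-reproducible.  CSV floats are written in shortest round-trip
form and read back with round-trip parsing.  Cross-validated SAS
predictions are rounded to 1e−6 before banding so float error cannot flip
a score sitting exactly on a band edge.  Degenerate inputs (constant
targets, empty communities, ties-only correlations, collinear predictors)
raise or report NA explicitly rather than producing silent numbers.
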