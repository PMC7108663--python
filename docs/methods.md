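# Methods

## Experimental design generator

Choice objects are four vases crossing two binary dimensions, color (stone
vs. wood) and shape (pear vs. cone).  Vase indices are row-major over
(color, shape) with phenotype A first: 0 = (A, A), 1 = (A, B), 2 = (B, A),
3 = (B, B).  An agent's preference is a pair of Bernoulli parameters
(`p_color`, `p_shape`), assumed independent, so the induced vase
distribution is their outer product; the marginals of the induced
distribution recover the parameters exactly.

Each condition's Block-1 roster contains two both-dimension agents, one
single-dimension agent and one uniform agent.  With group dimension g and
non-group dimension o, the canonical Logo roster in offset form (g, o) is
(+s, +s), (+s, −s), (+u, 0), (0, 0), where s = `strong_offset` and u =
`single_offset` (defaults 0.3, giving the 0.8/0.2/0.5 probabilities).
The NoLogo roster is the Logo roster reflected on both dimensions.  These
constraints jointly force: a group mean that deviates from 0.5 on exactly
the group dimension; within-condition symmetry around the group mean on the
non-group dimension; mirror symmetry across conditions; and a uniform grand
mean, so every vase is chosen equally often in expectation.  The exact
probability values are not uniquely determined by the published design
(they are shown graphically only), hence the two offsets are exposed as
parameters and every analysis is required by the test suite to hold for any
valid setting.

The single-dimension agent's preference is placed on the *group* dimension:
with the other rosters fixed, only this placement keeps the group mean's
deviation confined to one dimension.  Block-2 agents deviate from 0.5 only
on the non-group dimension (offset `single_offset`), so their preference is
orthogonal to the group-level preference, and they mirror each other across
conditions.

Counterbalancing of the group dimension (color/shape) and the favored
phenotype (A/B) is implemented per simulated participant as
`participant_id mod 4`, covering all four variants in rotation.  Sex labels
are cosmetic (two per condition) and the 4×100 sub-block structure of
Block 1 has no analytic role, so it is not modeled.

Schedules present each Block-1 agent 50 times in uniformly random order
(400 trials), then each Block-2 agent 30 times with the eight old agents
evenly over the remaining 40 trials (5 each, 100 total).  Presentation
indices count per-agent appearances from 1 and continue across blocks.

## Synthetic participants

No learner model is specified by the design itself; the package adopts the
minimal generative mechanism that produces a differential use of individual
and categorical knowledge.  A participant maintains per-agent count vectors
and one pooled count vector per condition, each initialized with a symmetric
prior (`prior_concentration = 1` pseudo-observation per vase).  The
predictive distribution for the shown agent is the mixture
`(1 − w_c)·normalize(individual) + w_c·normalize(pool)` with `w_c` the
condition's assimilation weight.  Both conditions pool — the conditions
differ only in the weight, reflecting that the hypothesis is a differential
*weighting* of group knowledge, not its presence or absence.  Setting the
weights equal therefore yields a null simulator in which the two conditions
are exchangeable up to the design's mirror reflection.

The prediction policy is `argmax` by default (the task instructs predicting
the *most likely* choice; ties break uniformly at random), or `softmax`
over the mixture probabilities with temperature 0.1 for likelihood-based
work.  Predictions are recorded as missed with probability 0.02 per trial
(the observed human timeout rate is about 2%); the agent's actual choice is
still observed and both count stores are updated, since choice feedback is
shown regardless of the response.  Default weights are `w_logo = 0.5`,
`w_nologo = 0.1` — a clearly separated pair used for effect-detection and
recovery studies.  Block-2 agents start from the prior and join their
condition's pool; note this builds generalization to new group members into
the simulator by construction, so a significant Block-2 interaction is
expected here even though observing one in humans is a substantive finding.

Weight recovery exploits two structural facts: the count trajectories
depend only on the agents' actual choices (recorded in the trial table), so
they can be replayed exactly without knowing the weights; and each trial's
predictive mixture involves only its own condition's weight, so `w_logo`
and `w_nologo` are fitted independently by a 1-D grid search of the softmax
log-likelihood (grid step 0.02).

## Divergence measures

Prediction counts are smoothed additively, adding one pseudocount per vase
before normalizing (`(c + 1)/(Σc + 4)`).  The block analysis smooths only
when some vase was never predicted; the assimilation analysis smooths
always, because its symmetric divergence needs strict positivity on both
sides.  The alternative reading of "one pseudocount over the support" as a
total mass of one (¼ per cell) changes only the smoothing strength, not any
structural result, and is not exposed.

`kl_divergence(p, q)` computes `Σ p log₂(p/q)` in bits with the 0·log 0 = 0
convention, raising an absolute-continuity error when q has zero mass where
p does not.  The analyses put the objective preference in the P slot and
the prediction distribution in the Q slot: this orientation is the one
under which zero *prediction* cells are fatal, matching the operational
need for smoothing.  Tiny negative float residues (order 1e-16, arising
when P and Q are numerically equal) are clamped to zero, which Gibbs'
inequality licenses.  The symmetric divergence is the Jeffreys form
KL(P‖Q) + KL(Q‖P); using the mean instead would scale every comparison by
a constant half.

## Block analysis

The divergence table holds one value per participant × condition × level:
the mean over analyzed agents of the KL divergence from the prediction
distribution to the agent's own preference (Individual) or to the
condition's group preference (Group).  Block 1 analyzes the four original
agents per condition over Block-1 trials.  Block 2 analyzes the new agent
of each condition over Block-2 trials only — the block's purpose is
generalization to an unseen agent; a switch (`block2_agent_set="all"`)
additionally scores the old agents' five Block-2 trials each.  The
group-level reference for Block 2 remains the Block-1 group preference.

The 2×2 fully-within ANOVA uses the contrast method: for each effect the
per-participant contrast score (interaction:
(Logo,Ind − Logo,Grp) − (NoLogo,Ind − NoLogo,Grp)) is tested with a
one-sample t, F = t² with df (1, n−1), p from the F distribution, and
partial η² = SS_effect/(SS_effect + SS_error).  For a 2×2 within design
this is algebraically identical to the full sums-of-squares decomposition
(verified against pingouin in the test suite).  Degenerate inputs: a
constant non-zero contrast has zero error variance (F undefined, flagged);
a constant zero contrast is reported as F = 0, p = 1, flagged.  Constancy is
detected by exact range, not by a variance threshold, so additive-structure
fixtures behave predictably.  All p-values are two-tailed.  Sphericity
corrections are moot for 2-level factors.

## Assimilation analysis

"Trial" in the time course means the per-agent presentation index
k = 1..50, with cumulative prediction counts through k — the final index
then contains the information of all preceding trials, which is what makes
the last-trial test sufficient.  At each k the four agents' smoothed
cumulative distributions are averaged; the dispersion is the mean Jeffreys
divergence of the agents from that mean (an information-theoretic analogue
of mean absolute deviation).  An all-pairs variant (mean Jeffreys
divergence over the six agent pairs) is available behind a flag.

The last-trial condition contrast is a paired Wilcoxon signed-rank test on
NoLogo − Logo (positive = stronger Logo assimilation).  Zero differences
are discarded; tied absolute differences share mid-ranks.  For n ≤ 25
without ties the exact null distribution of W⁺ is enumerated by dynamic
programming over subset rank sums; otherwise the normal approximation with
continuity correction and tie-corrected variance is used.  The z statistic
is always reported from the approximation formula.  The two computation
paths agree within 0.01 at n = 26 and the exact path matches scipy's exact
method to machine precision (both are tested).

The per-k mean NoLogo − Logo difference across participants is fitted with
OLS on ln(k) (statsmodels); with 50 points the residual df is 48.  A
constant response returns a flat fit (β₁ = 0, R² = 0) rather than an
error.  KDE summaries use scipy's Gaussian KDE with Scott's rule
(h_j = n^(−1/(d+4))·σ_j per dimension) over the per-(participant, agent)
marginal prediction probabilities P(color = A), P(shape = A).

## Calibration and power, problem sizes

The test suite checks, among others: type-I error of the interaction test
under the equal-weight null in [0.03, 0.07] at α = 0.05 over 1000 replicate
cohorts of 26 participants (simulated at 10 Block-1 trials per agent and no
Block 2 to keep the replicate loop small — the test's level, driven by the
exchangeability of the mirrored design, does not depend on the trial
count); detection of the full qualitative pattern under w = 0.5 vs 0.1 at
n = 26 with the standard 50-trial schedule in ≥ 80% of 200 replicates; and
recovery of both weights within ±0.1 from a single softmax cohort.  The
directional check on the Individual-level cell means is the weakest
component of the detection pattern (≈ 87% alone), echoing that this
contrast is also the weaker post-hoc in the design.

## Reproducibility

All randomness flows through `numpy` Generators.  Cohorts spawn one
independent child stream per participant from a root `SeedSequence`;
identical configuration and seed reproduce byte-identical summary JSON.
Functions take explicit `rng`/`seed` arguments rather than burying seeds in
parameter objects; the pipeline's root seed lives in `RunConfig`.

## Limitations

The synthetic cohort shares the human data's design, trial counts, miss
rate and hypothesized assimilation structure, but not human learning:
there is no forgetting, no attention drift, no subjective (as opposed to
objective) group prototype, and the missed trials are random rather than
attention-driven.  Passing tests therefore validate the *pipeline* —
its statistics, calibration and power under a known generative mechanism —
not claims about human cognition.  Conclusions about the weights w are
statements about the simulator.
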