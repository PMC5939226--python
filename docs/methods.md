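# Methods

## The task

The simulated paradigm is a two-condition gamble task on a 6 × 6 factorial
grid. Each gamble shows `n ∈ {2, 4, …, 12}` activated tokens on a background
colour cueing an environmental-threat prior `EnvThreat ∈ {1/6, …, 1}` that a
bomb was planted somewhere in a 12-site array. A planted bomb occupies one
site uniformly at random and is *activated* only if it lies under an
activated token, so

    P(ActBomb) = EnvThreat · n / 12  ∈ [1/72, 1].

In the **approach–avoidance (Ap/Av)** condition, accepting wins 10 p per
token unless an activated bomb is present (fixed loss −120 p); rejecting is
worth nothing; paying a 20 p fee *explores* the gamble, uncovering half of
the sites (an activated bomb is therefore seen with probability ½) before a
final accept/reject. In the **approach–approach (Ap/Ap)** control the same
grid is played without possible loss: the subject guesses whether an
activated bomb is present and wins 10 p per token for a correct guess;
exploration works identically.

Model-level quantities are in token units (1 token = 10 p): the loss is −12
tokens and the explore fee 2 tokens. Trial logs carry pence.

The five task-space descriptors per cell — threat, token count, P(ActBomb),
its binary entropy, and the true expected value (Ap/Av:
`EV = −12·P + n·(1−P)`; Ap/Ap: `EV = max(P·n, (1−P)·n)`) — are moderately
correlated by construction; the extreme pair is P(ActBomb) vs Ap/Av EV at
r = −0.86 over the 36 cells. The package treats that number as a structural
check on the grid itself.

## The choice model

Stage-1 choice among accept/no-bomb, reject/bomb and explore follows a
softmax with inverse temperature β over subjective values built from

    a = EnvThreat^j · n / 12          (subjective P(ActBomb))
    k = (a/2) / (1 − a/2)             (Bayes posterior after a null reveal)
    u = H₂(a)                          (binary entropy, bits)

Ap/Av:

    V(Accept)  = a·f + (1−a)·n
    V(Reject)  = 0
    V(NoSee)   = max(k^m·f + (1−k^m)·n, 0)
    V(Explore) = (1 − a/2)·V(NoSee) − 2 + u·w

(a seen bomb is always rejected, so the "see" branch contributes 0).

Ap/Ap:

    V(NoBomb)  = (1−a)·n
    V(Bomb)    = a·n
    V_S2Accept = (1−k^m)·n + i ,  V_S2Reject = k^m·n
    V(NoSee)   = the larger of the two (ties → the bomb guess)
    V(Explore) = (a/2)·n + (1 − a/2)·V(NoSee) − 2 + e + u·w

The free parameters and their interpretations:

| name | scale   | default | meaning |
|------|---------|---------|---------|
| f    | identity| −12     | perceived loss magnitude, tokens (Ap/Av only) |
| j    | log     | 1       | power-law distortion of the threat prior |
| m    | log     | 1       | power-law distortion of the no-see posterior |
| w    | identity| 0       | exploration bonus per bit of entropy of `a` |
| e    | identity| 0       | additive exploration over-valuation, tokens (Ap/Ap) |
| i    | identity| 0       | stage-2 accept bonus after a null reveal (Ap/Ap) |
| β    | log     | 1       | softmax inverse temperature |

Defaults recover the objective-value agent, so the β → ∞ limit of the
default model reproduces the optimal policy cell by cell (tested). A few
grid cells have exactly tied best actions (e.g. threat 2/6 × 12 tokens in
Ap/Av ties accept and explore at 4.0 tokens); the simulator splits such
cells stochastically and all argmax-based checks treat any tied action as
optimal.

Design choices worth making explicit:

- The probability of seeing an activated bomb during exploration is ½
  (half the sites are uncovered); `k` is the exact Bayes posterior under
  that reveal model, which a Monte-Carlo plant→activate→reveal simulation
  confirms.
- The 2-token explore fee is charged in both conditions; in Ap/Ap the free
  additive bonus `e` sits alongside it and can absorb any residual
  mis-specification of the fee.
- Only stage-1 choices enter the likelihood. The value recursion fixes the
  stage-2 policy deterministically (reject after seeing a bomb; otherwise
  the stage-2 argmax), so stage-2 data carry no extra information about the
  parameters; the simulator uses exactly that policy.
- Parameter applicability: `f` only in Ap/Av; `e`, `i` only in Ap/Ap;
  `j`, `m`, `w`, `β` in both but fitted separately per condition, never
  shared.

## Hierarchical fitting

Each subject's free parameters, mapped to an unconstrained scale (log for
`j`, `m`, `β`; identity for `f`, `w`, `e`, `i`), are modelled as draws from
independent group-level Gaussians. Group means and variances are fitted by
type-II maximum likelihood (empirical Bayes) with an EM loop:

- **E-step** — per-subject MAP estimation by L-BFGS on the unconstrained
  scale, started from the group mean, the previous MAP (after the first
  iteration) and seeded prior draws (5 restarts by default in the first
  iteration). The likelihood is evaluated from per-cell choice counts
  (values depend on the trial only through its grid cell), making each
  evaluation O(36).
- **Curvature** — the observed information is a central-difference Hessian
  of the negative log-likelihood, eigenvalue-clipped to positive
  semidefinite, plus the exact prior precision. This keeps the posterior
  precision at least the prior's, so weakly identified directions (`j` and
  `m` trade off against each other at small samples) fall back to the
  prior instead of producing runaway variance corrections.
- **M-step** — group mean = mean of the MAPs; group variance = mean of
  squared deviations plus the per-subject Laplace posterior variances,
  floored at 10⁻⁶. Convergence when the largest hyperparameter change is
  below 10⁻³ (at most 200 iterations).

Subject-level marginal likelihoods use the Laplace approximation
`log p(D|group) ≈ −NLL(θ̂) + log N(θ̂|μ,σ) + (d/2)·log 2π − ½·log det H`,
verified against brute-force quadrature to well under 1 % on 1- and
2-parameter toys. The total Laplace evidence is tracked per EM iteration;
because it is an approximation to the true EM objective it can wobble by a
few units near convergence, which is logged rather than hidden.

Models (subsets of free parameters, β always free) are compared by

    iBIC = −2 · Σ_s log p(D_s | group) + n_hyper · log(n_choices),

with two hyperparameters (mean, sd) per free parameter and `n_choices` the
total number of modelled stage-1 choices. Fit quality is summarised by
McFadden's pseudo-r² against the uniform three-choice model,
`1 − NLL_model / (n · log 3)`; the reference model is a documented package
choice, as is the Gaussian form of the group distributions.

## Synthetic cohorts and what they show

Because no subject data are deposited, validation rests on simulation. The
generator is the exact generative twin of the fitted hierarchy: subjects
drawn from the group Gaussians, sessions of 18 repetitions of the 36
gambles per condition in 12 alternating blocks (1296 trials), bomb states
pre-sampled per trial, softmax stage-1 choices, sampled reveals, and the
deterministic stage-2 policy. Every stream derives from one master seed.

Default generating distributions (unconstrained scale) are fixed once as a
realistic cohort: Ap/Av `f ~ N(−10, 2²)` (the loss slightly under-weighted
relative to the true −12), `log j ~ N(0, 0.3²)`, `log m ~ N(0, 0.4²)`,
`w ~ N(1, 0.5²)` (a positive uncertainty-linked exploration bonus),
`log β ~ N(log 2, 0.4²)`; Ap/Ap uses `w ~ N(0.5, 0.3²)`, `e ~ N(0, 0.5²)`,
`i ~ N(0.5, 0.5²)` with the same `j`, `m`, `β`. Under these values the
simulated choice maps show the task's behavioural signature: the
accept-majority region in Ap/Av (15 of 36 cells) is smaller than the
no-bomb-majority region in Ap/Ap (20 cells) while exploration rates stay
comparable, and choice entropy peaks where value differences are smallest.

Two end-to-end experiments define what "working" means here:

- **Parameter recovery** at study scale (20 subjects × 648 Ap/Av trials,
  the f+j+m+w+β structure): correlations between generating and recovered
  subject-level parameters are ≈ 0.94–0.99 for all five parameters at the
  default generating spread. `j` and `m` are the weakly identified pair;
  their recovery degrades first when trial counts shrink.
- **Model identification**: cohorts generated from the f+w+β model among
  the 8 candidates of the {f, j, w} power set are identified by minimum
  iBIC in ≥ 70 % of 20 seeded replicates. The identification study runs at
  a reduced scale (8 subjects, 216 trials each, 40 EM iterations per fit)
  chosen as the package's standard desk-scale configuration.

What passing these experiments does **not** show: that real subjects follow
the model (simulated agents are the model by construction), that the
printed group-level estimates of any particular cohort would be reproduced
(no data are deposited, so quantities like a fitted pseudo-r² or a fitted
loss magnitude are not targets), or anything about reaction times, learning
dynamics, or anxiety correlations, none of which are modelled.

## Numerical notes

- Softmax uses max-subtraction; β = 0 yields the uniform distribution.
- Log-scale parameters are clipped at e^±30 when mapped back, so extreme
  optimiser probes stay finite.
- Stage-2 value ties resolve to the reject/bomb guess (strict inequality
  for accepting).
- Empty task-space cells in the descriptive maps are reported as missing
  (NaN), never as zero-entropy cells.
- Known limitations: no lapse or perseveration terms, no trial-order
  effects, no shared parameters across conditions, and no full posterior
  sampling (the Laplace approximation is the evidence model throughout).
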