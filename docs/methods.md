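# Methods

## Scope and notation

The package works with paired choice tasks over the EQ-5D-5L: five
attributes (MO, SC, UA, PD, AD), five levels each, health states written as
5-digit labels (11111 best, 55555 worst).  Dummy coding uses level 1 as the
reference, giving a 20-dimensional coefficient vector β ordered
attribute-major (MO2..MO5, SC2..SC5, ...).  All level coefficients are
decrements (≤ 0) and monotone within an attribute in realistic settings,
though estimation does not impose either.

## Design construction

**Generator-developed designs.**  Runs of a strength-2 orthogonal array
OA(25, 5⁵) — built as the regular GF(5) fraction with columns
a, b, a+b, a+2b, a+3b — are paired with their element-wise mod-5 shifts
under generator vectors.  A generator entry of 0 leaves that attribute
overlapping (equal levels in both options); the two overlap generators
(1,1,1,0,0) and (0,0,2,1,1) give 50 sets with exactly two overlapping
attributes each.  For no-overlap designs the selection rule is that, per
attribute, the two generators contribute one shift in {1,4} and one in
{2,3}.

**Optimality bound.**  In an orthonormal contrast coding of each attribute
(rows orthonormal, orthogonal to the constant; `scipy.linalg.helmert`), the
normalized information matrix of a paired design at β = 0 is
`C = (1/4n) Σ z zᵀ`.  Over all cyclic shift distributions, the determinant
of an attribute's 4×4 block is maximised at equal weight on a {1,4} shift
and a {2,3} shift, where the block equals `I/(2(l−1)) = I/8`; the strength-2
property zeroes all cross-attribute blocks.  The package therefore uses
`det(C_opt) = (1/8)^20` as the optimal bound and reports
`(det C / det C_opt)^(1/20)` as D-efficiency.  The quoted generator pair
attains the bound exactly (verified to 1e-9 in the tests); generators with
both shifts in {1,4} attain 2√5/5 ≈ 89.4%.

**D-error.**  `det(M/n)^(−1/20)` in dummy coding, `M = Σ p(1−p) z zᵀ` with
the paired-logit probability p at the evaluation prior; +∞ when singular.
Normalising per choice set makes values comparable across design sizes
(duplicating every set leaves the D-error unchanged).  The Bayesian D-error
is the mean over prior draws; with the single zero draw it coincides with
the zero-prior D-error.

**Modified Fedorov search.**  Exchange search over an explicit candidate
set of choice sets: seeded random start, per-position scan of all
candidates, acceptance of the largest D-error reduction (ties to the lowest
candidate index), termination when a sweep's relative improvement falls
below 1e-8 or after 50 sweeps.  Determinant ratios are computed by the
rank-2 matrix determinant lemma against the running inverse, with an exact
recompute each sweep to kill drift.  Exchange searches are local, so
`n_restarts` repeats from distinct seeded starts and keeps the best; on a
24-candidate pool the search (5 restarts) matches the exhaustive optimum
over all C(24,21) subsets.  At least 20 choice sets are needed for a
nonsingular 20-parameter information matrix — there is no meaningful
D-error for smaller designs.

**Constrained Bayesian search.**  Same exchange mechanics, minimising the
Bayesian D-error subject to: no duplicated unordered pair, no dominated
option (one state weakly better everywhere and strictly somewhere), and
level balance — each level of each attribute within ± `level_balance_tol`
(default 1.0) of the uniform count 2n/5 over all options.  Acceptance is
lexicographic (balance violation first, then D-error), and an
infeasibility error is raised if the search ends unbalanced.  The exact
level-balance rule used with the published algorithm is not available, so
the ± tolerance band is this package's stand-in.

**Candidate enumeration.**  All unordered pairs with exactly *o*
overlapping attributes are enumerated in a fixed lexicographic order
(closed-form count `C(5,o)·5^o·20^(5−o)/2`; e.g. 31,250 at o = 4 and
1,000,000 at o = 2), with optional dominance exclusion and seeded uniform
subsampling.

## Estimation

**MNL.**  With two options and i.i.d. type-I extreme value errors the
choice probability depends only on `z = x_A − x_B`, so estimation is a
binary logit without intercept (statsmodels, Newton MLE).  Variances come
from the observed information; Wald p-values.  AIC = −2ℓ + 2k;
BIC = −2ℓ + k log(number of choice tasks).  Rank-deficient difference
designs are reported (`rank_deficient`) and SEs fall back to the
pseudo-inverse; separation is reported via `converged = False` with a
message rather than raised.  The interaction model enters
`f_i · (x β_int)` for a 0/1 full-attendance flag, so a full attender's
total decrement is β_main + β_int.

**Anchoring.**  Coefficients are divided by the summed level-5 decrement
(the utility of state 55555 relative to 11111), making the anchored value
of 55555 equal to 1 and the scale invariant to positive rescaling of β.
Since β and the anchor share a sign, anchored values are positive; the raw
(negative) decrements are retained alongside wherever both are useful.

**ECLC.**  Shared β, class-specific zero masks, EM:

* E-step: per-respondent posterior class probabilities from (β, π),
  accumulated in log space (`logsumexp`).
* M-step: π is the posterior mean; β takes up to five Newton steps on the
  expected complete-data log-likelihood with step-halving.  Any Q increase
  suffices for EM monotonicity (generalized EM), and the step-halving guard
  enforces it; the log-likelihood trace is recorded and asserted
  non-decreasing in the tests.
* Initialisation: π uniform, β from the plain MNL fit; optional seeded
  jitter restarts keep the best final log-likelihood.  Convergence when the
  log-likelihood gain drops below 1e-6 (500 iterations cap).
* Classes are structural (tied to attendance patterns), so there is no
  label switching.  A class whose probability collapses is reported, not
  raised.  Parameter count for AIC/BIC: the coefficients attended in at
  least one class, plus C − 1 mixing weights.

The all-ignored class has β_c = 0 and hence probability exactly 1/2 for
every pair; its log-likelihood is −(ΣᵢTᵢ)·log 2 identically, which the
tests assert.  With the full-attendance-only class the model reduces to the
MNL, and the EM solution matches the statsmodels fit to 1e-5 — a deliberate
cross-check of two independent implementations.

**Five-step class selection.**  Step 1: full attendance + the five
one-ignored patterns (6 classes).  Steps 2–3: drop classes with π below the
threshold (default 5%), add the ten two-ignored, then ten three-ignored
patterns.  Step 4: add the five single-attended patterns and the
all-ignored class.  Step 5: re-fit the survivors.  Dropped classes never
re-enter.  Screening fits use a looser EM tolerance (1e-4, 200 iterations)
than the final re-fit; the threshold decision does not need more.  With
threshold 0 nothing is ever dropped and the final model carries all 32
patterns (an over-identification warning is logged).

The procedure is genuinely fragile in small samples: when a true class's
behaviour is mimicked by whatever classes are available at an early step
(e.g. random choosers parked in a single-ignored class before the
all-ignored class is offered at step 4), a true class can be starved below
the threshold at a step-1 optimum and permanently lost.  This is a property
of the sequential design — verified by showing truth-initialised EM
converges to the same step-1 solution — not of the optimiser.

**Classification and CIs.**  Respondents are classified full / partial /
non by modal posterior class, ties broken toward the class with larger π.
With 21 tasks the Bayes-optimal classifier under the *true* parameters
attains only ~0.73–0.79 accuracy on the default scenario — an information
ceiling; the tests assert the estimated classifier comes within 0.03 of
that oracle rather than an absolute figure the data cannot support.
Class-probability CIs are percentile bootstrap over respondents (fixed
spec, warm-started re-fits), expanded if necessary to contain the point
estimate; the CI construction used for the published tables is unknown, so
widths are not an equivalence target.

## Synthetic data

The generator emulates the structure the analysis assumes: a respondent
draws an attendance class, then answers each task by the paired logit under
the masked shared β.  Defaults define the study conditions: the matching
generator design, 500 respondents × 21 tasks, classes {full 0.5, PD+AD
ignored 0.3, all ignored 0.2}, and a monotone β with level-2 decrements
near −0.2 and level-5 near −1 (per-attribute scales 1.1, 0.9, 1.0, 1.2,
0.8 — plausible magnitudes chosen once; configuration, not ground truth).
All randomness flows from one scenario seed through a fixed SeedSequence
split (task subset, class draws, choices, straightliners, engagement).

The 21 presented tasks are a seeded subset of the design's 50 sets,
redrawn (deterministically) until the dummy difference matrix has full
column rank: a subset leaving some attribute level never varying would be
an instrument that cannot estimate its own parameters.  Straightliner
contamination overwrites ⌊fraction·n⌋ respondents with fixed-position
answers (half left, half right), independent of the class draw.  Optional
engagement covariates draw completion times (lognormal around
class-specific medians 6.3/5.0/3.2 min for tasks, 10.2/8.7/7.6 for the
survey) and feedback agreement (probabilities 0.82/0.71/0.56, 10%
item-nonresponse) ordered full > partial > non by construction.

What the simulations do *not* emulate: preference heterogeneity within
classes, panel correlation beyond the class draw, dimension-order effects,
fatigue or learning across tasks, and real feedback behaviour.  Passing
recovery tests therefore show the estimators are correct under the model's
own assumptions, not that the model is correct for any survey population.

## Numerical and design choices

* Unordered-pair identity for duplicates ((A,B) ≡ (B,A)): a swapped pair
  carries identical information under the MNL.
* Fedorov tie-breaks to the lowest candidate index; all searches are
  bit-reproducible given a seed.
* Recovery tests average over a fixed prefix of seeds (1–3) rather than a
  single draw: the class-probability MLE has sampling SD ≈ 0.03 at n = 500,
  so single-seed checks against a ±0.05 band measure luck as much as
  correctness.
* The overlap-2 analysis arm shows honestly degraded class identification:
  under the overlap generators, PD+AD-ignorers are behaviourally identical
  to full attenders on the tasks whose generator zeroes PD and AD.

## Known limitations

* Only two-option choice sets; other attribute systems are handled
  generically by the enumeration utilities but untested beyond 5×5.
* ECLC assumes preference homogeneity across classes; models separating
  heterogeneity from non-attendance are out of scope.
* The sequential selection procedure is order-dependent by construction
  (dropped classes never return); a switch to allow re-entry would be a
  different procedure and is deliberately not the default.
* Bootstrap CIs at realistic sizes are expensive (one re-fit per
  replicate); the analysis scripts use 30 replicates.
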