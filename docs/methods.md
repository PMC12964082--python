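# Methods

## The transmission model

`dextral` implements the gene-culture model of human hand preference due to
Laland, Kumm, Van Horn and Feldman (1995), restricted to the regime the
data analysis actually uses: the right-shift allele D is assumed fixed, so
genetic variation is gone and every individual shares a genetic bias
`rho` towards right-handedness.  Conditional on the parental mating class,
an offspring becomes right-handed with probability

| mating class | P(right-handed offspring) |
|---|---|
| R x R   | 1/2 + rho + alpha |
| mixed   | 1/2 + rho + beta  |
| L x L   | 1/2 + rho - alpha |

`alpha >= 0` is the cultural effect of two same-handed parents, `beta`
(free sign; zero in the two-parameter model) the effect of mixed-handed
parents.  Offspring within a family are conditionally independent.  Under
random mating by phenotype the right-hander frequency F obeys

    F' = F^2 (1/2+rho+alpha) + 2F(1-F) (1/2+rho+beta) + (1-F)^2 (1/2+rho-alpha)

Note the squared weight on the L x L term: the three mating-class weights
are the Hardy-Weinberg-like pair frequencies (F^2, 2F(1-F), (1-F)^2) and
must sum to one; some printed statements of this recursion omit the square,
which breaks probability conservation, and we treat that as a typo.

Setting F' = F gives the equilibrium.  For beta = 0 it is closed-form,
F* = (1/2+rho-alpha)/(1-2 alpha); for beta != 0 it is the root in [0,1] of

    -2 beta F^2 + (2 alpha + 2 beta - 1) F + (1/2 + rho - alpha) = 0.

When both roots land in [0,1] the stable one (|dF'/dF| < 1) is kept.  The
closed form is verified against long fixed-point iteration of the
recursion (tolerance 1e-10) in the test suite, including a 1,000-draw
property test over the feasible region.  The model's *true incidence* of
left-handedness is `t = 1 - F*`; at the published point estimates
(rho = 0.277, alpha = 0.138) it is about 11.7%, i.e. ~88% right-handers.

Twin-pair expectations follow from the same machinery: parents mate at
random at equilibrium and both twins draw independently from their mating
class's row, so MZ and DZ pairs have identical expected (RR, RL, LL)
frequencies — about 20% discordance at the published estimates.

## Criterion-shift adjustment

Studies differ in the behavioural criterion used to call someone
left-handed, so each study's measured incidence (`m_p` parents, `m_o`
offspring) can deviate from `t`.  Following McManus (1985), the deviation
in each generation is attributed to exactly one error type (mutually
exclusive, collectively exhaustive), with proportions fixed by marginal
consistency — the misclassification map must carry `m` onto `t` (parents,
measured -> true) or `t` onto `m` (offspring, true -> measured):

    m_p > t:  u = (m_p - t)/m_p        (measured-left parents truly right)
    m_p < t:  v = (t - m_p)/(1 - m_p)  (measured-right parents truly left)
    m_o > t:  w = (m_o - t)/(1 - t)    (true-right offspring measured left)
    m_o < t:  x = (t - m_o)/t          (true-left offspring measured right)

Exact equality (|m - t| < 1e-12) maps to the identity.  The per-parent map
expands independently over the two parents of an (unordered) mating into a
3x3 row-stochastic matrix P; the offspring map is the 2x2 matrix O; the
measured-frequency table is M = P T O.  For twins the offspring map is
applied independently to both members of a pair (a 3x3 pair-transition
matrix on RR/RL/LL).  All of these forms are validated in tests against
brute-force expansions and a numeric marginal-consistency solver, since
the defining property (not the matrix entries) is what the construction
must satisfy.

For the sex-stratified extension the adjustment is configured as follows
(a design choice; the ingredients are the same per-individual maps):
a single pooled `m_p` over all parents with a 4x4 ordered-mating P (the
Kronecker square of the per-parent map), and per-sex `m_o` with per-sex O
whose true incidence is the sex-specific equilibrium incidence.

## Likelihoods, scenarios, estimation

The support function (log-likelihood without binomial coefficients, which
affect neither estimates nor G nor likelihood ratios) is

    S_T = sum_studies sum_classes [ R ln T(R|c) + L ln T(L|c) ]

and S_M likewise with each study's own M = P T O, where `t` and the
nuisances are recomputed from the candidate parameters at every
evaluation.  A flag restores the coefficients for users who want proper
log-likelihood values.

Three analysis scenarios: **A** estimates and tests on T; **B** estimates
on T but tests on M (the reading that reproduces the 1995 analysis); **C**
estimates and tests on M.  A and B share estimates by construction.

Estimation minimises the negative support with Nelder-Mead, multi-start:
starting points drawn uniformly from the feasible region
(rho in [0, 0.5], alpha in [0, 0.5 - rho], beta within the probability
bounds), infeasible proposals receiving a large sentinel penalty;
tolerances 1e-8.  Headline fits default to 1,000 random starts; the
simulation harness uses the five fixed guesses (rho, alpha) = (0.1, 0.1),
(0.01, 0.1), (0.1, 0.01), (0.45, 0.01), (0.01, 0.45).  A vectorised grid
search over the same box validates the simplex optimum and exposes the
support surface.

The sex-difference family replaces the mixed class with ordered
mother x father matings and splits offspring by sex: effects `alpha_i`
(same-handed parents), `beta_i` (right mother, left father), `gamma_i`
(left mother, right father) for offspring sex i, sharing one `rho`.
Models I (no sex differences, beta = gamma = 0, 2 parameters), II (no sex
differences, 3), III (parental sex differences only, 4), IV (offspring sex
differences with beta = gamma per sex, 5) and V (unconstrained, 7) form a
nesting chain compared by Wilks likelihood-ratio tests.  The sex-structured
equilibrium iterates the coupled (female, male) right-hander frequencies
under 1:1 sex ratio and random mating to 1e-10.

## G-tests and degrees of freedom

G = 2 sum O ln(O/E) over all cells, with E = class total x model
probability; zero observations contribute nothing; a zero expected
probability against a positive count is an error, never silently dropped.
Expected and observed totals match per mating class by construction, and
expected cells below 5 raise a warning flag.  Each familial study carries
df = 2 (three class cells minus the offspring criterion-shift nuisance);
S studies combined give df = 2S - k with k fitted parameters — for the
17-study compilation, df = 32 (two parameters) and 31 (three).  Twin
datasets carry df = 1 each and the combined twin df is the plain sum,
because no parameters are fitted to twin data.

## Synthetic data

The generator is the package's definition of the study conditions:

* 17 studies of 520–1,450 couples (30,000 offspring total, three children
  per couple — the "triplet" convention), matching the scale of the
  historical familial compilations;
* true mating-class counts drawn multinomially from the equilibrium pair
  distribution at the generating parameters; offspring binomial from T;
* criterion shift per study and generation: magnitude ~ U(0, 0.2) and a
  random direction, drawn independently for the parent and the offspring
  generation, applied as an independent per-individual misclassification
  probability.  Parents that flip move their family to the measured mating
  class; `m_p` is recomputed from the measured couple counts and `m_o`
  from the measured offspring counts.  Studies whose measured incidences
  degenerate to 0 or 1 are redrawn (bounded retries).

The shift generator is a deliberate, documented choice — published
accounts of such simulations leave the shift distribution unspecified —
so headline bias/MSE magnitudes depend on it and are treated as
order-of-magnitude targets, not exact ones.  What the generator does *not*
emulate about real data: family-size variation and sibling correlation
beyond the binomial model, secular trends in incidence, and any
correlation between the parent and offspring shifts of a study; passing
tests therefore validate the estimator under the model's own assumptions,
not the model's truth for real populations.

The bundled familial fixture (`familial17_synthetic.csv`) was produced by
this generator at rho = 0.277, alpha = 0.138 (seed 1995) and is labelled
synthetic: the historical 17-study count table is not redistributable
here, so published-value replication targets are documented in the
acceptance tests but can only be achieved when that table is supplied.
The bundled twin fixture reconstructs the two pooled MZ/DZ cross-tables
from published pooled totals (2,900 MZ pairs, 13.8% left, 21.68%
discordant; 2,589 DZ, 13.34%, 22.6%) to integer rounding.

## Estimator evaluation, bootstrap, filters

The harness fits every synthetic dataset (five fixed starts), reporting
per-parameter bias and MSE, and optionally non-parametric bootstrap
percentile intervals: offspring outcomes are resampled with replacement
within each study x mating-class cell (cell totals fixed) and `m_o`
recomputed per resample.  When `m_p` is itself derived from couple counts,
those counts are resampled multinomially and `m_p` recomputed as well —
omitting this leaves out the parental sampling noise that feeds the
adjustment and makes the intervals visibly under-cover.  Bootstrap refits
start from the dataset's point estimate (tolerance 1e-6); refit failures
are dropped and counted, with more than 50% failures an error.

Two practical non-identifiability filters are applied before evaluation
when enabled: datasets with measured left-handedness below 1% in either
generation, and datasets whose pooled empirical p(R|RxR) - p(R|LxL)
contrast is below 7 percentage points.  In both situations the mating
classes carry almost no information about (rho, alpha) separately.  The
bundled fixture passes both filters.

Default problem sizes in the tests and the acceptance script (hundreds of
datasets, tens of bootstrap resamples) are scaled-down versions of the
full protocol (15,000 datasets, 200 resamples); all sizes are plain
function arguments, and every random draw descends from a single recorded
seed.

## Known limitations

* Pre-fixation dynamics (selection on D, genotype trajectories) are out of
  scope; everything conditions on fixation of D.
* The supplementary linear-regression bias correction for unadjusted
  estimation is not implemented.
* The beta != 0 equilibrium root choice is verified numerically over the
  sampled region rather than proved globally.
* With `m_p` stored only as an externally reported number (no couple
  counts), the bootstrap cannot propagate parental sampling noise and
  intervals may under-cover for scenario C.
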