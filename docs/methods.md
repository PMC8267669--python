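# Methods

## Sensitivity calling and the marker screen

A cell line is *sensitive* to a target knockout iff its gene-effect
score is strictly below the threshold τ (default −0.5, dimensionless
gene-effect units in which 0 is non-essential and −1 is the median of
common-essential genes). The inequality is strict: a score of exactly
−0.5 is not sensitive. Lines with a missing target score are excluded
from all counts — they are never treated as insensitive.

The analysis universe is the intersection of cell-line ids present in
the gene-effect matrix and the mutation table (identity key is the
screen-sample id, never the human-readable name). Mutation records whose
`Variant_Classification` is exactly the token `Silent` are removed
before marker calling; a case-insensitive near-miss (`silent`) is
retained and logged, because silently filtering on a mislabeled token
would be worse than a visible warning. A line is "mutated in G" iff at
least one retained record exists for the pair; duplicates collapse, and
genes with no mutated universe line are dropped.

Each marker is tested on the 2×2 table over evaluable lines
(a = mutated ∧ sensitive, b = mutated ∧ insensitive, c/d = wild-type
counterparts). The default test is the one-sided Fisher exact test with
the alternative "sensitivity enriched among mutated lines", computed as
the hypergeometric tail P(A ≥ a) at the observed margins. Two selectable
variants support sensitivity analysis: the two-sided Fisher exact test,
and a one-sided Wilcoxon rank-sum test asking whether the raw scores of
mutated lines are shifted downward (this variant does not dichotomize
at τ). Degenerate margins (no mutated line, all lines mutated, no
sensitive or no insensitive line) carry no contrast and are reported as
p = 1 with a flag rather than raised as errors, so a screen over
thousands of markers never aborts mid-way.

Raw p-values are compared with α = 0.05; no multiplicity correction is
applied to the significance flag, but Benjamini–Hochberg q-values over
all emitted tests are always included so users can apply FDR control.
Markers mutated in fewer than m_min = 10 lines are flagged
`below_min_mutated` and kept: sparse markers are unreliable for
inference but may still be worth follow-up. Results are ordered by
ascending p with a deterministic tie-break (descending mutated count,
then symbol). The cross-target intersection keeps markers that are
significant and not sparse in *every* screen over the same universe.

Two properties of the exact test are worth stating because they shape
what calibration checks can show. First, it is conditional and
discrete: under a null in which each gene is mutated in ~39 of 777
lines, the attainable p-values near 0.05 are ~0.01 apart, so the
achieved rejection rate at p < 0.05 sits visibly *below* 0.05 (we
measure ≈ 0.035 at these margins). The test controls the type-I error
rate; it does not attain it exactly. Second, the one-sided p is
monotone in a at fixed margins, which the suite checks directly.

## Co-dependency

Pearson correlation between two genes' dependency profiles over
pairwise-complete lines. The effective sample size is always reported;
a correlation over fewer than 3 pairs or against a zero-variance
profile is *undefined* and flagged (reporting 0 would fabricate a
value). Ranking excludes the query itself and breaks ties by symbol.
Whether to correlate over all release lines or only the harmonized
universe is the caller's choice of input matrix; both are legitimate
and can differ slightly.

## Survival engine

Kaplan–Meier uses the product-limit estimator over distinct observed
times with Greenwood variance; censoring at t removes subjects from the
risk set after t. The two-group log-rank test accumulates
observed-minus-expected events with the hypergeometric variance at each
distinct event time and refers (O−E)²/V to χ²(1); a cohort pair with
zero events is a flagged degenerate result (p = 1), not an error.

Univariate Cox regression maximizes the partial likelihood with the
Efron approximation for tied event times, by Newton iterations on the
scalar coefficient with step-halving, to gradient tolerance 1e−8 and at
most 100 iterations (non-convergence raises with diagnostics; the
covariate is mean-centered internally, which leaves the partial
likelihood invariant). The fit reports β, SE from the observed
information, HR = exp(β), the 95% CI exp(β ± 1.96·SE), and Wald,
likelihood-ratio, and score-test p-values. With a binary covariate and
no tied times the score test is algebraically identical to the log-rank
statistic; the implementation realizes this identity to ~1e−10 in p,
which serves as a cross-check between the two independently implemented
routes (the Cox path is additionally verified against an established
Efron-ties fitter).

### Quartile-restricted cutoff scan

Candidates are the distinct observed expression values v with
Q1 ≤ v ≤ Q3 (quantiles by linear interpolation); each dichotomizes the
cohort as high iff expression > v (strict, fixed for determinism). Each
candidate is scored by the Cox likelihood-ratio p of the binary
indicator — the LRT is the most stable small-sample criterion, with the
Wald p also recorded per cutoff. The selected cutoff minimizes the LRT
p, ties broken toward the median and then toward the lower value.
Candidates whose split cannot be fitted (an empty side, too few events)
are flagged and skipped; if none fits, the scan fails loudly.

The scanned minimum p is optimistic: the minimum over ~n/2 correlated
tests is stochastically smaller than any single prespecified split. The
scan therefore never beats being bounded above by the median split
(when the median's dichotomy is among the candidates, which holds for
any cohort whose median-or-below values reach Q1 — always, in practice,
at the ≥20-subject minimum), and the suite asserts that bound on null
cohorts. Results are reported verbatim, as is conventional for
cutoff-optimized survival tools, with a `cutoff_optimized` caveat flag
always attached and no correction applied by default.

## Synthetic-data generators

The generators define the conditions under which the pipeline is
verified:

- **Gene effects.** Each selective gene assigns every line a latent
  sensitive state ~ Bernoulli(π); scores draw from N(−0.8, 0.1) when
  sensitive and N(0, 0.15) otherwise. The sensitive component sits 3 SD
  below τ = −0.5 and the background 3.3 SD above it, so latent state and
  thresholded call agree up to ~1.4e−3 tail probability per draw. A
  two-component mixture (rather than a continuous latent factor) was
  chosen because it makes the planted 2×2 table exactly computable.
  Co-dependent groups share one latent Bernoulli state: each member
  adopts it with concordance ρ, else redraws independently — planting
  both correlated profiles and concordant calls.
- **Mutations.** The marker gene mutates with probability q1 in
  sensitive lines and q0 elsewhere (odds ratio (q1/(1−q1))/(q0/(1−q0)));
  background genes mutate at 5% independently of sensitivity, matching
  the order of per-gene non-silent mutation prevalence in public
  cell-line panels. Records are labeled Silent with probability
  `silent_fraction` (default 0), else drawn uniformly from common
  non-silent classes.
- **Survival.** Event times are exponential with rate h0·exp(β·x),
  x ~ N(0,1), with independent exponential censoring and an optional
  administrative cutoff. Defaults: h0 = 0.1 events per time unit, no
  censoring.

Study conditions used throughout the verification suite and the
acceptance script: 777-line screens with π = 0.3, planted marker
q1 = 0.5 vs q0 = 0.05 among 200 background genes (50 null-screen and
100 recovery replicates); 2000 null log-rank cohorts at n = 100; 200
Cox-recovery cohorts at n = 500, β = ln 2; a 400-subject two-population
cohort (expression modes 0 and 3, SD 0.5, hazard ratio 3) for the
cutoff scan; a 2000-line trio at ρ = 1 for co-dependency. These sizes
keep each stage's Monte-Carlo error small relative to the tolerance it
is checked against.

What the generators do **not** emulate: lineage structure and batch
effects, realistic mutational signatures or hotspots, copy-number and
expression markers, correlated background genes, non-proportional
hazards. Passing tests therefore demonstrate statistical correctness of
the machinery on well-specified data, not robustness to every artifact
of real screens.

One RNG stream per generator operation, seeded independently, so
changing one spec leaves sibling datasets unchanged; identical spec and
seed reproduce identical output bytes.

## Numerical and design choices

- Gene-effect CSV parsing is round-trip exact (floats re-read
  bit-identically); a non-numeric score cell becomes missing and is
  counted in the load report, never silently coerced. DepMap headers
  `SYMBOL (ENTREZ)` split at the last `" ("`.
- Missing scores are excluded pairwise per operation, never imputed.
- Fisher one-sided p via the hypergeometric survival function (log-gamma
  based), verified against exact integer enumeration to 1e−12 over all
  tables with n ≤ 30.
- The KM variance is reported as 0 (not ∞) once the estimate reaches 0.
- All ranking tie-breaks are deterministic (stable sorts with explicit
  secondary keys), so reports are byte-reproducible.

## Known limitations

- Mutation markers only: presence/absence of non-silent mutations, no
  copy-number, fusion or expression markers in the screen itself.
- Univariate survival analysis only; no multivariate Cox, competing
  risks, or interval censoring.
- The screen tests dependence, not causation; lineage confounding is
  not adjusted for.
- The cutoff scan's selection optimism is flagged but not corrected;
  treat scanned p-values as exploratory.
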