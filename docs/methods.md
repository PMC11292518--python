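# Methods

## Scope and model

`aquaconv` detects convergent evolutionary signatures of a binary trait —
built around the fully aquatic mammals (African manatee, bottlenose dolphin,
blue whale) against terrestrial mammals — through two statistically
independent routes: convergent amino-acid substitutions, and convergent
acceleration of relative evolutionary rates (RERs).  Everything runs on
protein alignments and a rooted species tree; codon models, topology search
and dating are out of scope.

### Substitution model

Sequences evolve under a time-reversible 20-state Markov model: the JTT
empirical exchangeability matrix *S* combined with equilibrium frequencies
π, giving `Q_ij = S_ij π_j` (i ≠ j) with the diagonal set so rows sum to
zero, normalised so that −Σ π_i Q_ii = 1 — branch lengths are expected
substitutions per site.  Frequencies are either the JTT model's own or, by
default in the pipeline, the "+F" frequencies observed in the analysed gene
(with a 10⁻⁶ pseudocount so none is zero).  Among-site rate variation uses
Yang's discrete approximation to Gamma(α, α): K equiprobable categories,
each represented by its conditional mean, computed in closed form from the
regularised incomplete gamma function.  Defaults: α = 1.0, K = 4.  The gamma
shape is deliberately exposed rather than fixed: nothing in the package
depends on a particular α, and a per-gene estimated shape can be plugged in
through the model constructor.

The packaged JTT constants (`data/jtt.dat`) are the published Jones–Taylor–
Thornton (1992) values as distributed with standard phylogenetics software
(`jones.dat`); the file header states the layout.

### Likelihood and ancestral reconstruction

Felsenstein pruning over unique site patterns with per-pattern log-scale
accumulators; gap and unknown residues are missing data (tip partial of
ones).  Site log-likelihoods mix the K categories with equal prior weight.
Marginal ancestral posteriors come from the standard two-pass (inside ×
outside) algorithm; per node and site the category-specific conditionals
are mixed with the *site-specific posterior* category weights, giving the
exact marginal rather than the prior-weighted approximation.  Maximum a
posteriori (MAP) state calls break ties by alphabetical amino-acid order so
reruns are bit-identical.  Tip "posteriors" are point masses on the
observed residue and uniform over the 20 states for missing data (a
reporting convention; internal-node posteriors for an all-gap column
correctly equal π).

Correctness is anchored by an exhaustive-enumeration oracle: on random
trees of ≤ 5 leaves with random reversible models, pruning log-likelihoods,
marginal posteriors and category weights match a direct sum over all joint
ancestral state assignments to 10⁻⁸ (100 instances in the acceptance suite).

### Branch-length estimation

Per-gene branch lengths are fitted on the fixed topology by coordinate
ascent: bounded Brent search of each branch's one-dimensional likelihood
profile in [0, 20].  A sweep walks the tree in postorder, refreshing inside
partials with lengths already updated in that sweep while outside partials
are refreshed once per sweep; since that staleness can overshoot, a sweep
that fails to improve the full log-likelihood is damped by a line search
toward the previous point, making the reported likelihood non-decreasing
across sweeps.  Convergence: sweep improvement < 10⁻⁶ nats (default) or 100
sweeps, in which case the result is flagged unconverged rather than raising.

Two numerical points worth knowing:

- **Root ridge.**  Under a reversible model the likelihood depends on the
  two root-child branches only through their sum; the optimiser leaves the
  split at whatever the data cannot distinguish.  Recovery tests therefore
  check the sum for that pair and individual lengths elsewhere.  Neither
  root child is a foreground branch, so the RER association never sees this
  ridge.
- **Sweep tolerance in the calibration studies.**  The one-dimensional
  searches run at xatol 10⁻⁵, which leaves a ≈ 10⁻⁵-nat noise floor on the
  sweep improvements; below that, extra sweeps only chase noise.  The
  calibration studies and the pipeline therefore run the optimiser at a
  sweep tolerance of 10⁻⁴ (lengths change by < 0.1% relative to the 10⁻⁶
  setting, RERs negligibly), while the function default remains 10⁻⁶.

On data simulated under the model on a 4-leaf tree, 50,000 sites recover
all identifiable lengths within 5%, and the mean error shrinks as length
grows through 500 → 5,000 → 50,000 sites.

## Stage 1 — convergent substitutions

**Screen.**  A column is a candidate when all foreground species share one
residue F, all background species share one residue B, and F ≠ B.  The
marsupial outgroup (Tasmanian devil) is exempt — its large distance from
placentals makes the identity requirement uninformative — and may carry any
state.  A gap or unknown in any non-exempt species disqualifies the column
(the strictest reading of requiring within-group identity).  The screen
inspects extant sequences only; internal branches enter at the counting
step.

**Counting.**  Foreground branches are the three tip branches plus the
cetacean ancestor.  Counting runs over all unordered pairs of foreground
branches in which neither is ancestral to the other (so dolphin–cetacean
ancestor is excluded, manatee–cetacean ancestor is not).  At a site, a pair
counts one observed convergent substitution when both branches substitute
(MAP parent state ≠ MAP/observed child state) and the derived states
coincide.  Parallel substitutions (equal ancestral states) are included by
default, matching the inclusive usage of "convergent"; a
`strict_convergent_only` flag restricts to unequal ancestral states.

**Expectation.**  E sums, over sites, pairs and rate categories, the
probability that both branches independently substitute to the same derived
state, using the marginal parent posteriors and the category-specific
branch transition matrices, weighted by the site's posterior category
weights.  Treating the two parent posteriors as independent is the
approximation inherent to counting on marginal reconstructions (they are
correlated through shared data); it is slightly conservative in E for
sibling foreground branches.  By default E accumulates over **all** columns
— the per-gene null expectation — with screened-columns-only available as
an option (`expected_over="candidates"`), since either reading is
defensible.

**Test.**  p = P(X ≥ O) for X ~ Poisson(E); p = 1 when O = 0; E = 0 with
O > 0 reports p = 0 with a degenerate-expectation flag.  Genes with p < 0.05
are convergent; screened genes failing the test keep the trait-specific
label.  The Poisson null ignores the variance inflation from reusing one
reconstruction across sites, so the type-I rate is bounded (≤ 0.10 in the
acceptance suite) rather than asserted equal to the nominal 0.05.

## Stage 2 — RER association

Gene trees (from the stage above's estimator), a master tree of branch-wise
mean lengths across genes, then per gene: regress √(gene length) on
√(master length) across branches by ordinary least squares with intercept
and take standardized residuals (residual / √(RSS/(n−2)); all-zero when the
fit is exact).  The square-root transform stabilises the variance of
substitution counts; OLS with standardization is a deliberate,
dependency-free simplification of the weighted-regression variant used by
the R package that popularised RERs — the hook for alternative transforms
is the function boundary itself.  Branches of length 0 are data; branches
absent from a gene are missing; genes with < 3 usable branches yield an
all-missing column.

Association: two-sided Wilcoxon rank-sum of foreground vs background RERs,
exact null for small untied samples and tie-corrected normal approximation
otherwise; the effect size Rho is the rank-biserial correlation
2U₁/(n₁n₂) − 1, positive when foreground RERs are larger.  Genes with
Rho > 0 and p < 0.05 are convergently accelerated.  RERs are invariant to a
common rescaling of all gene trees (the regression absorbs it).

## Selection post-filters and genome statistics

Branch-site scan records (null/alternative log-likelihoods, BEB site
posteriors) are consumed from a TSV; the package applies 2ΔlnL against
χ²(df = 1) (a 50:50 boundary mixture is available), Benjamini–Hochberg
FDR, BEB > 0.5 site selection (strict), and the spacing rule: a gene is
removed when it has ≥ 2 selected sites whose consecutive intervals have
median ≤ 10 residues — with exactly two sites the single interval is its
own median; 0–1 sites never remove a gene.  The FDR significance threshold
is a config parameter (default 0.05) with no claim about any particular
study's setting.

Genome-wide heterozygosity is the ratio of heterozygous to all callable
sites after removing sites of depth < 10 (the denominator is depth-passing
sites, not genome length).  QV converts to errors per 10,000 bases as
10^(4 − QV/10); assembly fractions are reported at 3 decimals; gene-set
combination is exact set algebra with the inclusion–exclusion identity
asserted.

## Synthetic data: what it emulates and what it does not

The packaged 19-mammal tree follows the accepted placental topology for
these species (marsupial outgroup; sloth + manatee/elephant; primates and
rodents; bats, carnivores, horse, and the cetaceans inside Cetartiodactyla,
with the dolphin–whale ancestor labelled "Cetacea").  Its branch lengths
are **synthetic**, scaled to plausible amino-acid substitutions per site
(total tree length ≈ 1.9): the literature provides divergence times, not
per-gene substitution lengths, so no output on this tree reproduces any
published divergence estimate.

Simulation draws root states from π, one gamma category per site, and
propagates states through P(r_k t) down each branch, recording every
ancestral state.  Convergent columns are *injected by rewriting*: all
foreground species receive a shared derived state that differs from the
generating states at the foreground branches' parents, the background is
overwritten with a single different state, the exempt species is left
alone.  Rewriting (rather than re-simulating conditioned histories) is
sufficient because the screen and the counts inspect states, not histories;
the cost is that injected columns are not samples from any explicit
convergence process.  Accelerated genes multiply foreground branch lengths
by a factor (default 2) before simulation.  Variant tables are
Bernoulli(het rate) genotypes with Poisson depth, written as minimal VCF.

Real alignments additionally contain alignment error, indels,
heterotachy, selection, and non-independence between genes; passing
calibration here shows the machinery is correct and well-calibrated under
its own model, not that real-data error rates match.

## Calibration studies (standard sizes)

- Convergence stage: 500 null genes and 50 genes with 3 injected columns,
  500 sites each.  Reported: fraction of screen-passing null genes with
  p < 0.05 (bounded by 0.10) and detection sensitivity (≥ 0.80).
- RER stage: 200 null and 50 accelerated (×2) genes, 2,000 sites each, full
  ML gene trees.  Sensitivity and false-positive rate are measured on the
  realistic mixture (master averaged over all genes).  Null p-value
  uniformity (Kolmogorov–Smirnov < 0.1) is measured against a master built
  from the null genes alone: with a fifth of genes accelerated, the mixture
  master's foreground branches are inflated ≈ ×1.2, pushing null genes
  toward *negative* Rho — a direction the Rho > 0 rule discards (so the
  false-positive rate is unaffected), but one that would make a uniformity
  check on the contaminated run test the contamination, not the statistic.
- Heterozygosity: 10⁶ sites, het rate 5 × 10⁻⁴, Poisson depth mean 45,
  depth cutoff 10; the estimate falls within 3 binomial standard errors.

These sizes keep the full suite within desk-scale compute while giving
binomial standard errors of a few percent on the reported rates.

## Known limitations

- The expected-count independence approximation across a branch pair
  (above) and the Poisson null's ignorance of reconstruction uncertainty
  make the convergence p-value approximate; the bound, not the nominal
  level, is what the suite asserts.
- OLS-based RERs underweight long branches relative to the weighted
  variant; with few foreground branches (4 here) the rank-sum p-value is
  discrete and cannot fall below ≈ 3 × 10⁻⁵.
- The branch-site models themselves are not fitted here; the filters
  consume a table produced by external codon-model software.
- The master tree is contaminated by truly accelerated genes when their
  fraction is large (see above); with realistic genome-wide fractions the
  effect is negligible.
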