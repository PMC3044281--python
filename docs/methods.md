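# Methods

## Data model and simulation conditions

A dataset is an n × L matrix of categorical genotypes (minor-allele counts
0/1/2) with a binary phenotype. The null generator draws one minor allele
frequency q_l ~ U[0.05, 0.5] per SNP per dataset, genotypes i.i.d. under
Hardy–Weinberg equilibrium ((1−q)², 2q(1−q), q²), and assigns exactly
round(n·case_fraction) cases by a uniformly random labeling, independent of
every genotype. Defaults are n = 2000 balanced samples, matching the
case-control designs the collapse statistic is normally used on. Balanced
fixed labeling (rather than i.i.d. Bernoulli status) keeps the high/low-risk
threshold at exactly 1 and the cross-validation folds exactly stratifiable;
the choice is configurable and has little effect on any fitted df.

Simulated SNPs are mutually independent: no linkage disequilibrium, no
population structure, no missingness, no genotyping error. Passing
null-calibration results therefore demonstrate correctness of the selection
-effect accounting, not robustness to the correlation structure of real
genotype panels — on real data with LD the screened nulls shift further and
only the permutation and split procedures remain valid. The epistasis
generator (an explicit 3^k penetrance table over target SNPs) exists to
power positive-control checks of screening and search; it makes case counts
binomial rather than fixed.

## Screening

ReliefF uses the categorical mismatch distance (per-SNP diff 0/1, summed)
with k = 10 nearest hits and misses per probe, all samples probed by
default, neighbor ties broken by ascending sample index, and weights that
are hit/miss mismatch contrasts averaged over probes; genotype diffs already
live in {0, 1}, so no range normalization is applied. TURF repeats ReliefF
on the survivors and drops the lowest-weighted 10% per round (at least one
SNP, never overshooting the target size). These parameter values follow
common ReliefF practice; the screening software the shifted-null literature
used does not document its exact settings, which is why screened-null df
values carry a systematic allowance (below) and the screening claim is
stated as an ordering, not a number.

## MDR conventions

For a k-SNP subset, the 3^k joint-genotype cells are labeled high-risk iff
cases ≥ T × controls with T the case:control ratio of the fitting data
(T = 1 when balanced). Ratio ties are labeled high; cells with no samples
are labeled low; both conventions are configurable (`collapse`). The model
statistic is the Pearson χ² of the pooled 2×2 table without continuity
correction; a collapse that pools every sample into one risk group is
reported as 0 inside simulation engines (`on_degenerate="zero"`) and raises
otherwise.

Search evaluates every k-subset under stratified 10-fold CV. Within a fold
the collapse is learned on the training samples; the fold winner is the
subset with the lowest balanced training classification error (ties to the
lexicographically first subset). Held-out samples are called cases iff their
cell is high-risk in the training collapse, with unseen cells predicting
low-risk. The returned model maximizes CV consistency (number of folds won),
breaking ties by the highest mean held-out balanced accuracy and then by
subset order; its χ² is recomputed on the full data, which is why reported
values exceed anything a single fold could produce. The across-order
champion applies the same consistency-then-accuracy rule, which reproduces
the published behavior of preferring a 10/10 four-way model over a 10/10
single-SNP model of lower CV accuracy; the original software's exact
tie-break is undocumented, so this is an explicit convention here.

The entire search is vectorized: cell indices for all C(L, k) subsets are
built once (guarded at 500 000 subsets, k ≤ 8), per-fold counts come from
offset bincounts, and training counts are full-data counts minus held-out
counts.

## Interaction logistic regression

The "full d-way interaction model" is implemented as the saturated model on
the 3^d cells — fitted case probability = cell case fraction — whose
deviance is identical to a dummy-coded logistic regression with all
interaction terms but is immune to the separation/divergence pathologies of
iterative fitting when cells are empty or single-class. Empty cells
contribute nothing to the deviance; the LRT df stays at 3^d − 1 regardless
(reducing df by empty cells is exposed as an alternative only in the sense
that the fitted empirical df captures it). The full-vs-null statistic equals
the G² of the 3^d × 2 table, verified against a direct cell-wise oracle in
the tests. Stepwise search is forward-only on this deviance with index-order
tie-breaks; forward selection is marginally blind to pure XOR patterns,
which the positive-control tests respect by planting threshold-type
epistasis. The shrunken pair statistic R′ = R − (k_l + k_m) (single-locus
Pearson χ² subtracted from the pair LRT) is included as a demonstration that
referring a left-shifted statistic to the unshrunken null is conservative.

## Null engine and df fitting

`simulate_null_distribution` derives one child seed per replicate from a
master generator (all seeds < 2³¹, logged in the result), simulates a fresh
null dataset, runs the configured pipeline, and records the statistic.
The df estimator defaults to the method of moments, df̂ = sample mean, the
only estimator under which "df equals the mean statistic" is
self-consistent; a gamma MLE with scale fixed at 2 is available and agrees
within ~2% on genuine χ² samples. Tail probabilities for non-integer df use
the gamma(df/2, scale 2) survival function. The empirical nulls after search
and screening are *approximated* by χ², not equal to one; only the fitted
df, not distributional shape, is treated as meaningful.

Problem sizes used by the shipped experiments: no-search nulls at 500
replicates of n = 2000; pair search over 20 SNPs at 500 replicates, triple
and quadruple search at 100; the split-pipeline LRT null at 100 replicates
of 2000 × 2000 (the acceptance script) or 2000 × 200 (the test suite, where
the testing-stage null is unaffected by the screened dimension); screening
-shift and calibration checks at n = 450–500 with 200 replicates. These
sizes put every fitted df within a few percent Monte-Carlo error of its
large-N value.

## Calibrated testing

The permutation test re-runs the *entire* pipeline — screening included —
on each of B phenotype permutations (B = 500 by default, the practical
200–1000 range). The default p-value is the plug-in count/B, which matches
the convention used in the published AMD permutation analysis (0.0040 =
2/500); the add-one convention (count+1)/(B+1), which never returns zero and
is strictly super-uniform, is available. A freeze-screening shortcut is
deliberately not the default: permuting only the modeling stage is
anti-conservative.

Split testing partitions the samples into three nearly equal stratified
parts (per-class shuffle, round-robin deal with the deal position carried
across classes, so 146 samples split 49/49/48): screening on D⁽¹⁾ gives A₁,
modeling on D⁽²⁾ restricted to A₁ gives the selected sets A₂, and hypothesis
tests run on D⁽³⁾ only, Bonferroni-corrected by the number of models tested.
For LR models the analytic χ²(3ᵈ−1) reference applies unchanged. For MDR the
collapse is *re-learned on D⁽³⁾* — transporting the D⁽²⁾ collapse would make
the statistic a genuine 2×2 test (df 1), but re-learning is what reproduces
the observed behavior that the testing-stage null equals the plain no-search
collapse null; that null has no analytic form, so its reference df is fitted
on the fly from freshly simulated null data matched to |D⁽³⁾| and k (200
replicates by default) or supplied by the caller. Split testing trades power
for exactness: with ~666 testing samples the 4-way LRT's 81-cell table is
sparse enough that the empirical df falls visibly below 80, and with very
small samples the procedure detects nothing — the permutation test is the
better tool there.

## Known limitations

* The no-search collapse-null df values this package computes (~4.0–4.2,
  ~10.5–10.8, ~26–27 for k = 2, 3, 4 at n = 2000) are reproducible across
  sample sizes, tie conventions, and df estimators, but sit 6–18% below the
  values historically reported from the closed-source GUI implementation
  whose internal conventions are undocumented; the search-stage and
  split-stage values agree closely. Users comparing against legacy outputs
  should calibrate with this package's own null engine, which is the point
  of the design.
* SURF/SURF*-family screeners, LD-aware simulation, covariates,
  missing-genotype handling, and FDR control beyond Bonferroni are out of
  scope.
* TURF re-runs ReliefF each round; with the default 10% removal schedule on
  thousands of SNPs this is quadratic-ish and noticeably slower than plain
  ReliefF.
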