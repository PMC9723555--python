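# Methods

## Problem setting

Amplicon profiling of the 16S rRNA gene yields a taxa-by-samples count
table whose low-abundance tail mixes genuine rare organisms with
artifacts: cross-sample contamination within a sequencing run (index
hopping, reagent DNA), and sequencing-error variants of abundant true
taxa. `spuritax` treats a *defined reference community* — a mock mixture
or a gnotobiotic consortium whose member sequences are known — as ground
truth: any observed taxon that does not match a member is *spurious*.
The package quantifies how filtering strategies trade spurious-taxon
removal against loss of true members, and how that choice propagates into
alpha- and beta-diversity.

## Filtering model

Two strategies operate on a count table with entries `n_ij` and
per-sample proportions `p_ij`:

* **singleton removal** drops taxa with `Σ_j n_ij = 1` (a raw-count
  concept; non-integer tables are rejected);
* **relative-abundance filtering** keeps taxon *i* iff `p_ij > t` for at
  least one sample *j*. The threshold is evaluated on the *unfiltered*
  table and retained rows keep their raw counts; downstream steps
  re-normalize as needed.

The inequality is strict and exact ties at the cutoff are removed. This
is a deliberate convention: it makes the filter, the EMR statistic
(below) and the "rescale to 1000 reads, drop below 2.5 counts"
formulation mutually consistent; whether reference pipelines treat the
boundary as `>` or `≥` is generally unstated, and the difference only
matters on exact-tie proportions.

Normalization is offered in two flavors because both are in common use:
deterministic scaling of every sample to the minimum sample sum (exactly
proportion-preserving) and seeded without-replacement rarefaction
(multivariate hypergeometric per sample). The CLI requires an explicit
choice.

## Matching model

Observed representative sequences are classified against the reference
members by semi-global alignment (match +1, mismatch −1, gap −2, free end
gaps on both sequences). Identity is matches / alignment columns within
the mutual overlap; coverage is the fraction of the query inside the
overlap. A positive hit requires identity ≥ 0.97 and coverage ≥ 0.90.
E-values are deliberately not computed: they depend on database size and
carry no information against a closed set of a few reference sequences.

Numerical conventions worth knowing:

* best hits are ranked by identity × coverage, then identity, coverage
  and lexicographic member id. Ranking by identity alone is unsafe with
  overlap alignments, where a degenerate few-column alignment against the
  wrong reference can reach identity 1.0 at near-zero coverage;
* the dynamic program cannot place an insertion column next to a deletion
  column, so when query and reference both have leftover tails on the
  same side the tails align residue-to-residue and are charged to
  identity; coverage < 1 arises when the query overhangs past a reference
  end;
* `N` bases count as mismatches (conservative); ambiguity codes beyond
  `N` are rejected at parse time.

For denoised sequence variants a Hamming criterion is provided instead:
matched iff the minimum Hamming distance to an equal-length reference is
≤ 1; length mismatches count as distance infinity.

Greedy centroid clustering at 97% identity (`collapse_redundant`)
de-replicates spurious sequences across runs: sequences are processed in
decreasing length order and join the earliest centroid reached at
≥ 97% identity and ≥ 90% coverage.

## Benchmark statistics

Per sample, over taxa with nonzero count after filtering: the spurious
fraction (spurious / retained), the positive-hit fraction (distinct
reference members hit by ≥ 1 matched taxon, over the member count — so
satellite taxa cannot push it above 100%; a separate multiplicity column
reports matched-taxa-per-member), the cumulative spurious relative
abundance (on unfiltered proportions) and the first-spurious abundance
(the largest unfiltered proportion among spurious taxa, i.e. the
abundance at which the first spurious taxon appears when scanning taxa in
decreasing abundance). First-spurious abundances are computed per
replicate and aggregated as mean ± SD. The threshold sweep evaluates the
relative-abundance filter on a grid (default 0–0.5% in 0.05% steps, 11
points) and reports means and SDs across datasets.

The spurious fraction is *not* mathematically monotone in the threshold:
its denominator (retained taxa) shrinks too, so removing true members
inside the filtered band can raise the ratio. On even mock profiles,
where all members sit far above the sweep range, monotonicity is
structural; on log-distributed profiles it can fail at individual
thresholds. The positive-hit fraction is always non-increasing (nested
filters, fixed denominator).

## Alpha-diversity

Richness counts nonzero taxa. Effective microbial richness,
`EMR = #{i : p_ij > t}` with `t` = 0.25% by default, is invariant to
rescaling a sample and hence to sequencing depth and normalization; it
equals the taxon count after rescaling to 1000 reads and removing taxa
below 2.5 counts (ties removed, matching the strict filter inequality).
The Shannon effective count is `exp(H)` with natural-log entropy — the
base is a convention choice (common R-based amplicon toolkits use `e`),
documented here because some references use base 2.

IQRs use linear-interpolation ("type 7") quantiles, the default of both
numpy and R, for cross-platform reproducibility. CVs use the n−1 sample
standard deviation, in percent of the mean. Within-run CVs are computed
over the replicates of a group inside one run; across-run CVs over the
per-run replicate means of a group (the comparison of "the same sample
re-sequenced in different runs"). Pooling replicates instead of averaging
per run is possible by calling `richness_cv` directly on any grouping.

## Beta-diversity

Both UniFrac variants are computed from per-branch descendant masses: for
every non-root branch *b* with length `L_b`, `p_X(b)` is the fraction of
sample X's reads descending from *b*. Unweighted UniFrac is the unique /
union covered branch length on presence of descendants; generalized
UniFrac weights branches by `(p_A+p_B)^α`, with α = 0.5 the usual
compromise and α = 1 equal to weighted-normalized UniFrac. Branches with
no reads from either sample are skipped; two all-zero samples are an
error.

Rooting caveat: a branch above the LCA of all observed taxa has
`p_A = p_B = 1`, which contributes zero to the numerators but *does*
enter both denominators (union length; `L·2^α`). Distances therefore do
depend on a nonzero root-stem length. Synthetic trees generated here
carry no root stem; for user trees the convention follows the standard
formulas rather than attempting root-invariance.

Per-subject summaries use the median of all within-subject pairwise
distances by default; a consecutive-timepoints option exists because
longitudinal studies sometimes prefer adjacent pairs.

## Exclusivity of contaminants

Prevalence of a spurious taxon in a sample category is the percentage of
that category's samples in which it exceeds the abundance threshold
(default 0.25%). Samples with no hit to any spurious taxon are excluded
from denominators by default — in heterogeneous collections an absence is
indistinguishable from a primer/region mismatch — and a flag disables
this. Exclusivity for the top-prevalence category is tested with a pooled
two-proportion z-test against the runner-up category, two-sided, with
Benjamini–Hochberg adjustment across all tested taxa (α = 0.05). No
continuity correction is applied; the intended regime is large per-
category sample counts. Testing top-vs-runner-up (rather than top vs all
others pooled) is a design choice: it is the most conservative pairwise
contrast for claiming exclusivity.

## Synthetic-data generator

The generator emulates reference-community sequencing experiments and is
itself first-class, tested code. Per design:

* **reference community** — `n_true_taxa` members (default 8) with
  mutually dissimilar random 250-nt sequences (no pair aligns at ≥ 90%
  identity over ≥ 90% coverage) and an even profile by default;
  log-distributed (successive 10-fold dilutions, renormalized) and
  exponential rank-abundance (`∝ r^k`) profiles model the two common mock
  standards and gut-like communities respectively;
* **sequencing depth** — truncated normal, mean 25 000, SD 7 000, floor
  1 000 reads (the scale of typical MiSeq mock runs);
* **contaminants** — each run has a pool of 32 contaminant sequences,
  occasionally shared between runs (overlap probability 0.1, so most
  contaminants are run-specific); each pool member is present in a given
  sample with a probability calibrated so the expected cumulative
  spurious abundance equals 1%; individual abundances are log-uniform on
  [0.01%, 0.2%] — strictly below the 0.25% consensus cutoff. A `hard_case`
  preset raises the ceiling to 0.44% to reproduce the outlier regime in
  which the cutoff no longer removes everything. Note that a contaminant
  injected near 0.2% can still *realize* > 0.25% in one sample through
  multinomial noise at these depths; tests distinguish the guaranteed
  mechanism from such borderline events;
* **satellites** — Poisson(0.5) per member, 1–3 substitutions from the
  parent sequence, log-uniform abundance on [0.005%, 0.15%]. With ≤ 3
  substitutions on 250 nt they remain within the 97% identity criterion
  and are counted as matched (they inflate positive-hit multiplicity, not
  the spurious fraction); under the Hamming-1 criterion those with ≥ 2
  substitutions are spurious;
* **singleton artifacts** — Poisson(5) per sample, each a new unique
  random sequence with total count exactly 1;
* **tree** — a random bifurcating topology over all observed taxa with
  exponential(0.1) branch lengths and no root stem.

Every draw derives from one master seed via `numpy.random.SeedSequence`
spawn keys (one stream per structural element, one per
run × group × replicate), so outputs are bit-reproducible and adding
samples or runs never perturbs previously generated data. A multi-run
study returns a single merged count table over the union taxon space plus
metadata; per-run tables are column subsets. Taxa never realized in any
sample are dropped from all outputs.

What the generator does **not** model — and hence what passing tests do
not show about real data: chimeras and PCR errors beyond substitutions,
compositional correlations between taxa, primer/region effects, quality
scores or read-level structure, taxonomy, and the long ecological tails
of real communities. Contaminant abundances are independent across taxa,
which understates the burstiness of real index hopping.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use deliberately compact study
designs — e.g. triplicate mocks, multi-run studies of 2–3 groups × 3
replicates × 3–5 runs with 25 true taxa, 100-study ensembles for
directional claims, and 500 k-read depth series — sizes at which every
statistical expectation used in an assertion is comfortably resolved.
Exhaustive UniFrac validation runs over all 13 unlabeled rooted
bifurcating tree shapes with 2–6 leaves and all presence-set pairs, with
the generalized variant cross-checked against an independently coded
weighted-normalized oracle at α = 1.

## Known limitations

* Alignment identity/coverage conventions are explicit but not identical
  to BLAST's; absolute identity values can differ by a column or two when
  the optimum includes compensating gaps.
* The exclusivity z-test assumes independent samples within categories;
  repeated measures of the same subject violate this.
* EMR's depth-invariance is exact for the statistic, but at shallow depth
  the *estimate* of `p_ij` near the cutoff is noisy; taxa within ~20% of
  the cutoff can flip across it between resamplings.
* The spurious-fraction-vs-threshold curve is only guaranteed monotone
  for communities whose true members all lie above the swept range.
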