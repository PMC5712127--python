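# Methods

This note documents the models and procedures implemented in `spermevol`,
the choices made where conventions differ, and what the synthetic-data
generator does and does not emulate.

## Confident-proteome construction (`spermevol.evidence`)

Identification evidence arrives per (protein, replicate) with a unique
peptide count, an uncorrected spectral count, and a protein-level
identification probability from an upstream validation model. Two
thresholds are configurable and applied in sequence:

* `min_protein_prob` (default 0.99): rows are kept when the probability
  **strictly exceeds** the threshold. The companion peptide-level 95%
  threshold belongs to upstream search validation and is not re-applied
  here.
* Inclusion: a protein enters the confident proteome when detected in
  ≥ 2 replicates, or by ≥ 2 unique peptides **within one replicate**
  (the multi-peptide rule is deliberately not pooled across replicates —
  pooling would admit proteins supported by one weak peptide per run).

The filter is monotone: more evidence can only add inclusions.

**Parsimony grouping.** Proteins with identical peptide sets cannot be
distinguished and are merged into one group, represented by the
lexicographically smallest id. A protein whose peptide set is a strict
subset of another's adds no explanatory power and is *subsumed* into the
group of its largest superset (ties broken by representative id);
subsumed proteins remain in the output flagged `subsumed`, preserving
traceability rather than deleting records. For families built from
equality, nesting and disjointness the number of resulting groups equals
the exhaustive minimum-explanation set size (property-tested against a
brute-force cover search). With *partial* overlaps a smaller cover can
exist — e.g. {a,b}, {b,c}, {a,c} admits a 2-protein cover but forms
3 groups; subsumption grouping intentionally keeps all three, since
neither set contains another and collapsing them would discard
distinguishable evidence.

## Abundance estimation and comparison (`spermevol.abundance`)

Relative abundance uses the APEX form: spectral counts are corrected by
per-protein detection probabilities `O_i ∈ (0,1]` and normalized,
`a_i = C·(n_i/O_i)/Σ_k(n_k/O_k)`. The machine-learning step that produces
`O_i` from physicochemical properties is upstream; `O_i` is an input, and
`O_i = 1` recovers plain normalized spectral counting. The estimator is
scale-invariant in counts and conserves `Σ a_i = C` to 1e-9 relative
tolerance (both property-tested).

Cross-species comparison total-sum normalizes each profile, drops pairs
with a zero abundance on either side (no pseudocount — a pseudocount
would bend the low-abundance tail; the number dropped is reported),
log10-transforms, and fits OLS over ortholog pairs (one-to-one pairs by
default). A constant regressor or response returns slope 0, R² 0 by
convention. Quantile normalization was rejected to keep the estimator
transparent.

Differential-abundance *calls* come from an upstream count model (a
negative-binomial fit with BH correction); only the direction-bias test
is computed here: with `n_sig` significant calls of which `k_up` are up
in the focal species, the one-tail p is `P(X ≥ max(k_up, n_sig−k_up))`
for `X ~ Binomial(n_sig, ½)`, exact and symmetric under sign flips.

## Orthology conservation (`spermevol.orthology`)

The 2×2 overlap chi-square uses the Yates continuity correction
`Σ max(|O−E|−½, 0)²/E` with 1 df (the correction clamps at zero, so a
homogeneous table scores exactly 0); it reproduces the reported 25.55 on
the published overlap counts and matches `scipy.stats.chi2_contingency`
on random tables.

The resampling null draws, per iteration, a gene set the size of the
focal subset **without replacement** from the pool and records its
ortholog proportion for one species. Conventions:

* Pool default is the non-focal genes; `pool="all_genes"` instead
  samples from the whole genome including the focal subset. Both
  conventions appear in the literature for this kind of null; non-focal
  is the default so the focal set's own composition does not contribute
  to its null distribution.
* Empirical p-values use add-one smoothing `(count+1)/(n_iter+1)` per
  tail, doubled and capped at 1 for the two-sided value — never exactly 0,
  floor `1/(n_iter+1)`.
* `direction` is `deficit`/`excess` only when the two-sided p clears
  `alpha` (default 0.05), else `none`.
* Multi-species reports derive one child stream per species from a master
  seed (`numpy` `SeedSequence.spawn`), so per-species results are stable
  under changes to the species list tail. Identical seeds give bitwise
  identical null vectors.

Two structural facts about this empirical p under a true null, found
while validating calibration and worth knowing when choosing designs:
the discrete proportion grid puts tie mass at the observed value in both
tails (conservative, shrinking as subset size grows), and all null draws
share one realized pool, making them mutually correlated with strength
≈ subset/pool (anti-conservative as that ratio grows). Calibration is
therefore checked — and holds — in the regime the method is meant for:
a focal subset that is a small fraction of the genome, with thousands of
iterations.

## Phylostratigraphy (`spermevol.phylostrat`)

Hits are thresholded at `e < 1e-5` (strict) and query coverage ≥ 0.5,
with OR semantics over multiple HSPs; coverage is the HSP's span on the
query divided by query length, per HSP (no HSP stitching — stitching
rules are not standardized and would manufacture coverage). Relaxing
either threshold can only add hits (property-tested).

Classification against a strictly nested schema (every stratum contains
all inner strata plus the focal species):

* no non-focal hits → `focal_specific`;
* hits in every surveyed species → `conserved_all` (literally all
  surveyed species, not merely the outermost stratum);
* otherwise the candidate stratum is the innermost one containing all
  hits; the label is assigned only if the pattern is *continuous* —
  every ring (stratum minus inner stratum) from the innermost ring out
  to the candidate carries ≥ 1 hit — and the stratum's evidence rule
  holds. Continuity is anchored at the focal species, since the query
  protein exists there by definition: a protein hitting only a dipteran,
  with nothing in Lepidoptera, is discontinuous and `unresolved`.
* any continuity or rule failure → `unresolved`.

The shipped five-ring insect schema requires, for a Lepidoptera-specific
call, ≥ 1 non-focal butterfly **and** ≥ 1 moth; other strata default to
the ≥ 1-hit-in-own-ring rule that continuity already enforces. Rules and
schema are data (a flat text file), not code, so other clade designs are
usable. Summary percentages are reported to one decimal (round-half-even)
alongside raw fractions, since one-decimal rounding is lossy.

Absence of detectable homology cannot be distinguished from homology
eroded beyond recognition by rapid divergence; the classifier inherits
that caveat of all BLAST-based phylostratigraphy rather than solving it.

## Divergence statistics (`spermevol.divergence`)

dN/dS estimates come from an upstream maximum-likelihood codon-model fit
and are consumed as a table. The two-sample KS statistic evaluates both
ECDFs at every pooled sample point (correct under ties) and takes the
supremum difference; the p-value uses the asymptotic Kolmogorov
distribution at effective size `n_x·n_y/(n_x+n_y)` — appropriate at the
group sizes involved (hundreds to thousands) — with an exact small-sample
option for verification. D is property-tested against a brute-force
double-loop oracle on small tie-rich samples.

"Outliers exceeding twice the interquartile range" is read as Tukey-style
fencing above `Q3 + 2·IQR` (the location-free alternative `dN > 2·IQR`
ignores the distribution's position and was rejected); the multiplier is
configurable. Quantiles interpolate linearly between order statistics —
stated explicitly because the top-5% boundary depends on the convention.
Rapid evolvers are kept genes with `dN ≥` the 0.95 quantile of kept
values (inclusive, so boundary ties are all flagged; the flag count is
`⌈0.05·n_kept⌉` up to ties). The fence and threshold are computed
genome-wide over the full table, sperm genes included.

Synonymous saturation is flagged when median dS ≥ 3 or ≥ half the genes
exceed 3 (a conventional saturation point; the flag only gates a warning
and the dN-only comparison mode).

## Synthetic data (`spermevol.simulate`)

The generator emulates the statistical structure the analyses assume, at
the study's magnitudes (defaults: 15,000 genes, 584 sperm proteins, 3
replicates, 12 ortholog species, 5000 resampling iterations, stratum
mixture 45/25/140/15/15/173/171 across focal-specific, the four
restricted strata, conserved-in-all and unresolved):

* **Abundance / MS observation.** True log abundances of the focal and a
  second species are bivariate normal with correlation `abundance_corr`
  (default 0.65) and log-sd 1.5. The merged-experiment spectral count is
  Poisson with mean proportional to abundance × detection probability
  (`O_i ~ Beta(6,2)`), so the APEX correction `n_i/O_i` recovers the
  abundance share; counts are split multinomially across replicates.
  The merged depth defaults to 37,000 spectra — about 21 spectra per
  protein per replicate, a typical identification depth for this kind of
  experiment — at which counting noise attenuates the recoverable
  cross-species R² by ≈ 0.05 below ρ². Replicate identification requires spectra in that
  replicate *and* a logistic search-success draw in standardized log
  abundance (intercept 2.2, slope 1.3), giving the inclusion filter
  realistic abundance-dependent replicate structure. Decoy
  identifications (low probability, or single-replicate single-peptide)
  exercise the confidence and inclusion cuts.
* **Peptide incidence** plants identical-set pairs and strict-subset
  pairs so parsimony grouping is exercised.
* **Orthology.** Per-species Bernoulli ortholog flags at separate rates
  for sperm and background genes (defaults plant a deficit outside
  Lepidoptera: 0.45 vs 0.60; none within: 0.70 vs 0.70).
* **Homology hits.** Each sperm protein receives a hit set constructed to
  classify exactly as its planted category (every ring up to the planted
  stratum occupied; `conserved_all` hits all species; `unresolved` uses
  guaranteed-discontinuous templates). Passing records draw
  `e ∈ 10^[−150,−6]`, coverage ∈ [0.5,1]; failing records straddle both
  thresholds so the cuts are non-vacuous. `discontinuity_rate` (default
  0.05) corrupts a fraction of restricted patterns into discontinuity —
  at 0 the classifier recovers every planted label exactly.
* **Divergence.** Group-wise lognormal dN (Lepidoptera-specific sperm
  fastest, conserved sperm slowest, background between); dS lognormal
  around a saturated regime by default. Focal-specific and unresolved
  sperm proteins are excluded from the three-group table, since they
  belong to neither "Lepidoptera-specific" nor "homology outside
  Lepidoptera" and real ortholog alignments would not exist for them.
* **Differential calls** plant a configurable significant fraction (7%)
  with fair random direction, so the direction-bias test is calibrated.

One master seed spawns named substreams (design, evidence, abundance,
orthology, hits, divergence, differential): changing one block's
parameters does not perturb the draws of another, and identical seed +
config gives a bitwise-identical bundle.

**What the generator does not emulate:** spectra, sequences or
alignments; search-engine score distributions; correlated ortholog loss
across related species; gene-family structure (paralogy); compositional
coupling between abundance and evolutionary rate. Passing tests
demonstrate that the *procedures* behave correctly under the planted
statistical structure — they do not certify performance on real data
whose violations of these assumptions (e.g. non-Poisson overdispersion of
spectral counts, phylogenetically correlated homology failure) are the
interesting part.

## Problem sizes and numerical conventions in the checks

The acceptance checks run at: 500 calibration replicates (2000 focal
genes of 50,000, 2000 iterations each — a regime chosen so the empirical
p's discreteness is far finer than the KS detection radius at n = 500),
20-seed power runs at the planted 0.2-vs-0.8 deficit (subset 50 of 200,
2000 iterations), classifier recovery at 1000 proteins, 1000 random KS
oracle instances of size ≤ 20, and 20-seed R² recovery at 400 ortholog
pairs where the Monte-Carlo mean is compared against ρ² (per-seed R² has
sampling sd ≈ 0.04 at n = 400). Empirical p-values never report 0; KS
p-values are clipped to (0,1]; percentage reporting rounds half-even to
one decimal with raw fractions alongside.
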