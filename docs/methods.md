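# Methods

## Scope and assumptions

`wamecfix` begins where assembly and annotation end: its inputs are a
non-redundant unigene catalog (lengths, ranked taxonomy, KO/Pfam
annotations), a raw count matrix, and a sample table with RNA yields and
environmental covariates. Transcript abundance is treated as a proxy for
the *potential* activity of the encoded function; the package makes no
claim about absolute carbon-fixation rates, and the mapping from transcript
pool to realized flux is assumed only to be monotone within a lineage.
Each unigene is assumed to map to exactly one lineage (single taxonomic
assignment), which is what makes the contribution partition exact: summed
per-lineage activities equal the whole-community activity at every rank.

## Quantification

**TPM.** Per library, `rate_i = count_i/(length_i/1000)` and
`TPM_i = 1e6·rate_i/Σrate`. Columns sum to 1e6 (relative tolerance 1e-6 in
the tests). An all-zero library is an error, named for the offending
library.

**Low-expression filter.** A unigene is excluded only if its TPM is below
0.1 in *every* library; a single library at or above threshold retains it.
Survivors are deliberately not re-scaled, so post-filter column sums fall
short of 1e6 by exactly the removed mass — keeping all retained values on
the original per-million scale.

**Within-taxon re-normalization.** For comparisons of a taxon's gene
expression across samples, the taxon's unigenes are re-scaled to sum to 1e6
within each library, removing the taxon's overall abundance from the
contrast. Libraries where the taxon is absent are NaN, never zero: a
missing denominator is not evidence of zero expression.

**CCF activity** of a lineage is the summed TPM of its unigenes annotated
to any RuBisCO marker KO (default `{K01601, K01602}`, the large/small
subunits; user-overridable). A unigene carrying both markers counts once.

**NCF activity** is the summed TPM over unigenes annotated to any KO of the
five NCF pathways, divided by the number of *defined* distinct KOs in the
union. Dividing by the defined rather than the detected gene count was a
genuinely open choice; the defined denominator makes the statistic monotone
in expression (absence counts as zero rather than shrinking the
denominator) and comparable across lineages. The detected-gene variant is
available (`denominator="detected"`). Pathway KO membership follows the
KEGG carbon-fixation map and is fully user-editable; none of the machinery
depends on the specific lists.

**Completeness rule.** An order qualifies as NCF-active if it expresses at
least 15 distinct NCF KOs (boundary inclusive) in at least one library.
The threshold and the any-library criterion are parameters; a
union-over-libraries reading differs only for lineages whose expressed gene
sets are highly library-specific.

**Replicate aggregation** is the arithmetic mean of replicate values per
condition (station × layer × fraction). Per-library tables remain available;
nothing downstream requires the aggregated form.

## Size-fraction calibration

Each fraction's per-condition values are weighted by its share of the RNA
recovered per litre: `w_s = R_s/(R_s+R_l)`, whole-assemblage value
`= w_s·v_s + w_l·v_l`. Yield units cancel; replicate extractions are
averaged per condition. Zero yields are rejected unless explicitly allowed
(degenerate single-fraction case). If both fractions carry the same value
`v`, the pooled value is `v` — the conservation identity the tests enforce.

## Association statistics

* **Occupancy filter:** correlations use only genes expressed (TPM > 0) in
  at least 6 libraries (of 20 in the reference design), boundary inclusive.
* **Gene–gene correlation:** Pearson `r` with two-sided p (scipy), on
  taxon-normalized TPM aggregated per KO (summing unigenes annotated to the
  KO). No log transform by default and no multiple-testing correction by
  default, for comparability with how such matrices are usually read;
  Benjamini–Hochberg is a flag. Zero-variance vectors give NaN pairs;
  fewer than 3 paired observations is an error.
* **Rhodopsin–NCF regression:** OLS of an order's NCF activity on its
  rhodopsin (PF01036) expression, by default on the log2(value+1) scale on
  which such couplings are linear in practice; raw scale is a flag.
* **Mantel test:** Bray–Curtis distances between per-condition
  lineage-contribution profiles versus Euclidean distances of one z-scored
  environmental variable; the statistic is the Pearson correlation of the
  off-diagonal entries; `p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm)`,
  one-sided greater, 999 permutations, seeded generator. All four choices
  (metrics, correlation flavor, count, sidedness) are parameters, since any
  of them could legitimately be made differently. Significance classes are
  `p < 0.01`, `0.01 ≤ p < 0.05`, else not significant. The Mantel statistic
  is implemented in-package (the permutation stream must be seedable);
  tests cross-check it against scikit-bio and against a brute-force
  enumeration oracle.

## The synthetic-data generator

The generator emulates the reference field design: a shelf station with
surface and deep-chlorophyll-maximum layers plus a slope station with an
additional bottom-of-photic-zone layer (five water masses), two size
fractions and two replicates — 20 libraries at default settings — with
environmental gradients (temperature, salinity, depth, nitrate+nitrite,
phosphate, silicate, PAR) following linear layer trends.

* **Catalog:** each programmed lineage contributes background unigenes
  (default 50, no annotations) and one unigene per gene of each pathway it
  participates in. Lengths are lognormal (σ = 0.35 log-scale) around the
  lineage mean (default 1000 bp eukaryotes, 900 bp bacteria) with a 200 bp
  assembly floor.
* **Expected expression:** each pathway receives an expected read budget
  `library_depth × pool_fraction` (default 2% per pathway), jittered
  lognormally per (pathway, condition, fraction) with CV 0.5 to create
  between-condition biological variability. Within a pathway, expected
  *length-normalized rates* are allocated to lineages exactly in the
  programmed shares, so a programmed share is exactly the lineage's
  expected share of the pathway's TPM pool regardless of gene lengths.
  Background unigenes carry lognormal relative abundances (σ = 1.0) fixed
  across conditions.
* **Count noise:** negative binomial via library-level gamma mixing — a
  shared `Gamma(1/a, a)` factor per library times per-gene Poisson
  sampling. Marginally each gene is NB with dispersion `a` (default 0.1;
  `Var = μ + aμ²`; `a = 0` is Poisson), while the within-library relative
  composition — which is all TPM can see — retains binomial-scale sampling
  error. This locates the overdispersion in library-wide effects
  (extraction, depth, efficiency), consistent with deriving share-recovery
  error from binomial sampling; gene-level biological heterogeneity is
  carried by the static abundance profile instead. A mild lognormal
  replicate multiplier (CV 10%) is layered per library and cancels in TPM.
* **Rhodopsin coupling:** for each coupled order, rhodopsin expression is
  drawn from a linear model on the order's *realized* NCF expression,
  log2(TPM+1) scale, with residual SD set from the realized predictor
  variance so the population R² equals `rhodopsin_coupling_r2` (default
  0.8, mid-range of plausible couplings; `r² = 0` sets the slope to zero).
  Rhodopsin counts are the deterministic discretisation of that draw: the
  count-level sampling noise of the coupled gene is subsumed in the model
  residual, so the programmed R² is the R² of what the pipeline measures.
  Programming it through an additional independent count-noise layer would
  systematically attenuate the recovered R² below its nominal value.
* **Determinism:** one seeded generator drives everything in a fixed
  iteration order; identical configuration and seed reproduce the dataset
  exactly. If the depth cannot represent the rarest programmed share
  (expected count < 1), a warning is recorded in the ground truth and the
  run manifest.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chimeric or fragmented assemblies, annotation
error and multi-lineage ambiguity, within-lineage taxonomic structure below
the order, compositional coupling between pathways beyond the shared
library total, filtration artifacts (free-living cells retained on the
large-fraction filter), and any nonlinearity between transcript pool and
realized fixation rate.

## Problem sizes

The test and acceptance runs use desk-scale designs chosen so that sampling
error is far inside each tolerance: share recovery at library depth 1e6
(binomial share error ≈ 0.25 percentage points against a 1-point
tolerance), the rare-share case at depth 1e7 with a 5% pathway pool
(expected marker counts ≈ 2000, error ≈ 0.003 points against 0.02), and
R² recovery over 20 seeds × 500 conditions (Monte-Carlo SE of the mean
≈ 0.002 against ±0.03). The Mantel null calibration uses 200 independent
8-condition datasets at 999 permutations, with the exact binomial 95% band
around the nominal 5% rejection rate.

## Known limitations

* Supergroup labels are produced by an editable phylum→supergroup map; the
  shipped map covers common marine groups and falls back to the phylum name,
  so unmapped phyla appear as their own supergroup.
* The shipped KO lists (NCF pathways, photosynthesis/endocytosis cores) are
  reasonable KEGG-derived defaults, not a curated authority; analyses that
  depend on exact membership should supply their own lists.
* Mantel tests are run per environmental variable without multiplicity
  adjustment, mirroring common practice in community ecology; interpret
  families of tests accordingly.
* `ContributionTable` percentages are compositional; their distances
  (Bray–Curtis) treat the profile as relative abundance, and no
  log-ratio machinery is provided.
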