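# wamecfix

Lineage-resolved carbon-fixation profiling of whole-assemblage plankton
metatranscriptomes.

## The problem

Whole-assemblage metatranscriptomics (WAME) sequences the rRNA-depleted RNA
of an entire plankton community — eukaryotic phytoplankton and prokaryotes in
one experiment — so that every expressed transcript can be traced back both
to a function and to a source lineage. `wamecfix` turns an annotated unigene
catalog and a raw count matrix into lineage-resolved answers to four
questions about marine carbon fixation:

1. **Who carries the Calvin carbon-fixation (CCF) transcript pool?**
   CCF activity of a lineage is proxied by the summed TPM of its
   RuBisCO-annotated unigenes (KO `K01601`/`K01602` by default); the pool is
   partitioned into per-lineage percentage contributions.
2. **Who performs non-Calvin carbon fixation (NCF)?** NCF activity is the
   mean TPM per gene over the five recognized NCF pathways (reductive citric
   acid cycle, Wood–Ljungdahl, 3-hydroxypropionate bicycle,
   hydroxypropionate–hydroxybutyrate cycle, dicarboxylate–hydroxybutyrate
   cycle), with a completeness rule that an order must express at least 15
   distinct pathway genes to count as an NCF lineage.
3. **How do the separately sequenced size fractions combine?** The 0.2–3 µm
   and 3–200 µm fractions are merged by RNA-yield weighting:
   `TPM_small × RNA_small/(RNA_small + RNA_large)` plus the analogous large
   term, giving whole-assemblage values and per-fraction shares.
4. **What couples to what?** Pearson matrices between core photosynthesis
   and core endocytosis genes within a lineage (a transcriptional proxy for
   mixotrophy), OLS regressions of NCF activity on proton-pump-rhodopsin
   (Pfam `PF01036`) expression within bacterial orders, and Mantel tests
   (Bray–Curtis × Euclidean, permutation p) between lineage contributions
   and environmental factors.

Because real WAME datasets are enormous, the package ships a first-class
synthetic-data generator that emulates the field design (two stations, five
water masses, two size fractions, two replicates = 20 libraries) with
programmable ground truth: lineage shares of each pathway's transcript pool,
negative-binomial count noise, RNA yields, a rhodopsin–NCF coupling of
chosen population R², and environment variables tied to lineage activities.
Every downstream statistic can therefore be tested against known truth.

## Core quantities

For unigene *i* with length *L<sub>i</sub>* (bp) and count *c<sub>i</sub>*
in a library:

```
rate_i = c_i / (L_i / 1000)          TPM_i = 1e6 · rate_i / Σ_j rate_j
```

Unigenes with TPM < 0.1 in **every** library are excluded (no
re-normalization). Within-taxon comparisons re-normalize the taxon's
unigenes to a million ("per million mapped reads of the taxonomic group").
A lineage's contribution to a pathway pool is
`100 · activity(lineage) / Σ activity`, which sums to 100 per condition by
construction.

## Worked example

```python
import wamecfix as w
from wamecfix.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(seed=42, library_depth=500_000)
catalog, counts, samples, truth = simulate_dataset(cfg)

pathways = w.load_default_pathways()
tpm = w.compute_tpm(counts, catalog)
tpm_f, n_dropped = w.filter_low_expression(tpm, 0.1)

act = w.ccf_activity(tpm_f, catalog, pathways, rank="supergroup", samples=samples)
print(w.relative_contribution(act).values[["shelf_DCM_small", "slope_SUR_small"]].round(2))

ncf = w.ncf_activity(tpm_f, catalog, pathways, rank="order", samples=samples)
rho = w.rhodopsin_activity(tpm_f, catalog, pathways, rank="order", samples=samples)
res = w.ppr_ncf_regression(ncf.values.loc["Flavobacteriales"],
                           rho.values.loc["Flavobacteriales"])
print(f"R^2={res.r_squared:.3f}, slope={res.slope:.2f}, p={res.p_value:.2e}")
```

prints

```
                 shelf_DCM_small  slope_SUR_small
supergroup
Bacillariophyta            26.22            25.87
Chlorophyta                 9.91            10.13
Cyanobacteria              14.65            15.24
Dinophyta                  13.79            14.24
Haptophyta                 15.09            14.83
O_Stramenopiles            20.33            19.69
R^2=0.918, slope=0.97, p=1.28e-05
```

The contribution table recovers the generator's programmed CCF shares (25%,
10%, 15%, 15%, 15%, 20%) to within count-sampling error, per water mass and
size fraction; the regression recovers the programmed rhodopsin–NCF
coupling (population R² 0.8 by default; here estimated from the 10
replicate-averaged conditions).

The same analyses are available from the shell:

```bash
wamecfix simulate --seed 42 --outdir sim/
wamecfix contrib --catalog sim/catalog.tsv --counts sim/counts.tsv \
    --samples sim/samples.tsv --pathway ccf --rank supergroup --out contrib.tsv
wamecfix run-all --config run.json --seed 42 --outdir out/
```

`run-all` writes every table plus a `manifest.json` recording the
configuration, seeds, filter counts and warnings.

## Layout

| module | contents |
| --- | --- |
| `wamecfix.io` | typed tables (catalog, samples, pathway sets), TSV/JSON IO, validation |
| `wamecfix.simulate` | the synthetic-data generator and ground-truth bookkeeping |
| `wamecfix.quantify` | TPM, filters, taxon re-normalization, activities, contributions |
| `wamecfix.calibrate` | RNA-yield size-fraction integration |
| `wamecfix.associate` | occupancy filter, correlation matrices, OLS, Mantel tests |
| `wamecfix.pipeline` / `wamecfix.cli` | `run-all` driver, manifest, `wamecfix` command |

See `docs/methods.md` for the modelling choices and their rationale.
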