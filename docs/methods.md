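# Methods

## Model and assumptions

The package analyses a single family under a **dominant, single-locus**
model: one heterozygous alternate allele suffices for predisposition, so
the carrier predicate for individual *i* at biallelic variant *v* (alt
allele *a*) is `a ∈ g(i)` with `g(i)` the *unordered* genotype — phase is
never used, and a homozygous-alternate genotype counts as a carrier.
Coordinates are GRCh37, 1-based; there is no liftover. X-chromosome
genotypes are treated as printed allele pairs with no hemizygote
special-casing, matching how validation genotypes are reported in the
source tables.

All filters are **pointwise predicates per variant**. Two consequences are
used as test invariants: the discovery cascade's final shortlist equals
the conjunction of its four predicates regardless of stage order (only the
per-stage ledger depends on order), and the segregation filter's retained
set is invariant under permutations of the carrier order (only the
first-failing-carrier attribution changes).

### Filter semantics worth stating exactly

- **Frequency**: "MAF > 20 %" is a *strict* inequality; a variant at
  exactly the threshold is kept. A variant with no panel frequency is
  novel and kept. Rationale: several true candidates in the worked example
  have empty 1000 Genomes cells.
- **Functional**: the kept set defaults to the exonic protein-altering
  classes (missense, stop-gain, in-frame and frameshift deletion, plus the
  catch-all `other`, which covers insertions for which no dedicated class
  exists); synonymous and non-exonic variants are dropped.
- **Background occurrence**: the co-sequenced research samples are used
  occurrence-wise, not frequency-wise — carried by strictly more than
  `background_max_carriers` (default 1) excludes. Carrier matching is the
  exact `(chrom, pos, ref, alt)` key; no fuzzy indel matching.
- **Missing genotypes**: sharing requires an observed carrier genotype, so
  a missing call in a discovery individual drops the variant. The
  segregation filter defaults to *strict* (a missing obligate-carrier
  genotype raises — the worked example has complete Sanger genotypes), with
  a *permissive* mode that treats missing as "carrier unknown, do not
  exclude" and reports the skipped cells. The Monte-Carlo benchmark uses
  permissive mode because noisy replicates legitimately lack calls.
- **Indel representation**: printed tables write deletions as `GGA → -`;
  VCF requires anchored bases (`AGGA → A`). `io.to_table_style` /
  `io.to_vcf_style` convert between the two; the `-` token is an ordinary
  allele string everywhere else (so `-/-` is a homozygous-reference call
  at an insertion site, not a missing genotype — missing is `./.`).

### Prediction aggregation

Predictors are consumed as categorical letters; nothing is recomputed.
The default support policy counts PhyloP `C`, SIFT `D`, PolyPhen2 `D`/`P`,
LRT `D`, MutationTaster `D` as supportive, and counts protein-truncating /
in-frame-indel variant type as one supportive line of evidence. Both
knobs are explicit in `SupportPolicy` because the underlying convention is
genuinely ambiguous: conservation-only support matters for one candidate
(OR13C8) and the variant-type rule for another (the EPB41L4B in-frame
deletion, which has no predictor letters at all); with the defaults,
exactly one of the twelve worked-example candidates (SEC16A) is
unsupported, which is the published reading. GERP++ is accepted as an
optional sixth field and ignored by the default policy.

### Cohort comparison

Candidate-vs-cohort intersection is exact-key membership. The gene-level
cohort filter keeps variants in the candidate genes that are
protein-altering, have MAF ≤ 0.20, have ≥ 1 supportive prediction (when
required), and have case frequency ≥ control frequency (when required;
absent frequencies count as 0, which keeps the variant). Family
classification counts, per variant: families with exactly one genotyped
member who carries (*single carrier*); families with ≥ 2 genotyped members
and ≥ 2 genotyped affected members all carrying (*segregating*); families
with ≥ 2 genotyped members, at least one carrier, and an affected
non-carrier (*non-segregating*). Unaffected carriers never demote a
family — incomplete penetrance is tolerated by design. Families with no
carrier, and two-member families whose only carrier is unaffected, are
uninformative and uncounted.

## Packaged fixtures and their provenance flags

The worked-example tables are shipped as TSVs. Cells whose printed source
is typographically ambiguous carry flags (`counts_ambiguous`,
`freq_ambiguous`, `allele_as_printed`, `prediction_string_ambiguous`);
they record a curator's reading chosen for internal consistency (e.g.
family counts reconciled against the printed cohort allele frequencies)
and are deliberately excluded from exact assertions in the test suite.
Two scenario steps are a known narrative-vs-genotype divergence: computed
from the genotypes, assuming Co-652 a carrier excludes three genes
(OR13C8, EPB41L4B, **and TAS2R7**, where Co-652 is homozygous reference)
and Co-692 excludes two (DZIP1L **and PCOLCE2**). The package always
reports what the genotypes imply;
`fixtures.NARRATED_SCENARIO_EXCLUSIONS` preserves the narrated sets for
comparison.

## Simulator

The generator emulates the *post-annotation, shared-variant* landscape of
a family exome study at desk scale, not raw sequencing:

- **Pedigree**: `generations` (default 3) with `offspring_per_couple`
  (default 2) per couple and married-in founder spouses; ~10 members by
  default, matching the size of pedigree actually genotyped in such
  studies.
- **Disease**: one causal variant, population frequency 0 (novel — the
  worked example's candidates are all novel or < 1 %), heterozygous in one
  first-generation founder and gene-dropped; carriers affected with
  probability `penetrance` (default 1.0), non-carriers with probability
  `phenocopy_rate` (default 0.0). The defaults are the idealised design
  the deterministic filters assume; the interesting experiments perturb
  them.
- **Background**: `n_variants` (default 100) variants with MAF drawn from
  `0.5·Beta(0.5, 3)` (rare-skewed, median ≈ 0.05), founder genotypes under
  Hardy–Weinberg, transmission independent per variant — no linkage,
  recombination or de novo mutation, because the pipeline under test is
  per-variant. The default count is a desk-scale stand-in chosen so a
  full Monte-Carlo benchmark stays interactive; the functional-class mix
  (60 % missense, 25 % synonymous, 15 % non-exonic) exists to exercise the
  functional filter, not to match genome-wide annotation proportions.
  Background-variant MAF annotations equal their true simulation MAF
  (annotation error is not modelled).
- **Noise**: per-cell missingness and genotype error (replacement by a
  uniformly chosen different genotype); applied to the family table, not
  the background cohort.
- **Cohort**: `n_background_cohort` (default 30, the co-sequenced sample
  count of the emulated design) unrelated Hardy–Weinberg individuals.
- **Determinism**: one integer seed; each stage draws from a named
  `SeedSequence` spawn stream, so pedigree, transmission, phenotype,
  noise and cohort can be re-run independently and VCF/PED outputs are
  byte-identical across runs.

`recovery_benchmark` simulates replicates (per-replicate seeds derived
from the master seed), runs the discovery cascade with up to three assumed
carriers as the sequenced-trio stand-in and the segregation filter with
the full assumed set, and reports causal-variant retention and mean
shortlist sizes. With the ideal defaults retention is exactly 100 % by
construction; the benchmark's purpose is the degradation curves under
genotype error and under phenocopy-contaminated carrier sets.

**What passing simulations do not show**: the generator has no linkage
disequilibrium, no annotation error, no relatedness in the background
cohort, no multi-locus disease models, and its variant counts are far
below exome scale — results validate the *logic* of the filters, not
their genome-wide yield on real data.

## Numerical and design choices

- Genotype calls are normalised to sorted allele tuples, making equality
  and hashing order-free.
- Reports sort variants by natural chromosome order (1–22, X, Y) then
  position; variant keys are unique, so ties cannot occur.
- The exclusion ledger validates on every construction that the
  per-carrier sets are disjoint and partition the input shortlist.
- The pipeline resolves and validates all inputs before writing anything,
  so a failed run leaves no partial candidate table; the run log records
  the config hash and package version needed to reproduce a run.
- Test problem sizes (500 random tables for oracle equivalence, 1000
  ideal-design replicates, 200-replicate degradation comparisons, 10⁴
  samples for the Hardy–Weinberg check) were chosen so the suite gives
  3-standard-error statistical resolution while completing in well under
  a minute of simulation time.

## Known limitations

- No likelihood-based co-segregation statistics (LOD scores, Bayes
  factors): the segregation test is the deterministic carrier predicate,
  which is exactly as fragile to phenocopies and genotype error as the
  benchmark quantifies.
- No joint-genotyping, quality, or depth filtering; the pipeline consumes
  called genotypes.
- Gene symbols are compared as printed; no identifier remapping.
- The VCF writer emits minimal headers (GT only) and requires anchored
  alleles; `N` anchors from table-style conversion are sufficient for
  round trips but not for submission to external annotation tools.
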