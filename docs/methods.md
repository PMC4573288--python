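# Methods

## The analysis model

`cfmeth` analyses per-CpG methylated/unmethylated read-count tables from
pooled bisulfite sequencing. The statistical unit is one cytosine in CpG
context; a pool's methylome is a sorted table of (chromosome, 1-based
position, strand, methylated count, unmethylated count). All internal
coordinates are 1-based cytosine positions; BED tracks are converted at the
I/O boundary exactly once.

The per-base differential call between a case pool A and a control pool B
proceeds: (1) drop chromosomes X/Y (sex-chromosome dosage differs between
individuals and pools); (2) merge each CpG dyad's two strands into one
observation (both cytosines report the same underlying methylation state;
merging roughly doubles depth) — destranding is on by default and
switchable, since count tables in the wild come both ways; (3) keep loci
with coverage ≥ `min_coverage_per_group` (default 5) in *both* pools;
(4) two-sided Fisher exact test per locus; (5) DMV = percent methylation
difference (case − control); (6) Benjamini–Hochberg q-values across all
tested loci; (7) call a DML when |DMV| ≥ 20 and p ≤ 0.05, plus q ≤ 0.5
when emulating targeted-amplicon validation. All threshold comparisons are
inclusive; the hotspot DMV rule (≥ 50) is likewise inclusive and
configurable.

The Fisher test is an exact integer enumeration of the hypergeometric
distribution over the fixed margins with the standard two-sided rule (sum
probabilities of all tables no more probable than the observed one).
Integer arithmetic makes tie decisions exact and guarantees p ≥ P(observed
table) > 0; a result that would underflow double precision is floored at
the smallest positive float. The test assumes reads are independent draws
— it does not model extra-binomial variation between the pooled
individuals, which is why null calibration is verified by simulation (see
below) and why overdispersed simulations produce conservative-to-nominal,
not anti-conservative, behaviour at the whole-pipeline level only by
virtue of the DMV effect-size filter.

Context annotation is **multi-label**: a DML inside both a CpG island and
a TSS1500 window counts in both categories, because per-context summaries
are reported per context rather than as a partition; this changes
denominators relative to a priority scheme and is the documented choice.
Loci overlapping no track appear in the genome-wide summary only.

A hotspot call reports the full island interval; the minimal window
spanning the qualifying loci is exposed as auxiliary `core_start/core_end`
columns. No adjacency or maximum-span constraint is applied to the
qualifying loci. When two case/control comparisons are run (case vs each
control cohort), the pipeline also reports the intersection of the two
call sets as the consensus panel.

Pool similarity restricts all pools to the locus intersection at the DML
min-coverage (the same depth rule as testing, so every statistic shares
one locus index), then computes pairwise Pearson r, Ward linkage on
d = 1 − r, and PCA of the pools × loci matrix after per-locus centring
(component signs fixed by making each component's largest-magnitude
loading positive). Cross-platform concordance pairs loci by exact identity
after destranding both platforms identically and defines R² as the square
of the pooled Pearson r — stated explicitly because R² could otherwise
mean a regression goodness of fit.

## The generative model

The synthetic module emulates the structure such a study assumes, not raw
reads:

* **CpG placement** — a Poisson process along each chromosome with mean
  spacing 130 bp outside islands and 130/5 = 26 bp inside (dyads occupy
  2 bp and never overlap).
* **Landscape** — each dyad gets a true methylation proportion drawn once
  per study: Beta(6.8, 1.2) (mean 0.85) outside islands, Beta(0.75, 14.25)
  (mean 0.05) inside. The landscape is shared by all pools, so two pools
  simulated from identical parameters satisfy the two-group null exactly
  at every locus — the property null-calibration checks require. A pool
  simulated without a supplied landscape draws its own.
* **Global hypomethylation** — a subtractive shift (default 0.15, a free
  parameter: no quantitative magnitude is established for the cfDNA
  global shift) applied to background proportions only, clamped to [0, 1];
  islands stay low, reproducing "global hypomethylation with focal island
  hypermethylation" by construction.
* **Planted hotspots** — a chosen set of islands whose proportions in the
  affected pool are redrawn from a Beta centred at the planted level
  (default 0.9, concentration 50). These draws derive from the truth seed
  and pool label, not the measurement seed: they are pool biology, so a
  second platform re-measuring the same pool observes the same underlying
  proportions.
* **Counts** — coverage per cytosine ~ negative binomial (mean = the
  pool's depth, size k = 8, chosen as mild super-Poisson depth variation);
  methylated count ~ beta-binomial with intra-pool correlation ρ (default
  0.02; a pool of 40 individuals is overdispersed relative to binomial,
  and ρ = 0 recovers binomial exactly for calibration oracles). Both
  strands of each dyad are emitted with independent coverage draws so the
  destranding path is exercised.

### Genome geometry defaults

One 2 Mb chromosome, 200 non-overlapping islands of 600 bp placed one per
10 kb slot, ~19k CpG dyads, 100 genes (half with their TSS at an island
start, producing promoter-island overlap of the TSS1500/UTR5/Exon1 tracks
the way real annotation behaves). Island geometry keeps islands at roughly
a quarter of all CpGs — deliberately the smallest over-representation that
still gives every island ~23 dyads, enough for the ≥ 8-qualifying-loci
hotspot rule to be statistically robust (Poisson P(island < 8 dyads) ≈
2·10⁻⁵) at this desk scale; real genomes hold only ~7–10% of CpGs in
islands, but matching that share with 200 islands in 2 Mb would leave ~7
CpGs per island and break the hotspot rule by construction. Pool depths
default to 7.4 / 9.6 / 16.9 (H / DFS / MBC analogs); the recovery and
calibration experiments in the test and acceptance suites use 10 / 10 / 17.

### What the generator does not emulate

Read-level artefacts (bisulfite conversion failure, mapping bias, PCR
duplicates), copy-number variation, cell-type composition and deconvolution
mixtures, chromosome-scale methylation domains (PMDs), and locus-level
heterogeneity of the tumour fraction (the global shift is uniform across
background loci). Passing tests therefore demonstrate that the analysis
logic is correct and calibrated under the assumed sampling model — not
that real cfDNA data meet those assumptions.

## Numerical and design choices

* Group A is the case; `hyper` means DMV > 0. Swapping groups negates
  every DMV and preserves every p-value exactly.
* BH q-values via `statsmodels` (`fdr_bh`); the q threshold is off for the
  genome-wide call (only P and DMV thresholds are standard there) and 0.5
  for amplicon-style validation.
* Overlapping annotation intervals are kept, never merged; membership is
  "overlaps any interval".
* Chromosome names are taken verbatim; disjoint pool/track namespaces
  raise a configuration error rather than being silently coerced.
* Zero-coverage rows are retained at parse time and removed only by the
  explicit coverage filter, so filtering is observable in one place.
* A minus-strand cytosine with no plus partner destrands to its own
  plus-strand record at the dyad position (logged).
* The coverage-file dialect carries no strand; such pools are flagged and
  skipped by destranding.
* Orchestrated runs are a pure function of (config, seed): random streams
  are per-stage substreams of the root seed, artifact floats are written
  at fixed precision, and the manifest contains only deterministic content
  (parameters, counts, SHA-256 checksums); wall-times go to the log.
* Desk-scale problem sizes used throughout the test and acceptance suites:
  ~19k CpG dyads per pool, 5 replicate seeds for recovery and null
  calibration experiments — chosen so a full validation cycle completes in
  well under a minute while every asserted property retains a comfortable
  statistical margin.

## Known limitations

* The Fisher test ignores intra-pool overdispersion; with large ρ its
  nominal p-values would be anti-conservative per locus. The pipeline's
  defences are the DMV effect-size filter and pooled (not per-individual)
  inputs; a beta-binomial test with covariates is explicitly out of scope.
* Amplicon-level validation tests aggregate counts per amplicon; a
  per-locus alternative is available through the standard DML caller.
* Hotspot extent is the annotated island; no sub-island segmentation or
  window refinement is performed beyond the auxiliary core-span columns.
* The CpG-island definition is a required user input (a BED track); no
  island-finding from sequence is included.
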