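# Methods

This note documents the statistical model, the synthetic-data generator,
and the numerical and design choices behind `dgepipe`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The count model and the significance test

A DGE library is a multiset of 21-nt NlaIII tags; after cleaning, the
clean-tag total N plays the role of sequencing depth, and a gene's
expression is its unique-mapping tag count. Comparing a count x (total N₁)
against y (total N₂) uses the Audic–Claverie conditional distribution

    P(y | x) = (N₂/N₁)^y (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) ),

the posterior predictive for a second Poisson count given the first under
a flat prior. Mathematically this is a negative binomial with r = x+1
successes and success probability N₂/(N₁+N₂); the implementation evaluates
the closed form directly in log space via `gammaln` and never calls a
library distribution, so the test suite can use `scipy.stats.nbinom` and
exact `Fraction` arithmetic as two genuinely independent oracles.

**Tails and truncation.** The two-sided p-value is the doubled smaller
tail, capped at 1: `p = min(1, 2·min(P(Y≤y), P(Y≥y)))`. The shorter tail
is summed directly; for the open upper tail the summation proceeds in
blocks and stops once the last term t satisfies t < 10⁻¹⁹·S (S the running
sum) with term ratio r < 0.999 — past the mode the ratio
q·(x+y'+1)/(y'+1) decreases monotonically toward q < 1, so the neglected
remainder is geometrically bounded by t·r/(1−r) < 10⁻¹⁶·S, far inside the
10⁻¹⁰ agreement the exact-arithmetic oracle demands. The other tail is
recovered from normalization (both tails include the observed point).

**Exchange symmetry is approximate.** Swapping (x,N₁)↔(y,N₂) multiplies
the conditional pmf by N₁/N₂ and sums a different axis of the joint, so
the two orientations agree only in order of magnitude (measured: within a
factor ~2.5 in far tails, much closer near p = 1). This is a property of
the conditional construction itself, not of the implementation; the
property test asserts agreement within a factor of 4.

**Calibration.** The doubled-tail exact test is conservative for discrete
counts; under the generator's log-normal baseline at a mean of ~100
counts/gene its null rejection rate at p < 0.01 is about 0.008. The
acceptance test checks the rate against the binomial band around 0.01 at
10⁴ features; the conservatism places it near the lower edge of that band.

**Calls.** Per tumor/normal pair, BH adjustment runs across genes within
the pair; a feature is called up/down iff P < 0.01 AND FDR ≤ 0.001 (both
thresholds configurable) with direction from the log₂ TPM ratio. The
0.5-TPM pseudocount keeps ratios finite when one side is zero. A
feature-level status used by enrichment and the cluster scan is "down"
("up") when at least `min_samples` (default 2) pairs call that direction
and it outnumbers the opposite calls.

## Tag reference and mapping

Virtual tags are extracted from annotated transcript *sense* sequences:
every CATG with ≥ 17 nt downstream yields one tag keyed to the gene.
Extracting from transcripts rather than the raw genome is what makes
gene-level counting well-defined; the raw genome is still used for the
novel-tag screen. All CATG sites enter the index (tags shared by several
genes are kept but flagged ambiguous and can never count). Filtering order
is fixed — N-containing, then adapter-derived (tag equal to or a prefix of
the adapter), then single-copy — because the order determines the
clean-tag total. Mapping allows at most one mismatch with exact matches
taking precedence (maximizing specificity, the convention of short-tag
aligners); a tag counts only when it resolves to exactly one gene, and
assigned + unmapped + rejected mass always equals the clean mass.

## Small-RNA processing and the hairpin screen

Adapter clipping scores every clip position by a gap-free alignment of the
adapter prefix against the read suffix (match +1, mismatch −1), requiring
≥ 6 nt overlap and ≤ 20% mismatches; ties prefer the earlier cut. Collapsed
reads ≥ 18 nt are assigned to the first matching annotation category;
known-miRNA matching tolerates 3' isomiRs within ±2 nt (trimmings always,
extensions only when templated by the precursor).

Novel-candidate evaluation clusters genome-placed unannotated reads into
loci (gap ≤ 30 nt), extends ±70 nt, and folds the window. A *stem-loop* is
the maximal chain of nested base pairs around one hairpin loop, built from
the loop outward and terminated at any multiloop branching or at an
interior loop/bulge step larger than 10 nt. The candidate flags are:

* `hairpin_ok` — chain of ≥ 16 pairs, pairing density ≥ 0.5 over the
  chain's span, an uninterrupted helix of ≥ 15 bp inside the chain, the
  read stack 80%-contained on one arm with ≥ 75% of read positions paired,
  and read 5' ends within a 3-nt window (a Dicer-product proxy);
* `energy_ok` — folding energy < −20 kcal/mol;
* `recurrence_ok` — ≥ 1 TPM in ≥ 2 samples.

The uninterrupted-helix and read-pairing requirements are what separate
genuine inverted repeats from the incidental bulgy stems that minimum-free-
energy folding finds in any ~160-nt window (the chance of a 15-bp perfect
inverted repeat in 160 random nt is ~10⁻⁵). The flip side is a deliberate
limitation: real pre-miRNAs with bulges every few base pairs would need a
lower `min_stack`, at the cost of specificity on random sequence; a
shuffled-sequence energy comparison (randfold-style) would be the natural
extension. Folding is pluggable: ViennaRNA's nearest-neighbor model when
the bindings are importable, otherwise a built-in Nussinov-style base-pair
maximizer scored at −2 kcal/mol per stacked pair, calibrated so a 16-bp
stem clears the −20 kcal/mol rule. Flags are monotone in the thresholds:
relaxing the energy ceiling or the TPM floor never removes a reported
candidate.

## Enrichment, GSEA, and the positional scan

Over-representation uses the right-sided hypergeometric tail
P(X ≥ k | N, K, n) with BH across sets; the universe defaults to every
gene in the loaded collection (the detectability-filtered DE table is what
supplies queries). GSEA ranks features by mean pairwise log₂ ratio
(deterministic lexicographic tie-break), accumulates |score|^p/Σ at hits
and 1/(N−|S|) at misses, takes the signed extremum as ES (exact ties go to
the positive side, with a 10⁻¹² tolerance absorbing cumsum rounding), and
extracts the leading edge at the extremum. Significance uses gene-label
permutations (add-one smoothed, two-sided on |ES|) — with only 10 pairs,
phenotype permutation would have too few distinct relabelings. Core genes
are ranked by the number of leading edges containing them; miRNAs by the
number of pathways with ≥ 1 target in the leading edge (set semantics, so
several targets in one pathway count once), both also against the
designated cancer subset of the collection.

The positional scan sorts miRNA loci per chromosome, joins runs with
inter-locus gaps ≤ 10 kb, keeps runs of ≥ 3 statused members, and tests
each cluster's down (and up) membership against the genome-wide rate with
the right-sided hypergeometric, BH-adjusted across all cluster×direction
tests. Cluster p-values on 3–7-member clusters are heavily discrete and
therefore super-uniform under the null; the validity check asserts the
empirical CDF of null p-values never exceeds the uniform beyond the
Kolmogorov–Smirnov band, rather than two-sided closeness to U(0,1), which
no exact discrete test could satisfy.

## The synthetic-data generator

The generator emulates a 10-pair matched design with ~10⁶ clean tags per
mRNA library (both configurable; the real study does not publish per-
library totals, so 10⁶ is a stand-in).

* **Genome.** Random transcripts (200–1200 nt, 80% plus-strand) each with
  a guaranteed CATG + 17 nt site; intergenic spacers; a 3-kb mitochondrial
  decoy; a chromosome of planted hairpin loci (25-bp perfect-stem inverted
  repeats with 12-nt loops) alongside non-hairpin decoy loci; a miRNA
  chromosome with one 7-member tandem cluster (gaps < 10 kb), several
  background clusters, and scattered singletons; decoy rRNA/tRNA/snRNA/
  snoRNA/repeat sequences for the annotation hierarchy.
* **Effects.** Baselines are log-normal (σ = 1.2), so the 1 TPM
  detectability floor is populated by construction. DE features receive
  effects of constant magnitude `log2_effect` whose signs are assigned
  greedily so total expression mass is conserved. This mass balance is the
  global-normalization assumption that proportion-based (TPM) testing
  requires: without it every null gene inherits a systematic tumor/normal
  proportion shift and no threshold can control the false-discovery
  proportion. One consequence is an asymmetric up/down split (~20/80 at
  |log₂FC| = 2), which real tumor data also shows. The planted miRNA
  cluster is coherently downregulated.
* **Counts.** Negative binomial via gamma-Poisson mixing (variance
  μ + αμ²), degenerating to Poisson at dispersion α = 0 — the sampling
  model the significance test assumes — so tests can separate "statistic
  correct" from "model misspecified". Each gene's count lands on its
  3'-most CATG tag, which keeps the generator's bookkeeping an exact
  oracle for the mapping round-trip. Artifact mass (N-containing tags,
  adapter tags, single-substitution error copies) is layered on top to
  exercise the filters.
* **Small RNA.** Reads are insert + 3' adapter truncated to 36 nt at
  constant quality. Recurrent hairpins are expressed in 3 samples,
  singleton hairpins in 1, and non-hairpin decoy loci in 3 (so they fail
  only the hairpin criterion); an rRNA/tRNA decoy fraction exercises the
  hierarchy and a short-insert fraction exercises the length filter.
* **Determinism.** One integer seed; every stage derives its own
  generator from a (seed, stage) seed sequence; identical configurations
  are byte-identical, including all written files.

What the generator does *not* model — positional sequencing-error
profiles, quality-score variation, ligation bias, partial digestion,
isomiR 5' heterogeneity, correlated biological replicates — bounds what
passing tests show about real data: they validate the statistics and the
pipeline logic under the stated model, not robustness to those artifacts
(the dispersion knob probes the main misspecification axis).

## Problem sizes used by the checks

The test suite and acceptance script run at sizes chosen to keep a full
run on one CPU in a few minutes: DE recovery at 1,000 genes × 10 pairs
over 20 seeds (tests) or 5 seeds (script); null calibration at 10⁴
features; the hairpin screen at 3-pair studies over 10 (tests) or 5
(script) seeds; the cluster scan over 100 call-profile replicates; GSEA
and hypergeometric oracles on exhaustive small fixtures (lists ≤ 20,
universes ≤ 20). The qPCR-style concordance check emulates validating the
most consistently deregulated features: sequencing-side mean log₂ ratios
are compared in sign against noisy re-measurements of the true effects
(σ = 0.6 on the log₂ scale).

## Known limitations

* The mapper enumerates 1-mismatch neighbors per tag (63 lookups), which
  is exact and fast for tag-scale indexes but not a general aligner.
* Annotation-category matching is by substring against category reference
  sequences — appropriate for the synthetic catalogs; genomic-interval
  hierarchies would be needed for real annotation tracks.
* GSEA offers gene-label permutation only; sample permutation and
  signal-to-noise ranking are natural extensions.
* The built-in folder maximizes base pairs with a constant stack energy;
  it orders hairpin stability correctly but its absolute energies are not
  nearest-neighbor thermodynamics.
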