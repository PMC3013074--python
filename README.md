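# dgepipe

Tag-based digital gene expression (DGE) analysis for matched tumor/normal
designs, with integrated small-RNA profiling — the kind of analysis used to
characterize clear cell renal cell carcinoma by sequencing both mRNA tags
and miRNAs in tumor/adjacent-normal tissue pairs. The package is aimed at
computational biologists who want a tested, reusable implementation of this
pipeline whose every stage can be exercised end to end on synthetic data
with known ground truth.

## What it implements

**Tag quantification.** Expression is measured by 21-nt NlaIII tags
(`CATG` + 17 nt). A *virtual tag reference* maps every CATG site in every
annotated transcript to its gene; raw tag multisets are cleaned (N-containing,
adapter-derived, and single-copy tags removed), mapped with at most one base
mismatch requiring a unique gene assignment, and normalized to TPM
(tags per million clean tags): `TPM = count · 10⁶ / clean_total`. Unmapped
tags that hit the nuclear genome (but not the mitochondrion) and recur at
≥ 1 TPM in ≥ 2 samples are reported as novel expression tags.

**Differential expression.** For counts x (library total N₁) and y (total
N₂), the Audic–Claverie conditional probability

    P(y | x) = (N₂/N₁)^y · (x+y)! / ( x! · y! · (1 + N₂/N₁)^(x+y+1) )

is evaluated in log space; the two-sided p-value doubles the smaller tail
(summed with a proven truncation bound) and is capped at 1. Per pair,
p-values are Benjamini–Hochberg adjusted across genes; a feature is called
up/down when `P < 0.01` and `FDR ≤ 0.001`, with direction from the TPM
log₂ ratio (0.5-TPM pseudocount). Recurrence summaries count features
deregulated in at least k pairs.

**Small RNA.** 3' adapters are clipped by a gap-free dynamic-programming
alignment; reads are collapsed, length-filtered (≥ 18 nt), and assigned
hierarchically (known miRNA with ±2-nt 3' isomiR tolerance, then rRNA,
tRNA, snRNA, snoRNA, repeats, mRNA). Unannotated reads are clustered on
the genome, extended ±70 nt, folded (ViennaRNA when available, otherwise a
built-in base-pair maximizer), and reported as novel miRNA candidates when
the locus forms a stable stem-loop (MFE < −20 kcal/mol) with the read
stack on one arm and is expressed at ≥ 1 TPM in ≥ 2 samples.

**Pathways.** Right-sided hypergeometric over-representation with BH
correction; GSEA (weighted Kolmogorov–Smirnov-like running sum, gene-label
permutations) with leading-edge extraction; core-gene and miRNA
prioritization by the number of pathways (and of a designated cancer
subset) whose leading edge contains the gene or a miRNA's target; and a
positional scan for genomic miRNA clusters (runs of loci ≤ 10 kb apart,
≥ 3 members) coherently deregulated relative to the genome-wide rate.

**Synthetic studies.** `dgepipe.simulate` generates everything a real
study would sequence — a CATG-bearing genome, miRNA catalog with a planted
tandem cluster, negative-binomial tag libraries with mass-balanced planted
fold changes, adapter-ligated small-RNA reads, planted novel hairpins,
gene sets with planted enrichment — plus a machine-readable truth record,
so every claim the pipeline makes can be checked against what was planted.

## Worked example

```python
from dgepipe.config import PipelineConfig
from dgepipe.simulate import SimulationConfig
from dgepipe.pipeline import run_pipeline

cfg = PipelineConfig(seed=7)
cfg.simulation = SimulationConfig(
    seed=7, n_genes=300, n_pairs=4, n_mirnas=40,
    library_size=200_000, smallrna_library_size=30_000,
)
cfg.gsea_permutations = 200
res = run_pipeline(cfg, "run7")

truth = res["study"]["truth"]
calls = res["gene_calls"]
dereg = (calls != "ns").any(axis=1)
print(f"genes deregulated in >=1 pair: {int(dereg.sum())} "
      f"(planted DE genes: {len(truth.de_genes)})")
reported = [c for c in res["novel_candidates"] if c.reported]
print(f"novel miRNA candidates reported: {len(reported)} (planted: 3)")
top = res["clusters"].iloc[0]
print(f"top miRNA cluster: {top.chrom}:{top.start}-{top.end} "
      f"{top.direction}, {top.k}/{top.n_members} members, "
      f"p={top.p_hyper:.2e}, FDR={top.fdr:.2e}")
```

prints

```
genes deregulated in >=1 pair: 29 (planted DE genes: 30)
novel miRNA candidates reported: 3 (planted: 3)
top miRNA cluster: chrX:18048-24032 down, 7/7 members, p=1.93e-06, FDR=2.70e-05
```

29 of the 30 planted differentially expressed genes are recovered at the
joint `P < 0.01`, `FDR ≤ 0.001` threshold with no false calls (the 30th
sits below the 1 TPM detectability floor); all three planted novel hairpin
loci — and nothing else — pass the candidate screen; and the planted
7-member miRNA cluster tops the positional scan as coherently
downregulated. `run7/` contains every intermediate table (provenance
headers, byte-identical on rerun) plus `manifest.json`.

The same pipeline is available from the shell:

```bash
dgepipe run-all --seed 7 --outdir run7
dgepipe cluster-scan --loci run7/mirna_loci.bed --status status.tsv --out clusters.tsv
```

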