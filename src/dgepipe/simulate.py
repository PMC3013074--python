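"""Synthetic study generator for the matched tumor/normal DGE design.

Everything the real study obtained by sequencing is emulated here with a
machine-readable truth record: a small genome with CATG-bearing transcripts,
a miRNA catalog with a tandemly clustered family, planted novel hairpin
loci, negative-binomial tag libraries with planted fold changes, 3'-adapter-
ligated small-RNA reads, gene sets with planted enrichment, and miRNA target
tables.  Every generator is driven by a single integer seed; stage-level
sub-seeds are derived deterministically, so identical configurations yield
byte-identical outputs.

Count model: per-gene counts are negative binomial with mean proportional to
a log-normal baseline times 2^effect in the tumor; at dispersion 0 this
degenerates to Poisson, the sampling model the downstream significance test
assumes, so tests can separate "statistic correct" from "model
misspecified".
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tagdge import TAG_ANCHOR, TAG_LEN, TagLibrary, revcomp

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "Genome",
    "MirnaCatalog",
    "simulate_genome",
    "plant_truth",
    "simulate_tag_libraries",
    "simulate_smallrna_reads",
    "simulate_gene_sets",
    "simulate_target_map",
    "simulate_mirna_calls",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stage tags for sub-seed derivation
_STAGE_GENOME = 1
_STAGE_TRUTH = 2
_STAGE_TAGS = 3
_STAGE_SMALLRNA = 4
_STAGE_SETS = 5
_STAGE_TARGETS = 6
_STAGE_CALLS = 7


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults mirror the emulated design: 10 matched tumor/normal pairs,
    ~10^6 clean tags per mRNA library, 10% of genes truly DE at a mean
    absolute log2 fold change of 2.
    """

    seed: int = 0
    n_genes: int = 1000
    n_pairs: int = 10
    library_size: int = 1_000_000
    frac_de: float = 0.1
    log2_effect: float = 2.0
    dispersion: float = 0.0
    n_mirnas: int = 60
    n_novel_hairpins: int = 3
    adapter_sequence: str = "TCGTATGCCGTCTTCTGCTTG"
    error_rate: float = 0.0

    # secondary knobs (sizes, artifact fractions, catalog composition)
    baseline_sigma: float = 1.2
    transcript_len_range: tuple[int, int] = (200, 1200)
    read_length: int = 36
    smallrna_library_size: int = 100_000
    decoy_fraction: float = 0.10
    short_insert_fraction: float = 0.05
    artifact_n_fraction: float = 0.005
    artifact_adapter_fraction: float = 0.005
    n_singleton_hairpins: int = 1
    n_decoy_loci: int = 2
    hairpin_samples: int = 3
    mirna_cluster_size: int = 7
    n_background_clusters: int = 6
    n_gene_sets: int = 30
    gene_set_size: int = 40
    n_cancer_sets: int = 10
    n_novel_tags: int = 4

    def validate(self) -> None:
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValueError("frac_de must lie in [0, 1]")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if len(self.adapter_sequence) < 10:
            raise ValueError("adapter must be at least 10 nt")
        if self.transcript_len_range[0] < 25:
            raise ValueError("transcripts shorter than 25 nt cannot carry a tag")
        if self.n_genes < 1 or self.n_pairs < 1:
            raise ValueError("n_genes and n_pairs must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass
class TruthSet:
    """Planted ground truth for recovery testing.

    Effects are signed log2 fold changes (tumor vs normal); features absent
    from the mappings have effect exactly 0.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    novel_hairpin_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    enriched_sets: list[tuple[str, str]] = field(default_factory=list)
    cluster_mirnas: list[str] = field(default_factory=list)
    # per-feature baseline expression weights (generator-internal but exposed
    # so round-trip oracles can reconstruct expected means)
    baseline_genes: dict[str, float] = field(default_factory=dict)
    baseline_mirnas: dict[str, float] = field(default_factory=dict)

    def effect(self, feature_id: str) -> float:
        return self.de_genes.get(feature_id, self.de_mirnas.get(feature_id, 0.0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "de_genes": self.de_genes,
                    "de_mirnas": self.de_mirnas,
                    "novel_hairpin_loci": [list(t) for t in self.novel_hairpin_loci],
                    "enriched_sets": [list(t) for t in self.enriched_sets],
                    "cluster_mirnas": self.cluster_mirnas,
                    "baseline_genes": self.baseline_genes,
                    "baseline_mirnas": self.baseline_mirnas,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            de_genes=d["de_genes"],
            de_mirnas=d["de_mirnas"],
            novel_hairpin_loci=[tuple(t) for t in d["novel_hairpin_loci"]],
            enriched_sets=[tuple(t) for t in d["enriched_sets"]],
            cluster_mirnas=d["cluster_mirnas"],
            baseline_genes=d.get("baseline_genes", {}),
            baseline_mirnas=d.get("baseline_mirnas", {}),
        )


@dataclass
class MirnaCatalog:
    """Mature + precursor miRNA sequences and their genomic loci."""

    mature: dict[str, str]
    precursor: dict[str, str]
    loci: pd.DataFrame  # chrom, start, end, strand, feature_id
    cluster_members: list[str]


@dataclass
class Genome:
    """Synthetic reference bundle: sequences, annotation, and catalogs."""

    sequences: dict[str, str]
    annotation: pd.DataFrame  # chrom, start, end, strand, gene_id, transcript_id
    mirna_catalog: MirnaCatalog
    transcripts: dict[str, str] = field(default_factory=dict)  # gene_id -> sense seq
    decoys: dict[str, list[str]] = field(default_factory=dict)
    hairpin_loci: pd.DataFrame = field(default_factory=pd.DataFrame)
    mito_chrom: str = "chrM"

    @property
    def mito_sequence(self) -> str:
        return self.sequences[self.mito_chrom]

    def nuclear_sequences(self) -> dict[str, str]:
        return {c: s for c, s in self.sequences.items() if c != self.mito_chrom}


def simulate_genome(config: SimulationConfig) -> Genome:
    """Build the synthetic reference, annotation and miRNA catalog.

    Guarantees by construction: every protein-coding transcript carries at
    least one CATG with 17 nt downstream; every planted novel-hairpin locus
    is a perfect inverted repeat (25-nt stem, 12-nt loop); annotation is
    0-based half-open with explicit strand.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_GENOME)

    # --- protein-coding chromosome -------------------------------------
    lo, hi = config.transcript_len_range
    chrom_parts: list[str] = []
    ann_rows = []
    transcripts: dict[str, str] = {}
    pos = 0
    for i in range(config.n_genes):
        gid = f"G{i + 1:04d}"
        tlen = int(rng.integers(lo, hi + 1))
        seq = _random_dna(rng, tlen)
        # plant a guaranteed tag site away from the 3' end
        site = int(rng.integers(tlen // 4, tlen - TAG_LEN))
        seq = seq[:site] + TAG_ANCHOR + seq[site + len(TAG_ANCHOR) :]
        strand = "+" if rng.random() < 0.8 else "-"
        spacer = _random_dna(rng, int(rng.integers(200, 501)))
        chrom_parts.append(spacer)
        pos += len(spacer)
        chrom_parts.append(seq if strand == "+" else revcomp(seq))
        ann_rows.append(("chr1", pos, pos + tlen, strand, gid, f"{gid}.t1"))
        transcripts[gid] = seq
        pos += tlen
    chrom_parts.append(_random_dna(rng, 300))
    sequences = {"chr1": "".join(chrom_parts)}
    annotation = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id"]
    )

    # --- novel hairpin / decoy chromosome ------------------------------
    hp_rows = []
    parts = []
    pos = 0
    kinds = (
        ["recurrent"] * config.n_novel_hairpins
        + ["singleton"] * config.n_singleton_hairpins
        + ["decoy"] * config.n_decoy_loci
    )
    for i, kind in enumerate(kinds):
        spacer = _random_dna(rng, int(rng.integers(300, 801)))
        parts.append(spacer)
        pos += len(spacer)
        if kind == "decoy":
            locus = _random_dna(rng, 62)
        else:
            arm = _random_dna(rng, 25)
            loop = _random_dna(rng, 12)
            locus = arm + loop + revcomp(arm)
        parts.append(locus)
        hp_rows.append(("chr2", pos, pos + len(locus), "+", f"HP{i + 1:02d}", kind))
        pos += len(locus)
    parts.append(_random_dna(rng, 300))
    sequences["chr2"] = "".join(parts)
    hairpin_loci = pd.DataFrame(
        hp_rows, columns=["chrom", "start", "end", "strand", "hairpin_id", "kind"]
    )

    # --- miRNA chromosome: one planted tight cluster + background ------
    mature: dict[str, str] = {}
    precursor: dict[str, str] = {}
    loci_rows = []
    parts = []
    pos = 0
    # assign miRNAs to positional groups
    group_sizes = [config.mirna_cluster_size]
    remaining = config.n_mirnas - config.mirna_cluster_size
    for _ in range(config.n_background_clusters):
        size = int(rng.integers(3, 6))
        if remaining - size < 0:
            break
        group_sizes.append(size)
        remaining -= size
    group_sizes.extend([1] * remaining)
    idx = 0
    cluster_members: list[str] = []
    for g, size in enumerate(group_sizes):
        for j in range(size):
            mid = f"miR-{idx + 1:03d}"
            idx += 1
            m = _random_dna(rng, 22)
            loop = _random_dna(rng, 15)
            pre = m + loop + revcomp(m)
            gap = int(rng.integers(500, 1501)) if j > 0 else int(rng.integers(12_000, 30_001))
            spacer = _random_dna(rng, gap)
            parts.append(spacer)
            pos += len(spacer)
            parts.append(pre)
            loci_rows.append(("chrX", pos, pos + len(pre), "+", mid))
            pos += len(pre)
            mature[mid] = m
            precursor[mid] = pre
            if g == 0:
                cluster_members.append(mid)
    parts.append(_random_dna(rng, 500))
    sequences["chrX"] = "".join(parts)
    loci = pd.DataFrame(loci_rows, columns=["chrom", "start", "end", "strand", "feature_id"])

    # --- mitochondrion and decoy ncRNA catalog -------------------------
    sequences["chrM"] = _random_dna(rng, 3000)
    decoys = {
        "rRNA": [_random_dna(rng, 1500) for _ in range(4)],
        "tRNA": [_random_dna(rng, 75) for _ in range(10)],
        "snRNA": [_random_dna(rng, 150) for _ in range(5)],
        "snoRNA": [_random_dna(rng, 120) for _ in range(5)],
        "repeat": [_random_dna(rng, 300) for _ in range(5)],
    }

    return Genome(
        sequences=sequences,
        annotation=annotation,
        mirna_catalog=MirnaCatalog(mature, precursor, loci, cluster_members),
        transcripts=transcripts,
        decoys=decoys,
        hairpin_loci=hairpin_loci,
    )


def _balanced_signs(
    de_ids: list[str],
    baseline: Mapping[str, float],
    magnitude: float,
    preset: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Assign ±magnitude effects so total expression mass is conserved.

    TPM-based testing compares proportions, so planted fold changes must not
    shift the library composition — otherwise every null feature inherits a
    systematic tumor/normal proportion shift.  Features are taken in
    descending baseline order and each is given the sign that best cancels
    the running mass imbalance (up adds ``b(2^m − 1)``, down removes
    ``b(1 − 2^−m)``); ``preset`` effects (e.g. a coherently downregulated
    cluster) are honored as-is and entered into the balance.
    """
    effects: dict[str, float] = dict(preset or {})
    imbalance = sum(
        baseline[f] * (2.0 ** e - 1.0) for f, e in effects.items()
    )
    for f in sorted(de_ids, key=lambda f: -baseline[f]):
        if f in effects:
            continue
        up = baseline[f] * (2.0 ** magnitude - 1.0)
        down = baseline[f] * (2.0 ** -magnitude - 1.0)
        if abs(imbalance + up) < abs(imbalance + down):
            effects[f] = magnitude
            imbalance += up
        else:
            effects[f] = -magnitude
            imbalance += down
    return effects


def plant_truth(genome: Genome, config: SimulationConfig) -> TruthSet:
    """Choose DE features, baselines, and record all planted signals.

    Baseline expression weights are log-normal (so the 1 TPM detectability
    floor is exercised by construction).  DE genes/miRNAs get effects of
    constant magnitude ``log2_effect`` with signs chosen to conserve total
    expression mass (see :func:`_balanced_signs`); the positional miRNA
    cluster is planted coherently downregulated.  Enriched-set truth is
    appended by :func:`simulate_gene_sets`.
    """
    rng = _rng(config.seed, _STAGE_TRUTH)
    genes = sorted(genome.transcripts)
    baseline_genes = {
        g: float(b)
        for g, b in zip(genes, rng.lognormal(0.0, config.baseline_sigma, len(genes)))
    }
    n_de = int(round(config.frac_de * len(genes)))
    chosen = [str(g) for g in rng.choice(genes, size=n_de, replace=False)]
    de_genes = _balanced_signs(chosen, baseline_genes, config.log2_effect)

    mirnas = sorted(genome.mirna_catalog.mature)
    baseline_mirnas = {
        m: float(b)
        for m, b in zip(mirnas, rng.lognormal(0.0, config.baseline_sigma, len(mirnas)))
    }
    cluster = list(genome.mirna_catalog.cluster_members)
    preset = {m: -config.log2_effect for m in cluster}
    others = [m for m in mirnas if m not in preset]
    n_de_m = int(round(config.frac_de * len(others)))
    chosen_m = [str(m) for m in rng.choice(others, size=n_de_m, replace=False)]
    de_mirnas = _balanced_signs(chosen_m, baseline_mirnas, config.log2_effect, preset)

    hp = genome.hairpin_loci
    recurrent = hp[hp["kind"] == "recurrent"]
    loci = [
        (r.chrom, int(r.start), int(r.end), r.strand)
        for r in recurrent.itertuples(index=False)
    ]
    return TruthSet(
        de_genes=de_genes,
        de_mirnas=de_mirnas,
        novel_hairpin_loci=loci,
        cluster_mirnas=cluster,
        baseline_genes=baseline_genes,
        baseline_mirnas=baseline_mirnas,
    )


@dataclass
class SampleTagTruth:
    """Generator-side bookkeeping for one tag library."""

    gene_tag: dict[str, str]
    gene_counts: dict[str, int]      # counts placed on each gene's canonical tag
    n_mass: int                       # tag mass carrying 'N'
    adapter_mass: int                 # adapter-derived tag mass
    error_mass: int                   # mass moved onto mutated tags
    clean_mass: int                   # mass surviving the clean-tag filter,
                                      # per the generator's own accounting
    novel_tag_counts: dict[str, int]  # planted intergenic tag -> count


def _gene_tag(transcript: str) -> str:
    """3'-most CATG tag with a full 17 nt downstream (guaranteed to exist)."""
    pos = transcript.rfind(TAG_ANCHOR)
    while pos != -1:
        if pos + TAG_LEN <= len(transcript):
            return transcript[pos : pos + TAG_LEN]
        pos = transcript.rfind(TAG_ANCHOR, 0, pos)
    raise AssertionError("transcript lost its planted CATG site")


def simulate_tag_libraries(
    genome: Genome,
    truth: TruthSet,
    config: SimulationConfig,
) -> tuple[list[TagLibrary], dict[str, SampleTagTruth]]:
    """Draw raw tag libraries for every sample of every pair.

    Per-gene counts are NB (Poisson at dispersion 0) with mean proportional
    to a shared log-normal baseline, scaled by 2^effect in tumors, summing
    to ``library_size`` in expectation.  Each gene's count lands on its
    3'-most CATG tag.  Artifact mass (N-containing tags, adapter tags,
    single-substitution error copies) is layered on top to exercise the
    clean-tag filter, and a few recurrent intergenic "novel" tags are
    planted for the novel-tag screen.

    Returns the raw libraries (sample ids ``K<i>T``/``K<i>N``) and per-sample
    bookkeeping used as the oracle by round-trip tests.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_TAGS)
    genes = sorted(genome.transcripts)
    tags = {g: _gene_tag(genome.transcripts[g]) for g in genes}
    baseline = np.array([truth.baseline_genes[g] for g in genes])
    base_total = baseline.sum()

    # planted recurrent intergenic tags (CATG + 17nt from chr2 spacer regions)
    novel_tags = _plant_novel_tags(genome, rng, config.n_novel_tags)

    libraries: list[TagLibrary] = []
    truths: dict[str, SampleTagTruth] = {}
    for pair in range(1, config.n_pairs + 1):
        for condition in ("tumor", "normal"):
            sample_id = f"K{pair}{'T' if condition == 'tumor' else 'N'}"
            factor = np.array(
                [
                    2.0 ** truth.effect(g) if condition == "tumor" else 1.0
                    for g in genes
                ]
            )
            # normalize by the baseline mass: planted effects are
            # mass-balanced, so this keeps null proportions identical
            # across conditions while totals stay within ~0.1%
            props = baseline * factor / base_total
            mu = props * config.library_size
            if config.dispersion == 0:
                counts = rng.poisson(mu)
            else:
                shape = 1.0 / config.dispersion
                lam = rng.gamma(shape, mu * config.dispersion)
                counts = rng.poisson(lam)

            raw: Counter = Counter()
            gene_counts: dict[str, int] = {}
            error_mass = 0
            mutant_counter: Counter = Counter()
            for g, c in zip(genes, counts):
                c = int(c)
                if c == 0:
                    continue
                n_err = 0
                if config.error_rate > 0:
                    p_any = 1.0 - (1.0 - config.error_rate) ** TAG_LEN
                    n_err = int(rng.binomial(c, p_any))
                clean_c = c - n_err
                if clean_c > 0:
                    raw[tags[g]] += clean_c
                gene_counts[g] = clean_c
                for _ in range(n_err):
                    t = tags[g]
                    i = int(rng.integers(0, TAG_LEN))
                    alt = "ACGT"[int(rng.integers(0, 4))]
                    while alt == t[i]:
                        alt = "ACGT"[int(rng.integers(0, 4))]
                    mutant_counter[t[:i] + alt + t[i + 1 :]] += 1
                error_mass += n_err
            raw.update(mutant_counter)

            # planted novel intergenic tags, well above 1 TPM
            novel_counts: dict[str, int] = {}
            for t in novel_tags:
                c = int(rng.integers(20, 61))
                raw[t] += c
                novel_counts[t] = c

            # artifacts
            n_mass = 0
            target = int(config.artifact_n_fraction * config.library_size)
            while n_mass < target:
                t = list(_random_dna(rng, TAG_LEN))
                t[int(rng.integers(0, TAG_LEN))] = "N"
                c = int(rng.integers(2, 6))
                raw["".join(t)] += c
                n_mass += c
            adapter_mass = 0
            target = int(config.artifact_adapter_fraction * config.library_size)
            if target > 0:
                at = config.adapter_sequence[:TAG_LEN]
                raw[at] += target
                adapter_mass = target

            clean_mass = (
                sum(c for c in gene_counts.values() if c > 1)
                + sum(c for c in mutant_counter.values() if c > 1)
                + sum(c for c in novel_counts.values() if c > 1)
            )
            lib = TagLibrary(sample_id, condition, f"K{pair}", raw)
            libraries.append(lib)
            truths[sample_id] = SampleTagTruth(
                gene_tag=dict(tags),
                gene_counts=gene_counts,
                n_mass=n_mass,
                adapter_mass=adapter_mass,
                error_mass=error_mass,
                clean_mass=clean_mass,
                novel_tag_counts=novel_counts,
            )
    return libraries, truths


def _plant_novel_tags(genome: Genome, rng: np.random.Generator, n: int) -> list[str]:
    """Pick CATG+17 tags from intergenic chr2 sequence absent from transcripts."""
    seq = genome.sequences["chr2"]
    transcript_tags = {
        _gene_tag(t) for t in genome.transcripts.values()
    }
    out: list[str] = []
    positions = [i for i in range(len(seq) - TAG_LEN) if seq.startswith(TAG_ANCHOR, i)]
    rng.shuffle(positions)
    for i in positions:
        t = seq[i : i + TAG_LEN]
        if "N" not in t and t not in transcript_tags and t not in out:
            out.append(t)
        if len(out) == n:
            break
    return out


@dataclass
class SmallRnaTruth:
    """Generator-side bookkeeping for the small-RNA stage."""

    mirna_counts: dict[str, dict[str, int]]     # sample -> miRNA -> reads
    hairpin_samples: dict[str, list[str]]       # hairpin_id -> expressing samples
    hairpin_counts: dict[str, dict[str, int]]   # sample -> hairpin_id -> reads
    decoy_counts: dict[str, int]                # sample -> decoy ncRNA reads
    n_ge18: dict[str, int]                      # sample -> reads with insert >= 18 nt


def simulate_smallrna_reads(
    genome: Genome,
    truth: TruthSet,
    config: SimulationConfig,
) -> tuple[dict[str, list[tuple[str, str, str]]], SmallRnaTruth]:
    """Emit adapter-ligated small-RNA reads per sample.

    Each read is an insert (mature miRNA, planted-hairpin arm, decoy ncRNA
    fragment, or deliberately short fragment) followed by the 3' adapter,
    truncated to ``read_length`` with constant Phred quality.  miRNA
    abundances follow the planted effects in tumors; recurrent hairpins are
    expressed in ``hairpin_samples`` samples, singleton hairpins in one, and
    non-hairpin decoy loci in ``hairpin_samples`` samples (they must fail
    only the hairpin criterion).  Returns per-sample (id, sequence, quality)
    triples and the bookkeeping truth.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_SMALLRNA)
    catalog = genome.mirna_catalog
    mirnas = sorted(catalog.mature)
    baseline = np.array([truth.baseline_mirnas[m] for m in mirnas])

    samples = [
        f"K{p}{suffix}" for p in range(1, config.n_pairs + 1) for suffix in ("T", "N")
    ]
    hp = genome.hairpin_loci
    hairpin_samples: dict[str, list[str]] = {}
    for row in hp.itertuples(index=False):
        if row.kind == "singleton":
            k = 1
        else:
            k = min(config.hairpin_samples, len(samples))
        chosen = sorted(rng.choice(samples, size=k, replace=False).tolist())
        hairpin_samples[row.hairpin_id] = chosen

    hairpin_arm: dict[str, str] = {}
    for row in hp.itertuples(index=False):
        locus = genome.sequences[row.chrom][row.start : row.end]
        hairpin_arm[row.hairpin_id] = locus[:22]  # 5' arm read

    reads: dict[str, list[tuple[str, str, str]]] = {}
    mirna_counts: dict[str, dict[str, int]] = {}
    hairpin_counts: dict[str, dict[str, int]] = {}
    decoy_counts: dict[str, int] = {}
    n_ge18: dict[str, int] = {}
    qual = "I" * config.read_length
    decoy_pool = [s for cat in sorted(genome.decoys) for s in genome.decoys[cat]]

    for sample in samples:
        condition = "tumor" if sample.endswith("T") else "normal"
        factor = np.array(
            [
                2.0 ** truth.effect(m) if condition == "tumor" else 1.0
                for m in mirnas
            ]
        )
        props = baseline * factor
        props /= props.sum()
        n_decoy = int(config.decoy_fraction * config.smallrna_library_size)
        n_short = int(config.short_insert_fraction * config.smallrna_library_size)
        n_hp_each = 400  # well above the 1 TPM detectability floor
        n_mirna = config.smallrna_library_size - n_decoy - n_short
        counts = rng.multinomial(n_mirna, props)

        sample_reads: list[tuple[str, str, str]] = []
        per_mirna: dict[str, int] = {}
        ge18 = 0
        rid = 0

        def _emit(insert: str) -> None:
            nonlocal rid, ge18
            full = (insert + config.adapter_sequence)[: config.read_length]
            if config.error_rate > 0:
                full = _mutate(full, config.error_rate, rng)
            sample_reads.append((f"{sample}_{rid:06d}", full, qual[: len(full)]))
            rid += 1
            if len(insert) >= 18:
                ge18 += 1

        for m, c in zip(mirnas, counts):
            if c > 0:
                per_mirna[m] = int(c)
                for _ in range(int(c)):
                    _emit(catalog.mature[m])
        per_hp: dict[str, int] = {}
        for hid, expressing in sorted(hairpin_samples.items()):
            if sample in expressing:
                per_hp[hid] = n_hp_each
                for _ in range(n_hp_each):
                    _emit(hairpin_arm[hid])
        for _ in range(n_decoy):
            src = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
            ln = int(rng.integers(19, 29))
            start = int(rng.integers(0, len(src) - ln))
            _emit(src[start : start + ln])
        for _ in range(n_short):
            m = mirnas[int(rng.integers(0, len(mirnas)))]
            ln = int(rng.integers(12, 18))
            _emit(catalog.mature[m][:ln])

        reads[sample] = sample_reads
        mirna_counts[sample] = per_mirna
        hairpin_counts[sample] = per_hp
        decoy_counts[sample] = n_decoy
        n_ge18[sample] = ge18

    return reads, SmallRnaTruth(
        mirna_counts=mirna_counts,
        hairpin_samples=hairpin_samples,
        hairpin_counts=hairpin_counts,
        decoy_counts=decoy_counts,
        n_ge18=n_ge18,
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            alt = "ACGT"[int(rng.integers(0, 4))]
            while alt == out[i]:
                alt = "ACGT"[int(rng.integers(0, 4))]
            out[i] = alt
    return "".join(out)


def simulate_gene_sets(genome: Genome, truth: TruthSet, config: SimulationConfig):
    """Gene-set collection with two planted enriched sets.

    Background sets draw members uniformly; the two planted sets draw 70%
    of members from DE genes (one biased toward upregulated genes, one
    toward downregulated).  A subset of sets (including the first planted
    one) carries the "cancer" label.  Truth records the planted set ids and
    their directions.
    """
    from .pathways import GeneSetCollection

    rng = _rng(config.seed, _STAGE_SETS)
    genes = sorted(genome.transcripts)
    de_up = sorted(g for g, e in truth.de_genes.items() if e > 0)
    de_down = sorted(g for g, e in truth.de_genes.items() if e < 0)
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    planted: list[tuple[str, str]] = []
    for i in range(config.n_gene_sets):
        sid = f"PW{i + 1:03d}"
        size = max(5, int(rng.normal(config.gene_set_size, 5)))
        if i < 2 and de_up and de_down:
            direction = "up" if i == 0 else "down"
            pool = de_up if direction == "up" else de_down
            n_sig = min(len(pool), int(round(0.7 * size)))
            chosen = set(rng.choice(pool, size=n_sig, replace=False).tolist())
            rest = [g for g in genes if g not in chosen]
            chosen |= set(rng.choice(rest, size=size - n_sig, replace=False).tolist())
            planted.append((sid, direction))
        else:
            chosen = set(rng.choice(genes, size=min(size, len(genes)), replace=False).tolist())
        sets[sid] = frozenset(chosen)
        names[sid] = f"pathway_{i + 1}"
    cancer = {f"PW{i + 1:03d}" for i in range(min(config.n_cancer_sets, config.n_gene_sets))}
    truth.enriched_sets = planted
    return GeneSetCollection(sets, names, frozenset(genes), frozenset(cancer))


def simulate_target_map(genome: Genome, truth: TruthSet, config: SimulationConfig):
    """miRNA target tables: experimental plus two overlapping predictions.

    Deregulated miRNAs preferentially target oppositely-deregulated genes
    (repression logic); the positional-cluster miRNAs receive
    prediction-only targets, mirroring the poorly annotated family the
    analysis handles via a prediction intersection.  Returns
    ``(TargetMap, experimental_df, predicted_a_df, predicted_b_df)``.
    """
    from .pathways import TargetMap

    rng = _rng(config.seed, _STAGE_TARGETS)
    genes = sorted(genome.transcripts)
    mirnas = sorted(genome.mirna_catalog.mature)
    cluster = set(truth.cluster_mirnas)
    exp_rows, pa_rows, pb_rows = [], [], []
    for m in mirnas:
        n_targets = int(rng.integers(8, 20))
        effect = truth.effect(m)
        if effect != 0:
            opposite = [g for g, e in truth.de_genes.items() if e * effect < 0]
            n_sig = min(len(opposite), int(round(0.6 * n_targets)))
            chosen = list(rng.choice(sorted(opposite), size=n_sig, replace=False)) if n_sig else []
            rest = [g for g in genes if g not in chosen]
            chosen += list(rng.choice(rest, size=n_targets - len(chosen), replace=False))
        else:
            chosen = list(rng.choice(genes, size=n_targets, replace=False))
        for g in chosen:
            if m in cluster:
                pa_rows.append((m, g))
                pb_rows.append((m, g))
            else:
                exp_rows.append((m, g))
        # prediction noise present in table A only (should not intersect B)
        for g in rng.choice(genes, size=5, replace=False):
            pa_rows.append((m, str(g)))
    exp = pd.DataFrame(sorted(set(exp_rows)), columns=["mirna_id", "gene_id"])
    pa = pd.DataFrame(sorted(set(pa_rows)), columns=["mirna_id", "gene_id"])
    pb = pd.DataFrame(sorted(set(pb_rows)), columns=["mirna_id", "gene_id"])
    return TargetMap.from_tables(exp, pa, pb), exp, pa, pb


def simulate_mirna_calls(
    genome: Genome,
    truth: TruthSet,
    config: SimulationConfig,
    null: bool = False,
    down_rate: float = 0.35,
    up_rate: float = 0.25,
    cluster_down_prob: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Light-weight per-miRNA call profile for positional-cluster benchmarks.

    Draws a single down/up/ns status per miRNA at the given background
    rates.  Unless ``null``, planted cluster members are called down with
    ``cluster_down_prob`` (default 1: the planted cluster is coherently
    downregulated, matching how it is planted; lower values probe
    robustness to call noise).  This skips the full count pipeline so the
    cluster scan can be calibrated over many replicates.
    """
    if rng is None:
        rng = _rng(config.seed, _STAGE_CALLS)
    status: dict[str, str] = {}
    cluster = set() if null else set(truth.cluster_mirnas)
    for m in sorted(genome.mirna_catalog.mature):
        if m in cluster:
            status[m] = "down" if rng.random() < cluster_down_prob else "ns"
            continue
        u = rng.random()
        if u < down_rate:
            status[m] = "down"
        elif u < down_rate + up_rate:
            status[m] = "up"
        else:
            status[m] = "ns"
    return status


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: genome, truth, and all simulated inputs.

    Returns a dict with keys genome, truth, tag_libraries, tag_truth,
    smallrna_reads, smallrna_truth, gene_sets, target_map (plus the raw
    target tables).
    """
    genome = simulate_genome(config)
    truth = plant_truth(genome, config)
    libraries, tag_truth = simulate_tag_libraries(genome, truth, config)
    reads, sr_truth = simulate_smallrna_reads(genome, truth, config)
    gene_sets = simulate_gene_sets(genome, truth, config)
    target_map, exp, pa, pb = simulate_target_map(genome, truth, config)
    return {
        "genome": genome,
        "truth": truth,
        "tag_libraries": libraries,
        "tag_truth": tag_truth,
        "smallrna_reads": reads,
        "smallrna_truth": sr_truth,
        "gene_sets": gene_sets,
        "target_map": target_map,
        "target_tables": (exp, pa, pb),
    }
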