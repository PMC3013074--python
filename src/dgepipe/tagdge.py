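"""NlaIII tag-based digital gene expression quantification.

A DGE tag is the 4-bp NlaIII recognition site (CATG) plus the 17 bp
immediately downstream, 21 nt in total.  Expression is measured by counting
tags against a *virtual tag reference*: every CATG site in every annotated
transcript contributes one 21-nt tag keyed to its gene.  Raw tag multisets
are filtered (N-containing, adapter-derived, single-copy), mapped with at
most one base mismatch requiring a unique gene assignment, and normalized to
TPM (tags per million clean tags).  Tags that map nowhere in the index but do
hit the genome (and not the mitochondrion) are screened as novel expression
tags when they recur at >=1 TPM in >=2 samples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

TAG_ANCHOR = "CATG"
TAG_DOWNSTREAM = 17
TAG_LEN = len(TAG_ANCHOR) + TAG_DOWNSTREAM  # 21

_ALPHABET = "ACGT"

__all__ = [
    "TAG_LEN",
    "VirtualTagIndex",
    "TagLibrary",
    "build_virtual_tag_index",
    "filter_clean_tags",
    "map_tags",
    "MapResult",
    "tpm",
    "discover_novel_tags",
]


@dataclass
class VirtualTagIndex:
    """Tag sequence -> gene-id set, over all extractable CATG sites.

    ``tags`` maps each 21-nt tag to the set of gene ids whose transcripts
    contain it; tags shared by more than one gene are kept but flagged
    ambiguous (they can never yield a unique assignment).
    """

    tags: dict[str, frozenset[str]]
    build_label: str = "synthetic"
    annotation_label: str = "synthetic"

    @property
    def ambiguous(self) -> set[str]:
        return {t for t, genes in self.tags.items() if len(genes) > 1}

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags


@dataclass
class TagLibrary:
    """Per-sample multiset of tags with the clean-tag total.

    ``clean_total`` is the denominator of TPM and the ``N`` of the AC test;
    it is set by :func:`filter_clean_tags` (None for raw libraries).
    """

    sample_id: str
    condition: str  # "tumor" | "normal"
    pair_id: str
    counts: Counter = field(default_factory=Counter)
    clean_total: int | None = None

    def total(self) -> int:
        return sum(self.counts.values())


def build_virtual_tag_index(
    reference: Mapping[str, str],
    annotation: pd.DataFrame,
    build_label: str = "synthetic",
    annotation_label: str = "synthetic",
) -> VirtualTagIndex:
    """Extract CATG+17nt virtual tags from annotated transcripts.

    Every occurrence of CATG on the transcript sense strand with >=17 nt
    downstream yields one tag assigned to the transcript's gene.  Annotation
    columns: chrom, start, end, strand, gene_id, transcript_id (0-based
    half-open).  An empty annotation yields an empty index.

    Raises ValueError when an interval exceeds the reference bounds.
    """
    tags: dict[str, set[str]] = {}
    for row in annotation.itertuples(index=False):
        seq = reference[row.chrom]
        if row.start < 0 or row.end > len(seq):
            raise ValueError(
                f"annotation interval {row.chrom}:{row.start}-{row.end} "
                f"outside reference (len {len(seq)})"
            )
        t = seq[row.start : row.end]
        if row.strand == "-":
            t = revcomp(t)
        pos = t.find(TAG_ANCHOR)
        while pos != -1:
            if pos + TAG_LEN <= len(t):
                tags.setdefault(t[pos : pos + TAG_LEN], set()).add(row.gene_id)
            pos = t.find(TAG_ANCHOR, pos + 1)
    return VirtualTagIndex(
        tags={t: frozenset(g) for t, g in tags.items()},
        build_label=build_label,
        annotation_label=annotation_label,
    )


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def filter_clean_tags(
    raw: Mapping[str, int],
    adapter_sequence: str,
    sample_id: str = "",
    condition: str = "",
    pair_id: str = "",
) -> TagLibrary:
    """Remove erroneous tags and compute the clean-tag total.

    Filter order is fixed (it affects the clean total and is part of the
    contract): (1) tags containing 'N'; (2) tags equal to, or a prefix of,
    the sequencing adapter; (3) single-copy tags.  ``clean_total`` is the
    summed count of everything retained.
    """
    step1 = {t: c for t, c in raw.items() if "N" not in t}
    step2 = {t: c for t, c in step1.items() if not adapter_sequence.startswith(t)}
    step3 = {t: c for t, c in step2.items() if c > 1}
    lib = TagLibrary(sample_id, condition, pair_id, Counter(step3))
    lib.clean_total = sum(step3.values())
    return lib


def _neighbors(tag: str) -> Iterable[str]:
    """All sequences at Hamming distance exactly 1 from ``tag``."""
    for i, base in enumerate(tag):
        for alt in _ALPHABET:
            if alt != base:
                yield tag[:i] + alt + tag[i + 1 :]


@dataclass
class MapResult:
    """Outcome of mapping one library against the virtual tag index."""

    gene_counts: Counter          # gene -> uniquely mapped tag count
    unmapped: Counter             # tag -> count (no unique gene)
    rejected: Counter             # tag -> count (wrong length)

    def assigned_mass(self) -> int:
        return sum(self.gene_counts.values())


def map_tags(library: TagLibrary, index: VirtualTagIndex) -> MapResult:
    """Assign clean tags to genes allowing at most one mismatch, unique hits only.

    A tag counts for a gene iff the union of index entries within Hamming
    distance <=1 resolves to exactly one gene; exact matches take precedence
    over 1-mismatch matches.  Tags hitting >=2 genes (or an ambiguous index
    key) are unmapped.  Tags that are not 21 nt are rejected with a per-tag
    diagnostic count.  Mass is conserved: assigned + unmapped + rejected
    equals the library total.
    """
    gene_counts: Counter = Counter()
    unmapped: Counter = Counter()
    rejected: Counter = Counter()
    for tag, count in library.counts.items():
        if len(tag) != TAG_LEN:
            rejected[tag] += count
            continue
        genes = index.tags.get(tag)
        if genes is None:
            hit: set[str] = set()
            for nb in _neighbors(tag):
                g = index.tags.get(nb)
                if g is not None:
                    hit.update(g)
                    if len(hit) > 1:
                        break
            genes = frozenset(hit)
        if len(genes) == 1:
            gene_counts[next(iter(genes))] += count
        else:
            unmapped[tag] += count
    return MapResult(gene_counts, unmapped, rejected)


def tpm(count: int, clean_total: int) -> float:
    """Tags per million clean tags: ``count * 1e6 / clean_total``."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive (empty library?)")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e6 / clean_total


def _kmer_set(sequences: Iterable[str], k: int = TAG_LEN) -> set[str]:
    kmers: set[str] = set()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i : i + k])
        rc = revcomp(seq)
        for i in range(len(rc) - k + 1):
            kmers.add(rc[i : i + k])
    return kmers


def _hits_within_1(tag: str, kmers: set[str]) -> bool:
    if tag in kmers:
        return True
    return any(nb in kmers for nb in _neighbors(tag))


def discover_novel_tags(
    unmapped: Mapping[str, Mapping[str, int]],
    clean_totals: Mapping[str, int],
    index: VirtualTagIndex,
    mito_sequence: str,
    genome: Mapping[str, str],
    min_samples: int = 2,
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Screen unmapped tags for recurrent novel mRNA expression tags.

    A tag is reported iff it (a) has no <=1-mismatch hit in the virtual tag
    index, (b) has no <=1-mismatch hit in the mitochondrial sequence, (c) hits
    the nuclear genome exactly or with one mismatch (either strand), and
    (d) reaches ``min_tpm`` TPM in at least ``min_samples`` samples.

    Parameters
    ----------
    unmapped
        sample-id -> (tag -> count), the unmapped output of :func:`map_tags`.
    clean_totals
        sample-id -> clean-tag total, for TPM.

    Returns a DataFrame with tag, n_samples_detected, per-sample TPM columns
    (``tpm_<sample>``) and genomic hit coordinates of the exact hit when one
    exists (chrom, pos, strand; -1/"." for mismatch-only hits).
    """
    samples = sorted(unmapped)
    mito_kmers = _kmer_set([mito_sequence])
    candidate_tags = sorted({t for per in unmapped.values() for t in per})

    index_keys = set(index.tags)
    genome_items = [(c, s) for c, s in genome.items()]
    genome_kmers = _kmer_set(s for _, s in genome_items)

    rows = []
    for tag in candidate_tags:
        if len(tag) != TAG_LEN:
            continue
        if _hits_within_1(tag, index_keys):
            continue
        if _hits_within_1(tag, mito_kmers):
            continue
        if not _hits_within_1(tag, genome_kmers):
            continue
        tpms = {
            s: tpm(unmapped[s].get(tag, 0), clean_totals[s]) for s in samples
        }
        n_detected = sum(1 for v in tpms.values() if v >= min_tpm)
        if n_detected < min_samples:
            continue
        chrom, pos, strand = "", -1, "."
        for c, s in genome_items:
            i = s.find(tag)
            if i != -1:
                chrom, pos, strand = c, i, "+"
                break
            i = s.find(revcomp(tag))
            if i != -1:
                chrom, pos, strand = c, i, "-"
                break
        row = {
            "tag": tag,
            "n_samples_detected": n_detected,
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
        }
        row.update({f"tpm_{s}": tpms[s] for s in samples})
        rows.append(row)
    cols = ["tag", "n_samples_detected", "chrom", "pos", "strand"] + [
        f"tpm_{s}" for s in samples
    ]
    return pd.DataFrame(rows, columns=cols)
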