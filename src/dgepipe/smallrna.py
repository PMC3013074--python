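"""Small-RNA read processing and novel miRNA candidate evaluation.

The stage mirrors a small-RNA DGE workflow: 3' sequencing adapters are
clipped by a gap-free dynamic-programming alignment, reads are collapsed to
unique sequences and length-filtered (>=18 nt), surviving sequences are
assigned to an ordered annotation hierarchy (known miRNA first, then rRNA,
tRNA, snRNA, snoRNA, repeats, mRNA), and the unannotated remainder is
screened for novel miRNA hairpins.

A locus is accepted as a high-confidence novel miRNA candidate when
(1) its extended genomic sequence folds into a stable single stem-loop with
free energy below −20 kcal/mol, (2) the read stack sits on one arm of that
stem with tightly clustered 5' ends (a Dicer-product proxy), and (3) it is
expressed at >=1 TPM in at least two samples.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import pandas as pd

from .fold import default_folder, stem_pairs
from .tagdge import revcomp

__all__ = [
    "clip_adapter",
    "dedup_and_filter",
    "SmallRnaLibrary",
    "AnnotationHierarchy",
    "assign_annotation",
    "MirnaCandidate",
    "evaluate_novel_candidates",
]

CATEGORY_ORDER = ("known-miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA")


@lru_cache(maxsize=500_000)
def clip_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.2,
) -> str:
    """Clip a 3' adapter from a read by best gap-free semi-global alignment.

    Every clip position aligns a prefix of the adapter against the read
    suffix starting there (match +1, mismatch −1, no gaps).  The read is cut
    at the best-scoring position provided the overlap is at least
    ``min_overlap`` and the mismatch fraction is at most
    ``max_mismatch_rate``; ties prefer the earlier (more aggressive) cut.
    Reads with no acceptable adapter signal are returned unchanged.
    """
    if not read or not adapter:
        raise ValueError("read and adapter must be non-empty")
    best_score = None
    best_pos = len(read)
    for start in range(len(read) - min_overlap + 1):
        overlap = min(len(read) - start, len(adapter))
        mismatches = sum(
            1 for a, b in zip(read[start : start + overlap], adapter[:overlap]) if a != b
        )
        if mismatches > max_mismatch_rate * overlap:
            continue
        score = (overlap - mismatches) - mismatches
        if best_score is None or score > best_score:
            best_score = score
            best_pos = start
    return read[:best_pos]


@dataclass
class SmallRnaLibrary:
    """Collapsed small-RNA library: unique insert -> read count."""

    sample_id: str
    condition: str
    counts: Counter = field(default_factory=Counter)
    clean_total: int = 0


def dedup_and_filter(
    reads: Iterable[str],
    min_len: int = 18,
    sample_id: str = "",
    condition: str = "",
) -> SmallRnaLibrary:
    """Collapse identical sequences and drop those shorter than ``min_len``.

    ``clean_total`` is the number of retained reads (not unique sequences).
    """
    counts = Counter(r for r in reads if len(r) >= min_len)
    return SmallRnaLibrary(sample_id, condition, counts, sum(counts.values()))


@dataclass
class AnnotationHierarchy:
    """Ordered non-miRNA annotation collections for hierarchical assignment.

    ``categories`` maps category name -> reference sequences; lookups follow
    the fixed CATEGORY_ORDER, and a read is assigned to the first category
    whose reference contains it as a substring (either strand).  Known-miRNA
    assignment is handled separately (isomiR-aware) and always takes
    precedence.
    """

    categories: dict[str, list[str]] = field(default_factory=dict)

    def match_category(self, seq: str) -> str | None:
        rc = revcomp(seq)
        for cat in CATEGORY_ORDER:
            if cat == "known-miRNA":
                continue
            for ref in self.categories.get(cat, ()):
                if seq in ref or rc in ref:
                    return cat
        return None


def _match_mirna(
    seq: str,
    mature: Mapping[str, str],
    precursor_context: Mapping[str, str] | None,
    iso_3p: int,
) -> str | None:
    """Return the miRNA id matched exactly or with a <=iso_3p-nt 3' offset.

    3' trimmings of the mature sequence are always accepted; 3' extensions
    must be templated (match the precursor continuation) when precursor
    context is available, otherwise any extension of tolerated length counts.
    """
    for mid, m in mature.items():
        if seq == m:
            return mid
        for d in range(1, iso_3p + 1):
            if len(m) - d >= 1 and seq == m[:-d]:
                return mid
        if iso_3p and seq.startswith(m) and 0 < len(seq) - len(m) <= iso_3p:
            if precursor_context is None:
                return mid
            pre = precursor_context.get(mid)
            if pre is None:
                return mid
            i = pre.find(m)
            if i != -1 and pre[i : i + len(seq)] == seq:
                return mid
    return None


def assign_annotation(
    library: SmallRnaLibrary,
    hierarchy: AnnotationHierarchy,
    mature_mirnas: Mapping[str, str],
    precursors: Mapping[str, str] | None = None,
    iso_3p: int = 2,
) -> tuple[pd.Series, Counter, Counter]:
    """Partition a library across the annotation hierarchy.

    Returns ``(category_counts, mirna_counts, unannotated)`` where
    category_counts (reads, not unique sequences) covers every category plus
    "unannotated" and sums to ``clean_total``; mirna_counts aggregates reads
    per known mature miRNA (isomiRs with a ±``iso_3p``-nt 3' offset included);
    unannotated maps the remaining unique sequences to counts.
    """
    cat_counts = {c: 0 for c in CATEGORY_ORDER}
    cat_counts["unannotated"] = 0
    mirna_counts: Counter = Counter()
    unannotated: Counter = Counter()
    for seq, count in library.counts.items():
        mid = _match_mirna(seq, mature_mirnas, precursors, iso_3p)
        if mid is not None:
            cat_counts["known-miRNA"] += count
            mirna_counts[mid] += count
            continue
        cat = hierarchy.match_category(seq)
        if cat is not None:
            cat_counts[cat] += count
        else:
            cat_counts["unannotated"] += count
            unannotated[seq] += count
    return pd.Series(cat_counts), mirna_counts, unannotated


@dataclass
class MirnaCandidate:
    """A candidate novel miRNA locus with its evaluation flags."""

    chrom: str
    start: int
    end: int
    strand: str
    precursor: str
    mature_arm: str
    mfe: float
    tpm: dict[str, float]
    n_samples_detected: int
    hairpin_ok: bool
    energy_ok: bool
    recurrence_ok: bool
    structure: str = ""

    @property
    def reported(self) -> bool:
        return self.hairpin_ok and self.energy_ok and self.recurrence_ok


def _read_arm_chain(
    pairs: list[tuple[int, int]],
    read_lo: int,
    read_hi: int,
) -> tuple[int, float, bool, float, int] | None:
    """Locate the stem-loop whose arm carries the read stack.

    A stem-loop is a maximal chain of nested pairs around one hairpin loop
    (built loop-outward and capped at any multiloop branching).  Returns
    ``(chain_pairs, pairing_density, on_one_arm, read_paired_frac)`` for the
    deepest chain whose 5' or 3' arm contains the read interval, or None.
    ``(chain_pairs, pairing_density, on_one_arm, read_paired_frac,
    max_stack)`` — pairing_density is paired positions over the span of the
    outermost pair (genuine hairpins are compact, cascades of short helices
    separated by large loops are not); read_paired_frac is the fraction of
    read positions base-paired within the chain (the mature arm of a Dicer
    substrate is nearly fully paired to its star arm); max_stack is the
    longest uninterrupted helix, which separates true inverted repeats from
    incidental bulgy stems in random sequence.
    """
    if not pairs:
        return None
    pset = sorted(pairs)
    # immediate parent = smallest pair strictly enclosing; a pair whose
    # enclosed region branches (>1 child) caps the stem-loop: outer pairs
    # of a multiloop belong to no single hairpin
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children: dict[tuple[int, int], int] = {p: 0 for p in pset}
    for p in pset:
        enclosing = [q for q in pset if q[0] < p[0] and p[1] < q[1]]
        par = min(enclosing, key=lambda q: q[1] - q[0]) if enclosing else None
        parent[p] = par
        if par is not None:
            children[par] += 1
    best = None
    for p0 in (p for p in pset if children[p] == 0):
        chain = [p0]
        node = p0
        while parent[node] is not None and children[parent[node]] == 1:
            par = parent[node]
            # helix continuation tolerates only small bulges/interior loops;
            # a distant lone enclosing pair is not part of the stem
            gap = (node[0] - par[0] - 1) + (par[1] - node[1] - 1)
            if gap > 10:
                break
            node = par
            chain.append(node)
        i_out, j_out = chain[-1]
        i0, j0 = p0
        # the read may overhang the helix by a few unpaired nucleotides;
        # require 80% of the read inside one arm, and never both arms
        rlen = max(1, read_hi - read_lo)
        ov5 = max(0, min(read_hi, i0 + 1) - max(read_lo, i_out))
        ov3 = max(0, min(read_hi, j_out + 1) - max(read_lo, j0))
        on5 = ov5 >= 0.8 * rlen
        on3 = ov3 >= 0.8 * rlen
        if not (on5 or on3):
            continue
        density = 2 * len(chain) / (j_out - i_out + 1)
        paired = {a for a, _ in chain} | {b for _, b in chain}
        read_paired_frac = (
            sum(1 for p in range(read_lo, read_hi) if p in paired) / rlen
        )
        # longest uninterrupted helix within the chain
        ordered = sorted(chain)
        max_stack = run = 1
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            run = run + 1 if (a2, b2) == (a1 + 1, b1 - 1) else 1
            max_stack = max(max_stack, run)
        cand = (len(chain), density, on5 != on3, read_paired_frac, max_stack)
        if best is None or cand[0] > best[0]:
            best = cand
    return best


def evaluate_novel_candidates(
    unannotated: Mapping[str, Mapping[str, int]],
    clean_totals: Mapping[str, int],
    genome: Mapping[str, str],
    folder=None,
    min_samples: int = 2,
    min_tpm: float = 1.0,
    energy_threshold: float = -20.0,
    extend: int = 70,
    cluster_gap: int = 30,
    min_stem_pairs: int = 16,
    min_density: float = 0.5,
    min_read_paired: float = 0.75,
    min_stack: int = 15,
) -> list[MirnaCandidate]:
    """Screen unannotated small-RNA sequences for novel miRNA hairpins.

    Unique sequences are placed on the genome by exact match (either
    strand), placements are clustered into loci (gap <= ``cluster_gap``),
    each locus is extended by ``extend`` nt on both sides and folded.
    Flags per candidate:

    * ``hairpin_ok`` — the structure contains a stem-loop of at least
      ``min_stem_pairs`` base pairs with pairing density >= ``min_density``,
      containing an uninterrupted helix of >= ``min_stack`` bp, the read
      stack lies on one arm with >= ``min_read_paired`` of its positions
      base-paired, and read 5' ends cluster within a 3-nt window
      (Dicer-product proxy).  A folding failure sets this flag false rather
      than raising.
    * ``energy_ok`` — folding energy strictly below ``energy_threshold``
      (kcal/mol).
    * ``recurrence_ok`` — locus TPM >= ``min_tpm`` in >= ``min_samples``
      samples.

    All candidates are returned with their flags; only fully-flagged ones
    count as reported (``MirnaCandidate.reported``).
    """
    if folder is None:
        folder = default_folder()
    samples = sorted(unannotated)

    # place unique sequences on the genome (exact, first hit, either strand)
    placements: list[tuple[str, int, int, str, str]] = []
    all_seqs = sorted({s for per in unannotated.values() for s in per})
    for seq in all_seqs:
        for chrom, ref in genome.items():
            i = ref.find(seq)
            if i != -1:
                placements.append((chrom, i, i + len(seq), "+", seq))
                break
            i = ref.find(revcomp(seq))
            if i != -1:
                placements.append((chrom, i, i + len(seq), "-", seq))
                break

    # cluster placements into loci per chromosome/strand
    by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    for chrom, s, e, strand, seq in placements:
        by_key[(chrom, strand)].append((s, e, seq))
    candidates: list[MirnaCandidate] = []
    for (chrom, strand), items in sorted(by_key.items()):
        items.sort()
        cluster: list[tuple[int, int, str]] = []
        for item in items:
            if cluster and item[0] - max(e for _, e, _ in cluster) > cluster_gap:
                candidates.append(
                    _evaluate_locus(
                        chrom, strand, cluster, unannotated, clean_totals, genome,
                        folder, samples, min_samples, min_tpm, energy_threshold,
                        extend, min_stem_pairs, min_density, min_read_paired,
                        min_stack,
                    )
                )
                cluster = []
            cluster.append(item)
        if cluster:
            candidates.append(
                _evaluate_locus(
                    chrom, strand, cluster, unannotated, clean_totals, genome,
                    folder, samples, min_samples, min_tpm, energy_threshold,
                    extend, min_stem_pairs, min_density, min_read_paired,
                    min_stack,
                )
            )
    return candidates


def _evaluate_locus(
    chrom, strand, cluster, unannotated, clean_totals, genome, folder,
    samples, min_samples, min_tpm, energy_threshold, extend,
    min_stem_pairs, min_density, min_read_paired, min_stack,
) -> MirnaCandidate:
    lo = min(s for s, _, _ in cluster)
    hi = max(e for _, e, _ in cluster)
    ref = genome[chrom]
    ext_lo = max(0, lo - extend)
    ext_hi = min(len(ref), hi + extend)
    window = ref[ext_lo:ext_hi]
    if strand == "-":
        window = revcomp(window)
        read_lo = ext_hi - hi
        read_hi = ext_hi - lo
        starts = sorted(ext_hi - e for _, e, _ in cluster)
    else:
        read_lo = lo - ext_lo
        read_hi = hi - ext_lo
        starts = sorted(s - ext_lo for s, _, _ in cluster)

    hairpin_ok = False
    mfe = 0.0
    structure = ""
    try:
        structure, mfe = folder.fold(window)
        pairs = stem_pairs(structure)
        chain = _read_arm_chain(pairs, read_lo, read_hi)
        five_prime_tight = starts[-1] - starts[0] <= 3
        if chain is not None:
            n_chain, density, one_arm, read_paired, max_stack = chain
            hairpin_ok = (
                n_chain >= min_stem_pairs
                and density >= min_density
                and one_arm
                and read_paired >= min_read_paired
                and max_stack >= min_stack
                and five_prime_tight
            )
    except Exception:
        hairpin_ok = False

    energy_ok = mfe < energy_threshold
    seqs = [seq for _, _, seq in cluster]
    tpms: dict[str, float] = {}
    for s in samples:
        count = sum(unannotated[s].get(q, 0) for q in seqs)
        tpms[s] = count * 1e6 / clean_totals[s]
    n_det = sum(1 for v in tpms.values() if v >= min_tpm)
    mature = max(seqs, key=lambda q: sum(unannotated[s].get(q, 0) for s in samples))
    return MirnaCandidate(
        chrom=chrom,
        start=lo,
        end=hi,
        strand=strand,
        precursor=window,
        mature_arm=mature,
        mfe=mfe,
        tpm=tpms,
        n_samples_detected=n_det,
        hairpin_ok=hairpin_ok,
        energy_ok=energy_ok,
        recurrence_ok=n_det >= min_samples,
        structure=structure,
    )
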