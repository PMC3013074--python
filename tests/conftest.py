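"""Shared fixtures: small synthetic studies and oracle helpers."""

from __future__ import annotations

import math
from fractions import Fraction

import pytest

from dgepipe import tagdge
from dgepipe.simulate import (
    SimulationConfig,
    plant_truth,
    simulate_genome,
    simulate_smallrna_reads,
    simulate_tag_libraries,
)


# ----------------------------------------------------------------- oracles
def ac_probability_exact(y: int, x: int, n1: int, n2: int) -> Fraction:
    """Closed-form conditional probability in exact rational arithmetic."""
    r = Fraction(n2, n1)
    return r**y * math.comb(x + y, y) / (1 + r) ** (x + y + 1)


def ac_test_exact(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided p-value by exact-arithmetic tail summation.

    The lower tail is summed term by term; the upper tail follows from the
    exact normalization of the conditional distribution.
    """
    lower = sum(ac_probability_exact(k, x, n1, n2) for k in range(y + 1))
    upper = 1 - lower + ac_probability_exact(y, x, n1, n2)
    return float(min(Fraction(1), 2 * min(lower, upper)))


def map_tags_brute(library: tagdge.TagLibrary, index: tagdge.VirtualTagIndex):
    """All-pairs Hamming scan with exact-over-1-mismatch precedence."""
    gene_counts: dict[str, int] = {}
    unmapped: dict[str, int] = {}
    rejected: dict[str, int] = {}
    for tag, count in library.counts.items():
        if len(tag) != tagdge.TAG_LEN:
            rejected[tag] = rejected.get(tag, 0) + count
            continue
        if tag in index.tags:
            genes = index.tags[tag]
        else:
            genes = frozenset().union(
                *(
                    g
                    for key, g in index.tags.items()
                    if sum(a != b for a, b in zip(tag, key)) == 1
                ),
                frozenset(),
            )
        if len(genes) == 1:
            (g,) = genes
            gene_counts[g] = gene_counts.get(g, 0) + count
        else:
            unmapped[tag] = unmapped.get(tag, 0) + count
    return gene_counts, unmapped, rejected


def clip_brute(read: str, adapter: str, min_overlap: int = 6, max_mm: float = 0.2) -> str:
    """Independent enumeration of every clip position (oracle for clip_adapter)."""
    best = None
    for start in range(len(read) + 1):
        overlap = min(len(read) - start, len(adapter))
        if overlap < min_overlap:
            continue
        mm = sum(a != b for a, b in zip(read[start : start + overlap], adapter))
        if mm > max_mm * overlap:
            continue
        score = overlap - 2 * mm
        if best is None or score > best[0]:
            best = (score, start)
    return read if best is None else read[: best[1]]


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes=60,
        n_pairs=3,
        n_mirnas=30,
        library_size=50_000,
        smallrna_library_size=20_000,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    genome = simulate_genome(small_config)
    truth = plant_truth(genome, small_config)
    libraries, tag_truth = simulate_tag_libraries(genome, truth, small_config)
    reads, sr_truth = simulate_smallrna_reads(genome, truth, small_config)
    return {
        "config": small_config,
        "genome": genome,
        "truth": truth,
        "libraries": libraries,
        "tag_truth": tag_truth,
        "reads": reads,
        "sr_truth": sr_truth,
    }


@pytest.fixture(scope="session")
def toy_index() -> tagdge.VirtualTagIndex:
    """Three genes; one tag shared between two genes (ambiguous)."""
    t1 = "CATG" + "A" * 17
    t2 = "CATG" + "C" * 17
    shared = "CATG" + "G" * 17
    return tagdge.VirtualTagIndex(
        {
            t1: frozenset({"gA"}),
            t2: frozenset({"gB"}),
            shared: frozenset({"gA", "gC"}),
        }
    )
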