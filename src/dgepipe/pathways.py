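"""Gene-set and positional enrichment analysis.

Covers four stages downstream of differential expression:

* over-representation of deregulated genes in pathway gene sets by a
  right-sided hypergeometric test with Benjamini–Hochberg correction;
* gene set enrichment analysis (GSEA): a weighted Kolmogorov–Smirnov-like
  running sum over a ranked gene list, with the leading-edge subset ("core
  genes") extracted at the running-sum extremum and significance from
  gene-label permutations;
* prioritization of genes and miRNAs by the number of pathways (and of a
  designated cancer subset) in which they, or their targets, appear in the
  leading edge;
* a positional scan for genomic miRNA clusters whose members are
  coherently deregulated, against the genome-wide deregulation rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_fdr

__all__ = [
    "GeneSetCollection",
    "TargetMap",
    "hypergeom_enrich",
    "gsea_rank_metric",
    "GseaResult",
    "gsea_es",
    "core_gene_priority",
    "mirna_priority",
    "positional_cluster_test",
    "overlap_edges",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe, with an optional cancer subset."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()
    cancer_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        empty = [s for s, m in self.sets.items() if not m]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty[:3]}")
        if not self.universe:
            self.universe = frozenset().union(*self.sets.values())
        bad = {s for s, m in self.sets.items() if not m <= self.universe}
        if bad:
            raise ValueError(f"sets with members outside the universe: {sorted(bad)[:3]}")

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None,
                 cancer_ids: Iterable[str] = ()) -> "GeneSetCollection":
        sets, names = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                sid, name, members = fields[0], fields[1], fields[2:]
                sets[sid] = frozenset(m for m in members if m)
                names[sid] = name
        return cls(
            sets,
            names,
            frozenset(universe) if universe else frozenset(),
            frozenset(cancer_ids),
        )

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.sets):
                name = self.names.get(sid, sid)
                fh.write("\t".join([sid, name, *sorted(self.sets[sid])]) + "\n")


@dataclass
class TargetMap:
    """miRNA -> target genes with evidence provenance.

    Evidence is either 'experimental' (curated-database style) or
    'predicted-intersection' (present in both of two prediction tables).
    """

    targets: dict[str, frozenset[str]]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_tables(
        cls,
        experimental: pd.DataFrame,
        predicted_a: pd.DataFrame,
        predicted_b: pd.DataFrame,
    ) -> "TargetMap":
        """Build from an experimental table plus two prediction tables.

        All tables need columns ``mirna_id`` and ``gene_id``.  Predicted
        pairs enter only when present in BOTH prediction tables and not
        already experimentally supported.
        """
        evidence: dict[tuple[str, str], str] = {}
        for row in experimental.itertuples(index=False):
            evidence[(row.mirna_id, row.gene_id)] = "experimental"
        pa = {(r.mirna_id, r.gene_id) for r in predicted_a.itertuples(index=False)}
        pb = {(r.mirna_id, r.gene_id) for r in predicted_b.itertuples(index=False)}
        for pair in pa & pb:
            evidence.setdefault(pair, "predicted-intersection")
        targets: dict[str, set[str]] = {}
        for (m, g) in evidence:
            targets.setdefault(m, set()).add(g)
        return cls({m: frozenset(g) for m, g in targets.items()}, evidence)


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Right-sided hypergeometric over-representation across a collection.

    For each set of size K in a universe of size N, with a query of size n
    overlapping in k genes, ``p_hyper = P(X >= k)``; BH adjustment across
    sets.  ``frac_up`` is the fraction of overlapping genes called "up" in
    ``directions`` (NaN when directions are absent or no overlap).

    Query genes outside the universe are dropped with a warning; an empty
    query is an error.
    """
    q = set(query)
    if not q:
        raise ValueError("empty query")
    outside = q - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        q &= collection.universe
        if not q:
            raise ValueError("no query genes inside the universe")
    N = len(collection.universe)
    n = len(q)
    rows = []
    for sid in sorted(collection.sets):
        members = collection.sets[sid]
        K = len(members)
        overlap = q & members
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        if directions and overlap:
            ups = sum(1 for g in overlap if directions.get(g) == "up")
            frac_up = ups / k
        else:
            frac_up = float("nan")
        rows.append(
            {
                "set_id": sid,
                "name": collection.names.get(sid, sid),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_hyper": p,
                "frac_up": frac_up,
                "cancer": sid in collection.cancer_ids,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_hyper"].to_numpy())
    return out.sort_values(["p_hyper", "set_id"], kind="mergesort").reset_index(drop=True)


def gsea_rank_metric(records: pd.DataFrame) -> pd.Series:
    """Rank features by mean pairwise log2 ratio, descending.

    ``records`` needs columns ``feature_id`` and ``log2_ratio`` (one row per
    feature per pair).  Ties are broken by lexicographic feature id, so the
    ordering is fully deterministic.
    """
    score = records.groupby("feature_id")["log2_ratio"].mean()
    frame = score.reset_index().sort_values(
        ["log2_ratio", "feature_id"], ascending=[False, True], kind="mergesort"
    )
    return pd.Series(
        frame["log2_ratio"].to_numpy(), index=frame["feature_id"].to_numpy(), name="score"
    )


@dataclass
class GseaResult:
    set_id: str
    es: float
    p_perm: float
    leading_edge: tuple[str, ...]


def _running_es(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, int]:
    """Enrichment score and extremum index of the weighted running sum."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    n_miss = n - n_hits
    w = np.abs(scores) ** weight
    w_hits = np.where(hit_mask, w, 0.0)
    total = w_hits.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted hits
        w_hits = hit_mask.astype(float)
        total = w_hits.sum()
    inc = w_hits / total
    dec = np.where(~hit_mask, 1.0 / n_miss if n_miss else 0.0, 0.0)
    running = np.cumsum(inc - dec)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    # exact |max| == |min| ties go to the positive extremum; the tolerance
    # absorbs cumsum rounding so the tie-break is deterministic
    if running[i_max] >= -running[i_min] - 1e-12:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def gsea_es(
    ranked: pd.Series,
    gene_set: Iterable[str],
    set_id: str = "",
    weight: float = 1.0,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> GseaResult:
    """GSEA enrichment score, leading edge, and permutation p-value.

    ``ranked`` is a descending-ordered Series (feature -> score).  The
    running sum gains ``|score|^weight / sum(|score|^weight over hits)`` at
    each set member and loses ``1/(N - |S|)`` at each miss; ES is the signed
    extremum.  The leading edge comprises hits at or before the maximum
    (ES > 0) or at or after the minimum (ES < 0).  ``p_perm`` is two-sided
    over ``n_perm`` random same-size gene subsets (add-one smoothed).

    A set with no member in the ranked list is an error.  A set covering the
    whole list degenerates to a hits-only walk (ES = 1, whole set leading).
    """
    members = set(gene_set)
    features = ranked.index.to_numpy()
    hit_mask = np.isin(features, list(members))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    scores = ranked.to_numpy(dtype=float)
    es, i_ext = _running_es(scores, hit_mask, weight)
    if es > 0:
        lead = tuple(features[: i_ext + 1][hit_mask[: i_ext + 1]])
    elif es < 0:
        lead = tuple(features[i_ext:][hit_mask[i_ext:]])
    else:
        lead = ()
    if rng is None:
        rng = np.random.default_rng(0)
    n = features.size
    more_extreme = 0
    for _ in range(n_perm):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=n_hits, replace=False)] = True
        es_p, _ = _running_es(scores, perm_mask, weight)
        if abs(es_p) >= abs(es):
            more_extreme += 1
    p_perm = (more_extreme + 1) / (n_perm + 1)
    return GseaResult(set_id, es, float(p_perm), lead)


def core_gene_priority(
    results: Mapping[str, GseaResult],
    cancer_ids: Iterable[str] = (),
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank genes by the number of pathway leading edges containing them.

    Returns feature_id, n_pathways_total, n_pathways_cancer, direction
    (from ``directions`` when given), sorted by total descending then id.
    Genes in no leading edge are excluded.
    """
    cancer = set(cancer_ids)
    total: dict[str, int] = {}
    in_cancer: dict[str, int] = {}
    for sid, res in results.items():
        for g in set(res.leading_edge):
            total[g] = total.get(g, 0) + 1
            if sid in cancer:
                in_cancer[g] = in_cancer.get(g, 0) + 1
    rows = [
        {
            "feature_id": g,
            "n_pathways_total": total[g],
            "n_pathways_cancer": in_cancer.get(g, 0),
            "direction": directions.get(g, "") if directions else "",
        }
        for g in total
    ]
    out = pd.DataFrame(
        rows,
        columns=["feature_id", "n_pathways_total", "n_pathways_cancer", "direction"],
    )
    return out.sort_values(
        ["n_pathways_total", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def mirna_priority(
    target_map: TargetMap,
    results: Mapping[str, GseaResult],
    cancer_ids: Iterable[str] = (),
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank miRNAs by pathways whose leading edge contains >=1 of their targets.

    Set semantics: several targets in the same leading edge count the
    pathway once.  miRNAs with no recorded targets get count 0 (warned).
    """
    cancer = set(cancer_ids)
    rows = []
    for mirna in sorted(target_map.targets):
        targets = target_map.targets[mirna]
        if not targets:
            warnings.warn(f"miRNA {mirna} has no targets", stacklevel=2)
        n_total = 0
        n_cancer = 0
        for sid, res in results.items():
            if targets & set(res.leading_edge):
                n_total += 1
                if sid in cancer:
                    n_cancer += 1
        rows.append(
            {
                "feature_id": mirna,
                "n_pathways_total": n_total,
                "n_pathways_cancer": n_cancer,
                "direction": directions.get(mirna, "") if directions else "",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["feature_id", "n_pathways_total", "n_pathways_cancer", "direction"],
    )
    return out.sort_values(
        ["n_pathways_total", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def positional_cluster_test(
    loci: pd.DataFrame,
    status: Mapping[str, str],
    max_gap: int = 10_000,
    min_size: int = 3,
) -> pd.DataFrame:
    """Scan for genomic clusters of coherently deregulated miRNA genes.

    ``loci`` has columns chrom, start, end, strand, feature_id (0-based
    half-open).  A cluster is a maximal run of loci on one chromosome with
    consecutive gaps <= ``max_gap`` and at least ``min_size`` members that
    carry a status.  For each cluster and each direction (down, up), a
    right-sided hypergeometric test compares the cluster's members against
    the genome-wide rate over all statused features; BH across all tests.

    The scan is invariant to input row order and to coordinate translation.
    """
    loci = loci[loci["feature_id"].isin(status.keys())]
    loci = loci.sort_values(["chrom", "start", "feature_id"], kind="mergesort")
    universe = sorted(status)
    N = len(universe)
    K_dir = {
        d: sum(1 for f in universe if status[f] == d) for d in ("down", "up")
    }
    rows = []
    cluster_id = 0
    for chrom, group in loci.groupby("chrom", sort=True):
        run: list[pd.Series] = []
        for _, row in group.iterrows():
            if run and row["start"] - run[-1]["end"] > max_gap:
                cluster_id = _emit_cluster(rows, run, cluster_id, min_size, status, N, K_dir)
                run = []
            run.append(row)
        cluster_id = _emit_cluster(rows, run, cluster_id, min_size, status, N, K_dir)
    out = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "start", "end", "n_members", "members",
            "direction", "k", "K", "n", "N", "p_hyper",
        ],
    )
    if len(out):
        out["fdr"] = bh_fdr(out["p_hyper"].to_numpy())
        out = out.sort_values(["p_hyper", "cluster_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        out["fdr"] = []
    return out


def _emit_cluster(rows, run, cluster_id, min_size, status, N, K_dir) -> int:
    if len(run) < min_size:
        return cluster_id
    members = [r["feature_id"] for r in run]
    for direction in ("down", "up"):
        k = sum(1 for f in members if status[f] == direction)
        K = K_dir[direction]
        n = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "cluster_id": f"C{cluster_id:03d}",
                "chrom": run[0]["chrom"],
                "start": int(min(r["start"] for r in run)),
                "end": int(max(r["end"] for r in run)),
                "n_members": n,
                "members": ",".join(members),
                "direction": direction,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_hyper": p,
            }
        )
    return cluster_id + 1


def overlap_edges(collection: GeneSetCollection, min_jaccard: float = 0.25) -> pd.DataFrame:
    """Set–set Jaccard overlap edge list (for external network tools)."""
    sids = sorted(collection.sets)
    rows = []
    for i, a in enumerate(sids):
        for b in sids[i + 1 :]:
            sa, sb = collection.sets[a], collection.sets[b]
            j = len(sa & sb) / len(sa | sb)
            if j >= min_jaccard:
                rows.append({"set_a": a, "set_b": b, "jaccard": j})
    return pd.DataFrame(rows, columns=["set_a", "set_b", "jaccard"])
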