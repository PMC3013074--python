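"""End-to-end orchestration of the simulated study and its analysis."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, pathways, smallrna, tagdge
from .config import PipelineConfig
from .diffexp import call_de, pair_de_table, recurrence_summary
from .fold import default_folder
from .simulate import simulate_study


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run simulate → tag DGE → small RNA → diffexp → pathways, as toggled.

    Writes tab-separated tables (with provenance headers), FASTA/FASTQ/BED
    inputs, the truth record, and a JSON manifest with per-stage record
    counts.  Rerunning with an identical configuration reproduces identical
    outputs.  A stage failure raises with a stage-tagged message after the
    manifest of completed outputs is written.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.to_dict())
    seed = config.seed
    manifest: dict = {
        "config_hash": chash,
        "seed": seed,
        "outputs": [],
        "counts": {},
    }

    def _register(name: str, n: int | None = None) -> Path:
        manifest["outputs"].append(name)
        if n is not None:
            manifest["counts"][name] = n
        return outdir / name

    stage = "simulate"
    try:
        study = simulate_study(config.simulation)
        genome = study["genome"]
        truth = study["truth"]
        io.write_fasta(genome.sequences, _register("reference.fasta"))
        io.write_table(genome.annotation, _register("annotation.tsv", len(genome.annotation)), seed, chash)
        io.write_fasta(genome.mirna_catalog.mature, _register("mirna_mature.fasta"))
        io.write_fasta(genome.mirna_catalog.precursor, _register("mirna_precursor.fasta"))
        io.write_bed(genome.mirna_catalog.loci, _register("mirna_loci.bed"))
        truth.to_json(_register("truth.json"))
        study["gene_sets"].to_gmt(_register("gene_sets.gmt"))
        for lib in study["tag_libraries"]:
            io.write_tag_counts(lib.counts, _register(f"tags_{lib.sample_id}.tsv"))
        for sample, reads in study["smallrna_reads"].items():
            io.write_fastq(reads, _register(f"smallrna_{sample}.fastq"))

        results: dict = {"study": study}

        if config.stages.get("tags", True):
            stage = "tags"
            results.update(_run_tags(config, study, outdir, manifest, _register))
        if config.stages.get("smallrna", True):
            stage = "smallrna"
            results.update(_run_smallrna(config, study, outdir, manifest, _register))
        if config.stages.get("diffexp", True):
            stage = "diffexp"
            results.update(_run_diffexp(config, study, results, manifest, _register))
        if config.stages.get("pathways", True):
            stage = "pathways"
            results.update(_run_pathways(config, study, results, manifest, _register))
    except Exception as err:
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results


def _run_tags(config, study, outdir, manifest, _register):
    genome = study["genome"]
    index = tagdge.build_virtual_tag_index(genome.sequences, genome.annotation)
    clean: dict[str, tagdge.TagLibrary] = {}
    mapped: dict[str, tagdge.MapResult] = {}
    for lib in study["tag_libraries"]:
        cl = tagdge.filter_clean_tags(
            lib.counts, config.simulation.adapter_sequence,
            lib.sample_id, lib.condition, lib.pair_id,
        )
        clean[lib.sample_id] = cl
        mapped[lib.sample_id] = tagdge.map_tags(cl, index)
    samples = sorted(clean)
    gene_counts = pd.DataFrame(
        {s: pd.Series(mapped[s].gene_counts) for s in samples}
    ).fillna(0).astype(int)
    gene_counts.index.name = "gene_id"
    io.write_table(
        gene_counts.reset_index(),
        _register("gene_counts.tsv", len(gene_counts)),
        config.seed, manifest["config_hash"],
    )
    novel = tagdge.discover_novel_tags(
        {s: mapped[s].unmapped for s in samples},
        {s: clean[s].clean_total for s in samples},
        index,
        genome.mito_sequence,
        genome.nuclear_sequences(),
        min_samples=config.min_samples,
        min_tpm=config.detect_tpm,
    )
    io.write_table(novel, _register("novel_tags.tsv", len(novel)), config.seed, manifest["config_hash"])
    return {
        "tag_index": index,
        "clean_libraries": clean,
        "mapped": mapped,
        "gene_counts": gene_counts,
        "clean_totals": {s: clean[s].clean_total for s in samples},
        "novel_tags": novel,
    }


def _run_smallrna(config, study, outdir, manifest, _register):
    genome = study["genome"]
    catalog = genome.mirna_catalog
    hierarchy = smallrna.AnnotationHierarchy(
        {**genome.decoys, "mRNA": list(genome.transcripts.values())}
    )
    libs: dict[str, smallrna.SmallRnaLibrary] = {}
    mirna_counts: dict[str, dict] = {}
    unannotated: dict[str, dict] = {}
    category_rows = []
    for sample, reads in sorted(study["smallrna_reads"].items()):
        clipped = [
            smallrna.clip_adapter(seq, config.simulation.adapter_sequence)
            for _, seq, _ in reads
        ]
        lib = smallrna.dedup_and_filter(clipped, config.min_len, sample)
        cats, mir, unann = smallrna.assign_annotation(
            lib, hierarchy, catalog.mature, catalog.precursor
        )
        libs[sample] = lib
        mirna_counts[sample] = dict(mir)
        unannotated[sample] = dict(unann)
        category_rows.append({"sample_id": sample, **cats.to_dict()})
    mirna_table = pd.DataFrame(mirna_counts).fillna(0).astype(int)
    mirna_table.index.name = "mirna_id"
    io.write_table(
        mirna_table.reset_index(),
        _register("mirna_counts.tsv", len(mirna_table)),
        config.seed, manifest["config_hash"],
    )
    io.write_table(
        pd.DataFrame(category_rows),
        _register("smallrna_categories.tsv", len(category_rows)),
        config.seed, manifest["config_hash"],
    )
    candidates = smallrna.evaluate_novel_candidates(
        unannotated,
        {s: libs[s].clean_total for s in libs},
        genome.nuclear_sequences(),
        folder=default_folder(),
        min_samples=config.min_samples,
        min_tpm=config.detect_tpm,
        energy_threshold=config.energy_threshold,
    )
    cand_df = pd.DataFrame(
        [
            {
                "chrom": c.chrom, "start": c.start, "end": c.end, "strand": c.strand,
                "mature_arm": c.mature_arm, "mfe": c.mfe,
                "n_samples_detected": c.n_samples_detected,
                "hairpin_ok": c.hairpin_ok, "energy_ok": c.energy_ok,
                "recurrence_ok": c.recurrence_ok, "reported": c.reported,
            }
            for c in candidates
        ]
    )
    io.write_table(cand_df, _register("novel_mirna_candidates.tsv", len(cand_df)), config.seed, manifest["config_hash"])
    return {
        "smallrna_libraries": libs,
        "mirna_table": mirna_table,
        "smallrna_totals": {s: libs[s].clean_total for s in libs},
        "novel_candidates": candidates,
    }


def _run_diffexp(config, study, results, manifest, _register):
    pairs = [
        (f"K{p}", f"K{p}T", f"K{p}N")
        for p in range(1, config.simulation.n_pairs + 1)
    ]
    out = {}
    chash = manifest["config_hash"]
    for label, counts, totals in (
        ("gene", results.get("gene_counts"), results.get("clean_totals")),
        ("mirna", results.get("mirna_table"), results.get("smallrna_totals")),
    ):
        if counts is None:
            continue
        records = pair_de_table(
            counts, totals, pairs, pseudo=config.pseudo_tpm, detect_tpm=config.detect_tpm
        )
        matrix = call_de(records, config.p_max, config.fdr_max)
        recur = recurrence_summary(matrix)
        io.write_table(records, _register(f"de_{label}_records.tsv", len(records)), config.seed, chash)
        io.write_table(
            matrix.reset_index(), _register(f"de_{label}_calls.tsv", len(matrix)), config.seed, chash
        )
        io.write_table(
            recur.rename_axis("min_pairs").reset_index(),
            _register(f"de_{label}_recurrence.tsv", len(recur)),
            config.seed, chash,
        )
        out[f"{label}_records"] = records
        out[f"{label}_calls"] = matrix
        out[f"{label}_recurrence"] = recur
    return out


def _dominant_status(matrix: pd.DataFrame, min_pairs: int = 2) -> dict[str, str]:
    """Per-feature status: direction called in >= min_pairs pairs (ties -> ns)."""
    status = {}
    for fid, row in matrix.iterrows():
        n_up = int((row == "up").sum())
        n_down = int((row == "down").sum())
        if n_down >= min_pairs and n_down > n_up:
            status[fid] = "down"
        elif n_up >= min_pairs and n_up > n_down:
            status[fid] = "up"
        else:
            status[fid] = "ns"
    return status


def _run_pathways(config, study, results, manifest, _register):
    chash = manifest["config_hash"]
    out: dict = {}
    collection = study["gene_sets"]
    gene_calls = results.get("gene_calls")
    gene_records = results.get("gene_records")
    if gene_calls is None:
        return out
    status = _dominant_status(gene_calls, config.min_samples)
    query = [g for g, s in status.items() if s != "ns" and g in collection.universe]
    enrich = pathways.hypergeom_enrich(query, collection, status)
    io.write_table(enrich, _register("pathway_enrichment.tsv", len(enrich)), config.seed, chash)
    out["enrichment"] = enrich

    ranked = pathways.gsea_rank_metric(gene_records)
    rng = np.random.default_rng(config.seed + 17)
    gsea_results = {}
    rows = []
    for sid in sorted(collection.sets):
        members = collection.sets[sid] & set(ranked.index)
        if not members:
            continue
        res = pathways.gsea_es(
            ranked, members, sid, config.gsea_weight,
            n_perm=config.gsea_permutations, rng=rng,
        )
        gsea_results[sid] = res
        rows.append(
            {
                "set_id": sid, "es": res.es, "p_perm": res.p_perm,
                "n_leading_edge": len(res.leading_edge),
            }
        )
    io.write_table(pd.DataFrame(rows), _register("gsea.tsv", len(rows)), config.seed, chash)
    out["gsea"] = gsea_results

    core = pathways.core_gene_priority(gsea_results, collection.cancer_ids, status)
    io.write_table(core, _register("core_genes.tsv", len(core)), config.seed, chash)
    out["core_genes"] = core

    target_map = study["target_map"]
    mirna_rank = pathways.mirna_priority(target_map, gsea_results, collection.cancer_ids)
    io.write_table(mirna_rank, _register("mirna_priority.tsv", len(mirna_rank)), config.seed, chash)
    out["mirna_priority"] = mirna_rank

    mirna_calls = results.get("mirna_calls")
    if mirna_calls is not None:
        mstatus = _dominant_status(mirna_calls, config.min_samples)
        clusters = pathways.positional_cluster_test(
            study["genome"].mirna_catalog.loci, mstatus,
            max_gap=config.cluster_gap, min_size=config.min_cluster_size,
        )
        io.write_table(clusters, _register("mirna_clusters.tsv", len(clusters)), config.seed, chash)
        out["clusters"] = clusters

    edges = pathways.overlap_edges(collection)
    io.write_table(edges, _register("pathway_edges.tsv", len(edges)), config.seed, chash)
    out["edges"] = edges
    return out
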