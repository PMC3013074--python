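"""Adapter clipping, deduplication, annotation hierarchy, hairpin screening."""

import numpy as np
import pytest

from conftest import clip_brute
from dgepipe.fold import StackFold, ViennaFold, stem_pairs
from dgepipe.smallrna import (
    AnnotationHierarchy,
    assign_annotation,
    clip_adapter,
    dedup_and_filter,
    evaluate_novel_candidates,
)
from dgepipe.tagdge import revcomp

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"


class TestClipAdapter:
    def test_exact_adapter_suffix_clipped(self):
        insert = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        read = (insert + ADAPTER)[:36]
        assert clip_adapter(read, ADAPTER) == insert

    def test_no_adapter_signal_unchanged(self):
        read = "A" * 36
        assert clip_adapter(read, ADAPTER) == read

    def test_full_adapter_read_clips_to_empty(self):
        assert clip_adapter(ADAPTER, ADAPTER) == ""

    def test_agrees_with_position_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        bases = "ACGT"
        for _ in range(300):
            n = int(rng.integers(15, 50))
            read = "".join(bases[i] for i in rng.integers(0, 4, n))
            if rng.random() < 0.6:  # plant an adapter suffix
                cut = int(rng.integers(0, n))
                read = read[:cut] + ADAPTER[: n - cut]
            assert clip_adapter(read, ADAPTER) == clip_brute(read, ADAPTER)

    def test_tolerates_one_substitution_in_adapter(self):
        rng = np.random.default_rng(22)
        bases = "ACGT"
        n_exact = 0
        for _ in range(2000):
            insert = "".join(bases[i] for i in rng.integers(0, 4, 22))
            read = list((insert + ADAPTER)[:36])
            i = int(rng.integers(22, 36))  # one error in the adapter region
            read[i] = bases[(bases.index(read[i]) + 1) % 4]
            if clip_adapter("".join(read), ADAPTER) == insert:
                n_exact += 1
        assert n_exact / 2000 >= 0.99

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            clip_adapter("", ADAPTER)


class TestDedupAndFilter:
    def test_collapses_identical(self):
        seq = "ACGTACGTACGTACGTACGTAC"
        lib = dedup_and_filter([seq] * 5)
        assert dict(lib.counts) == {seq: 5} and lib.clean_total == 5

    def test_short_sequences_dropped(self):
        lib = dedup_and_filter(["ACGTACGTACGTACGTA"])  # 17 nt
        assert lib.clean_total == 0

    def test_simulated_clean_total_matches_generator(self, small_study):
        cfg = small_study["config"]
        for sample, reads in list(small_study["reads"].items())[:2]:
            clipped = [clip_adapter(seq, cfg.adapter_sequence) for _, seq, _ in reads]
            lib = dedup_and_filter(clipped, 18, sample)
            assert lib.clean_total == small_study["sr_truth"].n_ge18[sample]


class TestAssignAnnotation:
    @pytest.fixture()
    def setup(self):
        mature = {"miR-a": "ACGTACGTACGTACGTACGTAC"}
        precursor = {"miR-a": "ACGTACGTACGTACGTACGTACGG" + "TTTT"}
        hierarchy = AnnotationHierarchy(
            {"rRNA": ["G" * 30 + "ACGTACGTACGTACGTAA" + "G" * 30]}
        )
        return mature, precursor, hierarchy

    def _lib(self, seqs):
        return dedup_and_filter(seqs, 18)

    def test_exact_mature_counted(self, setup):
        mature, precursor, hierarchy = setup
        cats, mir, unann = assign_annotation(
            self._lib([mature["miR-a"]] * 3), hierarchy, mature, precursor
        )
        assert mir["miR-a"] == 3 and cats["known-miRNA"] == 3

    def test_templated_3p_extension_counted(self, setup):
        mature, precursor, hierarchy = setup
        iso = mature["miR-a"] + "G"  # matches precursor continuation
        _, mir, _ = assign_annotation(self._lib([iso]), hierarchy, mature, precursor)
        assert mir["miR-a"] == 1

    def test_3p_trimming_counted(self, setup):
        mature, precursor, hierarchy = setup
        _, mir, _ = assign_annotation(
            self._lib([mature["miR-a"][:-2]]), hierarchy, mature, precursor
        )
        assert mir["miR-a"] == 1

    def test_exact_only_mode(self, setup):
        mature, precursor, hierarchy = setup
        _, mir, _ = assign_annotation(
            self._lib([mature["miR-a"][:-2]]), hierarchy, mature, precursor, iso_3p=0
        )
        assert not mir

    def test_decoy_assigned_to_rrna_not_mirna(self, setup):
        mature, precursor, hierarchy = setup
        decoy = "ACGTACGTACGTACGTAA"  # substring of the rRNA reference
        cats, mir, unann = assign_annotation(
            self._lib([decoy]), hierarchy, mature, precursor
        )
        assert cats["rRNA"] == 1 and not mir and not unann

    def test_partition_sums_to_clean_total(self, small_study):
        cfg = small_study["config"]
        genome = small_study["genome"]
        hierarchy = AnnotationHierarchy(
            {**genome.decoys, "mRNA": list(genome.transcripts.values())}
        )
        sample, reads = next(iter(small_study["reads"].items()))
        clipped = [clip_adapter(seq, cfg.adapter_sequence) for _, seq, _ in reads]
        lib = dedup_and_filter(clipped, 18, sample)
        cats, mir, unann = assign_annotation(
            lib, hierarchy, genome.mirna_catalog.mature, genome.mirna_catalog.precursor
        )
        assert cats.sum() == lib.clean_total
        assert sum(mir.values()) == cats["known-miRNA"]
        assert sum(unann.values()) == cats["unannotated"]


class TestFoldBackends:
    def test_stackfold_pairs_perfect_stem(self):
        arm = "GCGCAUGCAUGCGCGCAU".replace("U", "T")
        seq = arm + "TTTTT" + revcomp(arm)
        struct, energy = StackFold().fold(seq)
        pairs = stem_pairs(struct)
        assert len(pairs) >= len(arm) - 2
        assert energy < -20

    def test_stackfold_unpaired_short_sequence(self):
        struct, energy = StackFold().fold("AAAA")
        assert struct == "...." and energy == 0.0

    def test_dot_bracket_is_balanced(self):
        rng = np.random.default_rng(31)
        bases = "ACGT"
        for _ in range(10):
            seq = "".join(bases[i] for i in rng.integers(0, 4, 40))
            struct, _ = StackFold().fold(seq)
            stem_pairs(struct)  # raises on unbalanced output

    def test_vienna_backend_on_canonical_hairpin(self):
        try:
            folder = ViennaFold()
        except ImportError:
            pytest.skip("ViennaRNA bindings not available")
        struct, energy = folder.fold("GGGGGGGGGCCCCAAAACGGGGCCCCCCCCC")
        assert "(" in struct and energy < 0


def _perfect_hairpin_genome(arm_len=25, loop=12, seed=41):
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    arm = "".join(bases[i] for i in rng.integers(0, 4, arm_len))
    hairpin = arm + "".join(bases[i] for i in rng.integers(0, 4, loop)) + revcomp(arm)
    flank5 = "".join(bases[i] for i in rng.integers(0, 4, 150))
    flank3 = "".join(bases[i] for i in rng.integers(0, 4, 150))
    genome = {"chrH": flank5 + hairpin + flank3}
    read = hairpin[:22]
    return genome, read, arm


class TestEvaluateNovelCandidates:
    def test_planted_hairpin_reported(self):
        genome, read, _ = _perfect_hairpin_genome()
        unann = {"s1": {read: 40}, "s2": {read: 60}, "s3": {read: 80}}
        totals = {s: 20_000 for s in unann}
        cands = evaluate_novel_candidates(unann, totals, genome, StackFold())
        assert len(cands) == 1
        c = cands[0]
        assert c.hairpin_ok and c.energy_ok and c.recurrence_ok and c.reported
        assert c.mfe < -20

    def test_single_sample_fails_recurrence_only(self):
        genome, read, _ = _perfect_hairpin_genome(seed=42)
        unann = {"s1": {read: 40}, "s2": {}, "s3": {}}
        totals = {s: 20_000 for s in unann}
        (c,) = evaluate_novel_candidates(unann, totals, genome, StackFold())
        assert c.hairpin_ok and not c.recurrence_ok and not c.reported

    def test_non_hairpin_sequence_fails_hairpin_flag(self):
        rng = np.random.default_rng(43)
        bases = "ACGT"
        genome = {"chrR": "".join(bases[i] for i in rng.integers(0, 4, 400))}
        read = genome["chrR"][180:202]
        unann = {"s1": {read: 40}, "s2": {read: 60}}
        totals = {s: 20_000 for s in unann}
        (c,) = evaluate_novel_candidates(unann, totals, genome, StackFold())
        assert not c.hairpin_ok and not c.reported

    def test_below_tpm_not_recurrent(self):
        genome, read, _ = _perfect_hairpin_genome(seed=44)
        # 10 reads in 20M is 0.5 TPM: detectable in no sample
        unann = {"s1": {read: 10}, "s2": {read: 10}}
        totals = {s: 20_000_000 for s in unann}
        (c,) = evaluate_novel_candidates(unann, totals, genome, StackFold())
        assert not c.recurrence_ok

    def test_flags_monotone_in_thresholds(self):
        genome, read, _ = _perfect_hairpin_genome(seed=45)
        unann = {"s1": {read: 40}, "s2": {read: 60}}
        totals = {s: 20_000 for s in unann}
        loose = evaluate_novel_candidates(
            unann, totals, genome, StackFold(), min_tpm=0.5, energy_threshold=-10
        )
        tight = evaluate_novel_candidates(
            unann, totals, genome, StackFold(), min_tpm=1.0, energy_threshold=-20
        )
        # raising the energy ceiling / lowering min_tpm never removes a report
        for t, l in zip(tight, loose):
            if t.reported:
                assert l.reported

    def test_reverse_complemented_genome_still_reports_hairpin(self):
        # a stem-loop is a near-palindrome: flipping the genome leaves the
        # read mappable (on either strand) and the hairpin detectable
        genome, read, _ = _perfect_hairpin_genome(seed=46)
        flipped = {"chrH": revcomp(genome["chrH"])}
        unann = {"s1": {read: 40}, "s2": {read: 60}}
        totals = {s: 20_000 for s in unann}
        (c,) = evaluate_novel_candidates(unann, totals, flipped, StackFold())
        assert c.reported

    def test_minus_strand_placement(self):
        rng = np.random.default_rng(47)
        bases = "ACGT"
        read = "".join(bases[i] for i in rng.integers(0, 4, 22))
        flank5 = "".join(bases[i] for i in rng.integers(0, 4, 100))
        flank3 = "".join(bases[i] for i in rng.integers(0, 4, 100))
        genome = {"chrR": flank5 + revcomp(read) + flank3}
        assert read not in genome["chrR"]  # forward match would mask the test
        unann = {"s1": {read: 40}, "s2": {read: 60}}
        totals = {s: 20_000 for s in unann}
        (c,) = evaluate_novel_candidates(unann, totals, genome, StackFold())
        assert c.strand == "-"
        assert (c.start, c.end) == (100, 122)
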