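import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trfscope.fragmentio import (
    DEFAULT_ADAPTER,
    AlignedFragment,
    align_fragments,
    count_fragments,
    ingest_alignments,
    preprocess_reads,
    write_sam,
)


class TestPreprocess:
    def test_adapter_removal_then_end_trim(self):
        insert = "ACGUACGUACGUACGUACGUACGUACG"  # 27 nt
        read = insert.replace("U", "T") + DEFAULT_ADAPTER[:8]  # 35 nt
        result = preprocess_reads([read])
        assert result.reads == [insert[4:-4]]
        assert len(result.reads[0]) == 19
        assert result.n_adapter_trimmed == 1

    def test_one_mismatch_allowed_in_long_matches(self):
        insert = "A" * 30
        adapter12 = DEFAULT_ADAPTER[:12]
        mutated = "G" + adapter12[1:]
        result = preprocess_reads([insert + mutated])
        assert result.reads == ["A" * 22]  # trimmed at the mismatched adapter
        # short prefixes must match exactly
        result = preprocess_reads([insert + "X"[:0] + "G" + DEFAULT_ADAPTER[1:8]])
        assert result.n_adapter_trimmed == 0

    def test_length_threshold_and_empty_insert(self):
        assert preprocess_reads(["A" * 22]).reads == []  # below 23, adapter-free
        assert preprocess_reads([DEFAULT_ADAPTER]).reads == []  # empty insert
        assert preprocess_reads(["A" * 23]).reads == ["A" * 15]

    def test_bad_characters_skipped_with_tally(self):
        with pytest.warns(UserWarning, match="non-nucleotide"):
            result = preprocess_reads(["ACGNACGT" + "A" * 20, "A" * 25])
        assert result.n_bad_chars == 1
        assert len(result.reads) == 1

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=80))
    def test_never_shorter_than_contract(self, read):
        result = preprocess_reads([read], min_len=23, end_trim=4)
        for out in result.reads:
            assert len(out) >= 23 - 2 * 4


def brute_force_scan(read, ref, max_mismatches):
    """Independent all-position Hamming scan (the alignment oracle)."""
    hits = []
    for sp in ref:
        for start in range(sp.length - len(read) + 1):
            window = sp.sequence[start : start + len(read)]
            mism = sum(a != b for a, b in zip(window, read))
            if mism <= max_mismatches:
                hits.append((mism, (sp.id, start, start + len(read))))
    if not hits:
        return set()
    best = min(m for m, _ in hits)
    return {loc for m, loc in hits if m == best}


class TestAlign:
    def test_exact_unique_hit(self, sim_reference):
        frag = sim_reference.species[2].sequence[10:35]
        [aligned] = align_fragments([frag], sim_reference)
        assert aligned.loci == ((sim_reference.species[2].id, 10, 35),)
        assert aligned.n_hits == 1

    def test_multi_map_reported(self, sim_reference):
        # CCA-anchored 3' fragments are shared across species ends
        frag = "CCA"
        ref = sim_reference
        [aligned] = align_fragments([frag], ref, max_mismatches=0)
        ends = {(sp.id, sp.length - 3, sp.length) for sp in ref}
        assert ends <= set(aligned.loci)

    def test_best_stratum_semantics(self, sim_reference):
        sp0 = sim_reference.species[0]
        frag = list(sp0.sequence[20:45])
        frag[5] = "A" if frag[5] != "A" else "C"  # 1 mismatch vs sp0
        frag = "".join(frag)
        [aligned] = align_fragments([frag], sim_reference, max_mismatches=2)
        oracle = brute_force_scan(frag, sim_reference, 2)
        assert set(aligned.loci) == oracle
        assert (sp0.id, 20, 45) in oracle

    def test_agrees_with_brute_force_on_random_reads(self, sim_reference):
        rng = np.random.default_rng(17)
        reads = []
        for _ in range(100):
            sp = sim_reference.species[rng.integers(len(sim_reference))]
            ell = int(rng.integers(18, 40))
            start = int(rng.integers(0, sp.length - ell + 1))
            frag = list(sp.sequence[start : start + ell])
            for _ in range(int(rng.integers(0, 4))):  # 0-3 mutations
                i = int(rng.integers(ell))
                frag[i] = "ACGU"[rng.integers(4)]
            reads.append("".join(frag))
        aligned = {a.fragment_seq: set(a.loci) for a in align_fragments(reads, sim_reference)}
        for read in set(reads):
            assert aligned.get(read, set()) == brute_force_scan(read, sim_reference, 2)

    def test_empty_reference_rejected(self):
        from trfscope.reference import TRNAReference

        with pytest.raises(ValueError, match="empty"):
            align_fragments(["ACGU"], TRNAReference([]))


class TestIngestAndCount:
    def test_sam_round_trip(self, tmp_path, sim_reference):
        reads = [sp.sequence[:25] for sp in sim_reference] + ["CCA" + "U" * 20]
        fragments = align_fragments(reads, sim_reference)
        sam = tmp_path / "frags.sam"
        write_sam(fragments, sim_reference, sam)
        back = ingest_alignments(sam, sim_reference)
        assert {f.fragment_seq: set(f.loci) for f in back} == {
            f.fragment_seq: set(f.loci) for f in fragments
        }

    def test_secondary_alignments_merge(self, tmp_path, sim_reference):
        frag = AlignedFragment(
            fragment_seq=sim_reference.species[0].sequence[:20],
            loci=(
                (sim_reference.species[0].id, 0, 20),
                (sim_reference.species[1].id, 0, 20),
            ),
        )
        sam = tmp_path / "multi.sam"
        write_sam([frag], sim_reference, sam)
        [back] = ingest_alignments(sam, sim_reference)
        assert set(back.loci) == set(frag.loci)

    def test_unknown_reference_name_in_bed(self, tmp_path, sim_reference):
        bed = tmp_path / "x.bed"
        bed.write_text("NoSuchSpecies\t0\t20\tread1\t0\t+\n")
        with pytest.raises(ValueError, match="NoSuchSpecies"):
            ingest_alignments(bed, sim_reference)

    def test_bed_ingestion(self, tmp_path, sim_reference):
        sid = sim_reference.species[0].id
        bed = tmp_path / "x.bed"
        bed.write_text(f"{sid}\t0\t20\tr1\t0\t+\n{sid}\t0\t20\tr2\t0\t+\n")
        [frag] = ingest_alignments(bed, sim_reference)
        assert frag.n_reads == 2
        assert frag.fragment_seq == sim_reference.species[0].sequence[:20]

    def test_counting_no_double_count(self, sim_reference):
        seq = sim_reference.species[0].sequence[:20]
        multi = AlignedFragment(seq, ((sim_reference.species[0].id, 0, 20),
                                      (sim_reference.species[1].id, 0, 20)), n_reads=3)
        table = count_fragments({"A": [multi], "B": []})
        assert table.counts.loc[seq, "A"] == 3  # once per read, not per locus
        assert table.counts.loc[seq, "B"] == 0
        assert len(table.loci[seq]) == 2

    def test_counting_order_invariance(self, sim_reference):
        reads = [sim_reference.species[0].sequence[:20],
                 sim_reference.species[1].sequence[5:30]] * 3
        t1 = count_fragments({"s": align_fragments(reads, sim_reference)})
        t2 = count_fragments({"s": align_fragments(reads[::-1], sim_reference)})
        assert t1.counts.equals(t2.counts)

    def test_total_reads_conserved(self, sim_reference):
        rng = np.random.default_rng(3)
        reads = []
        for _ in range(200):
            sp = sim_reference.species[rng.integers(len(sim_reference))]
            start = int(rng.integers(0, 50))
            reads.append(sp.sequence[start : start + 20])
        aligned = align_fragments(reads, sim_reference)
        table = count_fragments({"s": aligned})
        assert table.counts["s"].sum() == sum(a.n_reads for a in aligned) == len(reads)
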