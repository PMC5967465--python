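import numpy as np
import pytest

from silicomate.consensus import build_consensus, ConsensusParams
from silicomate.io_formats import SequenceRecord, project_alignment, read_sam
from silicomate.matesim import (
    LibrarySpec,
    MatePair,
    Read,
    mate_name,
    reverse_complement,
    sample_mate_pairs,
)
from silicomate.synthetic import (
    SyntheticGenomeSpec,
    SyntheticTruth,
    _OpIndex,
    emit_truth_sam,
    evaluate_linkage_recovery,
    mask_reference,
    mutate_genome,
    shred_paired_end,
    simulate_reference_with_repeats,
)


class TestReferenceSimulation:
    def test_same_seed_identical(self):
        spec = SyntheticGenomeSpec(length=30_000, repeat_copies=3, repeat_length=400, seed=5)
        a = simulate_reference_with_repeats(spec)
        b = simulate_reference_with_repeats(spec)
        assert a.reference.bases == b.reference.bases
        assert a.repeat_intervals_ref == b.repeat_intervals_ref

    def test_interval_bookkeeping(self):
        spec = SyntheticGenomeSpec(length=100_000, repeat_copies=10, repeat_length=800, seed=1)
        t = simulate_reference_with_repeats(spec)
        assert len(t.repeat_intervals_ref) == 10
        for s, e in t.repeat_intervals_ref:
            assert 0 <= s < e <= 100_000 and e - s == 800
        # non-overlapping, ordered
        flat = [x for iv in t.repeat_intervals_ref for x in iv]
        assert flat == sorted(flat)

    def test_background_base_frequencies(self):
        spec = SyntheticGenomeSpec(length=100_000, repeat_copies=0, repeat_length=1, seed=2)
        t = simulate_reference_with_repeats(spec)
        sigma = (100_000 * 0.25 * 0.75) ** 0.5
        for b in "ACGT":
            assert abs(t.reference.bases.count(b) - 25_000) <= 3 * sigma

    def test_impossible_placement_is_error(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_reference_with_repeats(
                SyntheticGenomeSpec(length=10_000, repeat_copies=9, repeat_length=1000, seed=0)
            )

    def test_mask_reference_covers_intervals(self):
        spec = SyntheticGenomeSpec(length=20_000, repeat_copies=2, repeat_length=300, seed=3)
        t = simulate_reference_with_repeats(spec)
        masked = mask_reference(t)
        for s, e in t.repeat_intervals_ref:
            assert set(masked.bases[s:e]) == {"N"}
        assert "N" not in masked.bases[: t.repeat_intervals_ref[0][0]]


class TestMutation:
    def test_zero_rates_identity(self):
        t = simulate_reference_with_repeats(SyntheticGenomeSpec(length=5000, repeat_copies=0, repeat_length=1, seed=4))
        mutate_genome(t, 0.0, 0.0, seed=5)
        assert t.query.bases == t.reference.bases
        assert t.mutation_table == []
        assert t.align_ops == [("M", 5000)]

    def test_substitutions_differ_and_count(self):
        L = 50_000
        t = simulate_reference_with_repeats(SyntheticGenomeSpec(length=L, repeat_copies=0, repeat_length=1, seed=6))
        mutate_genome(t, snp_rate=0.02, indel_rate=0.0, seed=7)
        snps = [row for row in t.mutation_table if row[0] == "SNP"]
        for _, qpos, ref_b, alt_b in snps:
            assert ref_b != alt_b
            assert t.query.bases[qpos] == alt_b
        sigma = (L * 0.02 * 0.98) ** 0.5
        assert abs(len(snps) - 0.02 * L) <= 3 * sigma

    def test_indels_shift_coordinates_consistently(self):
        t = simulate_reference_with_repeats(SyntheticGenomeSpec(length=20_000, repeat_copies=2, repeat_length=300, seed=8))
        mutate_genome(t, 0.0, 0.002, indel_max=6, seed=9)
        net = sum(n for op, n in t.align_ops if op == "I") - sum(
            n for op, n in t.align_ops if op == "D"
        )
        assert len(t.query.bases) == len(t.reference.bases) + net
        # mapped repeat intervals keep their length within the net indel drift
        for (qs, qe), (rs, re) in zip(t.repeat_intervals, t.repeat_intervals_ref):
            assert 0 <= qs < qe <= len(t.query.bases)


class TestShredding:
    def test_error_free_reads_are_exact_substrings(self, small_truth):
        reads, origins = shred_paired_end(small_truth.query, coverage=2, seed=13)
        q = small_truth.query.bases
        for rd in reads[:200]:
            qpos, strand = origins[rd.name]
            sub = q[qpos : qpos + len(rd.bases)]
            assert rd.bases == (sub if strand == "+" else reverse_complement(sub))

    def test_pair_count_formula(self, small_truth):
        reads, _ = shred_paired_end(small_truth.query, read_length=100, coverage=30, seed=14)
        L = len(small_truth.query.bases)
        assert len(reads) == 2 * round(30 * L / 200)

    def test_same_seed_identical_reads(self, small_truth):
        a, _ = shred_paired_end(small_truth.query, coverage=1, seed=15)
        b, _ = shred_paired_end(small_truth.query, coverage=1, seed=15)
        assert [(r.name, r.bases) for r in a] == [(r.name, r.bases) for r in b]

    def test_every_read_has_an_origin(self, small_truth):
        reads, origins = shred_paired_end(small_truth.query, coverage=1, seed=16)
        assert set(origins) == {r.name for r in reads}


def _manual_truth(ref_bases, ops):
    """Truth with an explicit query-vs-reference alignment, query derived from ops."""
    q = []
    r = 0
    rng = np.random.default_rng(0)
    for op, n in ops:
        if op == "M":
            q.append(ref_bases[r : r + n])
            r += n
        elif op == "I":
            q.append("".join("ACGT"[i] for i in rng.integers(0, 4, n)))
        else:
            r += n
    return SyntheticTruth(
        reference=SequenceRecord(id="synref", bases=ref_bases),
        query=SequenceRecord(id="synquery", bases="".join(q)),
        align_ops=list(ops),
    )


class TestTruthSam:
    def test_pure_substitution_genome_all_match_cigars(self, tmp_path, small_truth):
        t = simulate_reference_with_repeats(SyntheticGenomeSpec(length=8000, repeat_copies=0, repeat_length=1, seed=17))
        mutate_genome(t, 0.02, 0.0, seed=18)
        reads, _ = shred_paired_end(t.query, coverage=2, seed=19)
        path = tmp_path / "t.sam"
        emit_truth_sam(reads, t, path)
        for rec in read_sam(path):
            assert rec.cigar == "100M"

    def test_read_over_deletion_gets_d_op(self, tmp_path):
        ref = "ACGT" * 100
        t = _manual_truth(ref, [("M", 100), ("D", 2), ("M", 298)])
        from silicomate.synthetic import ShotgunRead

        rd = ShotgunRead(name="x/1", bases=t.query.bases[90:110], quals="I" * 20, qpos=90, strand="+", mate=1)
        emit_truth_sam([rd], t, tmp_path / "d.sam")
        (rec,) = read_sam(tmp_path / "d.sam")
        assert rec.cigar == "10M2D10M" and rec.pos == 91

    def test_read_over_insertion_gets_i_op(self, tmp_path):
        ref = "ACGT" * 100
        t = _manual_truth(ref, [("M", 100), ("I", 5), ("M", 300)])
        from silicomate.synthetic import ShotgunRead

        rd = ShotgunRead(name="x/1", bases=t.query.bases[95:115], quals="I" * 20, qpos=95, strand="+", mate=1)
        emit_truth_sam([rd], t, tmp_path / "i.sam")
        (rec,) = read_sam(tmp_path / "i.sam")
        assert rec.cigar == "5M5I10M" and rec.pos == 96

    def test_read_inside_large_insertion_is_unmapped(self, tmp_path):
        ref = "ACGT" * 50
        t = _manual_truth(ref, [("M", 100), ("I", 80), ("M", 100)])
        from silicomate.synthetic import ShotgunRead

        rd = ShotgunRead(name="x/1", bases=t.query.bases[110:140], quals="I" * 30, qpos=110, strand="+", mate=1)
        emit_truth_sam([rd], t, tmp_path / "u.sam")
        (rec,) = read_sam(tmp_path / "u.sam")
        assert rec.is_unmapped

    def test_projection_reproduces_reference_footprint(self, tmp_path):
        """Round trip at zero divergence: every projected base equals the reference."""
        t = simulate_reference_with_repeats(SyntheticGenomeSpec(length=6000, repeat_copies=0, repeat_length=1, seed=20))
        mutate_genome(t, 0.0, 0.0, seed=21)
        reads, _ = shred_paired_end(t.query, coverage=3, seed=22)
        path = tmp_path / "p.sam"
        emit_truth_sam(reads, t, path)
        ref = t.reference.bases
        n_checked = 0
        for rec in read_sam(path):
            for rpos, base, _ in project_alignment(rec):
                assert ref[rpos - 1] == base
                n_checked += 1
        assert n_checked > 0

    def test_reverse_strand_reads_written_forward(self, tmp_path, small_truth):
        reads, _ = shred_paired_end(small_truth.query, coverage=0.5, seed=23)
        path = tmp_path / "r.sam"
        emit_truth_sam(reads, small_truth, path)
        by_name = {f"{r.name}": r for r in reads}
        for rec in read_sam(path):
            if rec.is_unmapped:
                continue
            suffix = "/1" if rec.flag & 0x40 else "/2"
            rd = by_name[rec.qname + suffix]
            expected = rd.bases if rd.strand == "+" else reverse_complement(rd.bases)
            assert rec.seq == expected
            assert bool(rec.flag & 0x10) == (rd.strand == "-")


class TestOpIndexEdges:
    def test_leading_deletion_trimmed(self):
        idx = _OpIndex([("M", 100), ("D", 5), ("M", 100)])
        rpos, cig = idx.map_interval(100, 120)  # read starts right after the deletion
        assert cig == [("M", 20)] and rpos == 105

    def test_leading_insertion_soft_clipped(self):
        idx = _OpIndex([("M", 100), ("I", 10), ("M", 100)])
        rpos, cig = idx.map_interval(105, 125)
        assert cig == [("S", 5), ("M", 15)] and rpos == 100


class TestLinkageRecovery:
    def _toy_truth(self):
        # contigs [0,100) [140,240) [280,380); repeats [100,140) and [240,280)
        ref = "A" * 380
        return SyntheticTruth(
            reference=SequenceRecord(id="synref", bases=ref),
            repeat_intervals_ref=[(100, 140), (240, 280)],
        )

    def _pair(self, start, insert, r=10, label="l"):
        return MatePair(
            name=mate_name(label, "synref", start, insert),
            read1=Read("A" * r, "I" * r),
            read2=Read("T" * r, "I" * r),
        )

    def _spec(self, insert):
        return LibrarySpec(insert_size=insert, read_length=10, target_coverage=1, label="l", min_depth=0)

    def test_spanning_pair_recovers_junction(self):
        t = self._toy_truth()
        # read1 at [80,90) in contig 0, read2 at [150,160) in contig 1
        assert evaluate_linkage_recovery([self._pair(80, 80)], t, self._spec(80)) == 0.5

    def test_exhaustive_spanning_enumeration_on_toy(self):
        """Dense sampling across all starts recovers both junctions exactly."""
        t = self._toy_truth()
        insert, r = 80, 10
        pairs = [self._pair(s, insert) for s in range(0, 380 - insert + 1)]
        assert evaluate_linkage_recovery(pairs, t, self._spec(insert)) == 1.0

    def test_insert_shorter_than_repeat_recovers_nothing(self):
        t = self._toy_truth()
        insert = 30  # repeat is 40 long: geometrically impossible
        pairs = [self._pair(s, insert) for s in range(0, 351)]
        assert evaluate_linkage_recovery(pairs, t, self._spec(insert)) == 0.0

    def test_empty_stream_zero(self):
        assert evaluate_linkage_recovery([], self._toy_truth(), self._spec(80)) == 0.0

    def test_zero_junctions_is_error(self):
        t = SyntheticTruth(reference=SequenceRecord(id="r", bases="A" * 100))
        with pytest.raises(ValueError, match="undefined"):
            evaluate_linkage_recovery([], t, self._spec(50))


class TestClosedLoop:
    def test_consensus_reproduces_reference_at_zero_divergence(self, tmp_path):
        t = simulate_reference_with_repeats(SyntheticGenomeSpec(length=10_000, repeat_copies=0, repeat_length=1, seed=30))
        mutate_genome(t, 0.0, 0.0, seed=31)
        reads, _ = shred_paired_end(t.query, coverage=20, seed=32)
        path = tmp_path / "cl.sam"
        emit_truth_sam(reads, t, path)
        (cons,) = build_consensus(read_sam(path), [t.reference])
        interior = slice(500, 9_500)
        called = [
            (c, r)
            for c, r in zip(cons.bases[interior], t.reference.bases[interior])
            if c != "N"
        ]
        assert len(called) > 8_000
        assert all(c == r for c, r in called)

    def test_heterozygous_sites_called_as_ambiguity(self, tmp_path):
        """Two shredded haplotypes differing at known sites give IUPAC calls."""
        t = simulate_reference_with_repeats(SyntheticGenomeSpec(length=20_000, repeat_copies=0, repeat_length=1, seed=33))
        mutate_genome(t, 0.0, 0.0, seed=34)
        hap2 = SyntheticTruth(reference=t.reference)
        mutate_genome(hap2, snp_rate=0.003, indel_rate=0.0, seed=35)
        reads1, _ = shred_paired_end(t.reference, coverage=20, seed=36, id_prefix="h1_")
        reads2, _ = shred_paired_end(hap2.query, coverage=20, seed=37, id_prefix="h2_")
        path = tmp_path / "het.sam"
        emit_truth_sam(list(reads1) + list(reads2), t, path)
        (cons,) = build_consensus(read_sam(path), [t.reference])
        amb = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
               frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}
        ok = tot = 0
        for _, qpos, ref_b, alt_b in hap2.mutation_table:
            if cons.depths[qpos] >= 8:
                tot += 1
                ok += cons.bases[qpos] == amb[frozenset(ref_b + alt_b)]
        assert tot > 20
        assert ok / tot >= 0.95
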