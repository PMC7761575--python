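import numpy as np
import pytest
from scipy.stats import binom

from amplihap import consensus as cz
from amplihap._seq import revcomp
from amplihap.io_formats import FastqRecord, ValidationError
from amplihap.synthetic_data import ReadSimConfig, simulate_reads


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _fastq(seqs, qual=20):
    return [
        FastqRecord(id=f"r{i}", sequence=s, qualities=(qual,) * len(s))
        for i, s in enumerate(seqs)
    ]


class TestAssembleContigs:
    def test_tiling_reads_reconstruct_sequence(self, rng):
        ref = _random_seq(rng, 2000)
        cfg = ReadSimConfig(coverage=50, error_rate=0.0, amplicons=((0, 2000),))
        r1, r2 = simulate_reads(ref, cfg, rng=rng)
        contigs = cz.assemble_contigs([r.sequence for r in r1 + r2])
        assert len(contigs) == 1
        assert contigs[0].sequence in (ref, revcomp(ref))

    def test_disjoint_reads_stay_separate(self, rng):
        a, b = _random_seq(rng, 100), _random_seq(rng, 100)
        contigs = cz.assemble_contigs([a, b])
        assert len(contigs) == 2

    def test_read_and_reverse_complement_merge(self, rng):
        a = _random_seq(rng, 120)
        contigs = cz.assemble_contigs([a, revcomp(a)])
        assert len(contigs) == 1
        assert contigs[0].sequence in (a, revcomp(a))
        assert contigs[0].support == 2

    def test_errors_are_outvoted(self, rng):
        ref = _random_seq(rng, 800)
        cfg = ReadSimConfig(coverage=30, error_rate=0.01, amplicons=((0, 800),))
        r1, r2 = simulate_reads(ref, cfg, rng=rng)
        contigs = cz.assemble_contigs([r.sequence for r in r1 + r2])
        best = max(contigs, key=lambda c: len(c.sequence))
        mismatches = min(
            sum(a != b for a, b in zip(best.sequence, ref)),
            sum(a != b for a, b in zip(best.sequence, revcomp(ref))),
        )
        assert len(best.sequence) == 800 and mismatches <= 3


class TestLayout:
    def test_identical_contig_gives_two_identical_rows(self, rng):
        ref = _random_seq(rng, 300)
        msa = cz.layout_against_reference([cz.Contig("c1", ref, 1)], ref)
        rows = msa.gapped_strings()
        assert rows[0][1] == rows[1][1] == ref

    def test_low_identity_contig_discarded(self, rng):
        ref = _random_seq(rng, 300)
        junk = _random_seq(rng, 300)
        with pytest.raises(cz.AssemblyError, match="no layout"):
            cz.layout_against_reference([cz.Contig("c1", junk, 1)], ref)

    def test_insertion_opens_gap_block_in_reference_row(self, rng):
        """A 10 bp insertion must appear as a 10-column gap in the reference
        row; verified against an independent affine local aligner."""
        from Bio import Align

        ref = _random_seq(rng, 400)
        ins = "TTAGGCATCA"
        contig = ref[:200] + ins + ref[200:]
        msa = cz.layout_against_reference([cz.Contig("c1", contig, 1)], ref)
        rows = dict(msa.gapped_strings())
        assert "-" * 10 in rows["reference"]
        assert rows["c1"].replace("-", "") == contig

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -8
        aligner.extend_gap_score = -1
        best = aligner.align(contig, ref)[0]
        assert "-" * 10 in best[1]  # the oracle also opens a 10-column gap
        gap_at = best[1].index("-" * 10)
        assert rows["reference"].index("-" * 10) == gap_at

    def test_reverse_complement_contig_is_oriented(self, rng):
        ref = _random_seq(rng, 300)
        msa = cz.layout_against_reference([cz.Contig("c1", revcomp(ref), 1)], ref)
        assert dict(msa.gapped_strings())["c1"] == ref


class TestConsensusFromMsa:
    def test_identical_rows_return_sequence(self, rng):
        ref = _random_seq(rng, 200)
        msa = cz.layout_against_reference(
            [cz.Contig(f"c{i}", ref, 1) for i in range(3)], ref
        )
        assert cz.consensus_from_msa(msa) == ref

    def test_majority_base_wins(self, rng):
        ref = _random_seq(rng, 200)
        mutant = ref[:100] + ("A" if ref[100] != "A" else "C") + ref[101:]
        msa = cz.layout_against_reference(
            [cz.Contig("a", mutant, 1), cz.Contig("b", mutant, 1), cz.Contig("c", ref, 1)],
            ref,
        )
        assert cz.consensus_from_msa(msa) == mutant

    def test_reference_only_column_emits_n(self, rng):
        ref = _random_seq(rng, 300)
        msa = cz.layout_against_reference([cz.Contig("c1", ref[:150], 1)], ref)
        out = cz.consensus_from_msa(msa)
        assert out[:150] == ref[:150]
        assert set(out[150:]) == {"N"}

    def test_empty_msa_is_error(self, rng):
        ref = _random_seq(rng, 100)
        msa = cz.layout_against_reference([cz.Contig("c1", ref, 1)], ref)
        msa.rows = []
        msa.row_ids = []
        with pytest.raises(cz.AssemblyError):
            cz.consensus_from_msa(msa)


class TestMapReads:
    def test_exact_substring_maps_at_offset(self, rng):
        ref = _random_seq(rng, 1000)
        (aln,) = cz.map_reads([ref[300:400]], ref)
        assert aln.ref_start == 300 and aln.nm == 0 and aln.cigar is None

    def test_foreign_read_unmapped(self, rng):
        ref = _random_seq(rng, 1000)
        assert cz.map_reads([_random_seq(rng, 150)], ref) == []

    def test_single_substitution_recorded(self, rng):
        """One mismatch; placement agrees with exhaustive scan of offsets."""
        ref = _random_seq(rng, 600)
        read = list(ref[200:320])
        read[60] = "A" if read[60] != "A" else "C"
        read = "".join(read)
        (aln,) = cz.map_reads([read], ref)
        assert aln.nm == 1
        best = min(
            range(len(ref) - len(read) + 1),
            key=lambda off: sum(a != b for a, b in zip(read, ref[off : off + len(read)])),
        )
        assert aln.ref_start == best == 200

    def test_reverse_strand_read_maps(self, rng):
        ref = _random_seq(rng, 500)
        (aln,) = cz.map_reads([revcomp(ref[100:220])], ref)
        assert aln.ref_start == 100 and aln.strand == 1


class TestPileupAndCall:
    def test_unanimous_alt_has_ab_one(self, rng):
        ref = _random_seq(rng, 200)
        alt_base = "A" if ref[100] != "A" else "C"
        mutant = ref[:100] + alt_base + ref[101:]
        alns = cz.map_reads([mutant[60:160]] * 50, ref)
        calls = cz.pileup_and_call(alns, ref, mean_qual=20)
        assert len(calls) == 1
        c = calls[0]
        assert (c.position, c.ref, c.alt, c.ab, c.depth) == (100, ref[100], alt_base, 1.0, 50)

    def test_qual_matches_binomial_tail(self, rng):
        """QUAL is the Phred-scaled binomial tail; one alt read in 50 at
        mean Phred 30 falls below the QUAL>20 filter."""
        ref = _random_seq(rng, 200)
        alt_base = "A" if ref[100] != "A" else "C"
        mutant = ref[:100] + alt_base + ref[101:]
        reads = [ref[60:160]] * 49 + [mutant[60:160]]
        calls = cz.pileup_and_call(cz.map_reads(reads, ref), ref, mean_qual=30)
        (c,) = calls
        expected = -10 * np.log10(binom.sf(0, 50, 10 ** (-3.0)))
        assert c.qual == pytest.approx(expected, rel=1e-6)
        assert c.qual < 20

    def test_no_disagreement_no_calls(self, rng):
        ref = _random_seq(rng, 300)
        alns = cz.map_reads([ref[i : i + 100] for i in range(0, 200, 20)], ref)
        assert cz.pileup_and_call(alns, ref) == []

    def test_deletion_calls_reproduce_haplotype(self, rng):
        """A 5 bp deletion is called (possibly as adjacent sub-runs when the
        banded alignment splits it); applying the calls recovers the truth."""
        ref = "ACGTGG" + _random_seq(rng, 200) + "TTACGA"
        hap = ref[:50] + ref[55:]  # 5 bp deletion
        alns = cz.map_reads([hap[10:110]] * 30, ref)
        calls = cz.pileup_and_call(alns, ref, mean_qual=20)
        dels = [c for c in calls if c.alt == ""]
        assert dels and sum(len(c.ref) for c in dels) == 5
        assert cz.apply_calls(ref, calls) == hap


class TestFilterCalls:
    def _call(self, qual, ab):
        return cz.VariantCall(position=0, ref="A", alt="C", qual=qual, ab=ab, depth=50)

    def test_qual_boundary_is_strict(self):
        cfg = cz.PolishConfig()
        assert cz.filter_calls([self._call(20.0, 0.9)], 1, cfg) == []
        assert len(cz.filter_calls([self._call(20.0001, 0.9)], 1, cfg)) == 1

    def test_ab_applies_only_to_last_two_iterations(self):
        cfg = cz.PolishConfig(iterations=6)
        low_ab = self._call(35.0, 0.20)
        for it in (1, 2, 3, 4):
            assert len(cz.filter_calls([low_ab], it, cfg)) == 1
        for it in (5, 6):
            assert cz.filter_calls([low_ab], it, cfg) == []
        boundary = self._call(35.0, 0.25)
        assert cz.filter_calls([boundary], 6, cfg) == []  # strict >

    def test_pure_subset_preserving_order(self, rng):
        cfg = cz.PolishConfig()
        calls = [
            cz.VariantCall(position=i, ref="A", alt="C",
                           qual=float(rng.uniform(0, 60)), ab=float(rng.uniform(0, 1)),
                           depth=50)
            for i in range(40)
        ]
        for it in (1, 5):
            out = cz.filter_calls(calls, it, cfg)
            assert [c for c in calls if c in out] == out  # subsequence

    def test_iteration_index_validated(self):
        with pytest.raises(ValidationError):
            cz.filter_calls([], 0, cz.PolishConfig())
        with pytest.raises(ValidationError):
            cz.filter_calls([], 7, cz.PolishConfig(iterations=6))


class TestApplyCalls:
    def test_empty_calls_identity(self, rng):
        ref = _random_seq(rng, 100)
        assert cz.apply_calls(ref, []) == ref

    def test_single_substitution(self, rng):
        ref = _random_seq(rng, 100)
        alt = "A" if ref[10] != "A" else "C"
        out = cz.apply_calls(ref, [cz.VariantCall(10, ref[10], alt, 50.0, 1.0, 30)])
        assert out[10] == alt and out[:10] == ref[:10] and out[11:] == ref[11:]

    def test_overlap_resolved_by_qual(self, rng):
        ref = _random_seq(rng, 100)
        a = cz.VariantCall(10, ref[10:13], "", 30.0, 0.5, 30)   # deletion
        alt = "A" if ref[11] != "A" else "C"
        b = cz.VariantCall(11, ref[11], alt, 60.0, 0.9, 30)     # higher QUAL wins
        out = cz.apply_calls(ref, [a, b])
        assert len(out) == 100 and out[11] == alt

    def test_fixed_point_after_applying_truth(self, rng):
        """Apply calls from error-free reads, re-pileup: nothing left."""
        ref = _random_seq(rng, 500)
        hap = ref[:200] + ("A" if ref[200] != "A" else "C") + ref[201:]
        reads = [hap[i : i + 120] for i in range(0, 380, 10)]
        calls = cz.pileup_and_call(cz.map_reads(reads, ref), ref, mean_qual=20)
        new_ref = cz.apply_calls(ref, calls)
        assert new_ref == hap
        assert cz.pileup_and_call(cz.map_reads(reads, new_ref), new_ref, mean_qual=20) == []


class TestPolishAndReconstruct:
    def _reads_for(self, hap, rng, error=0.0, coverage=50):
        cfg = ReadSimConfig(coverage=coverage, error_rate=error,
                            amplicons=((0, len(hap)),))
        r1, r2 = simulate_reads(hap, cfg, rng=rng)
        return r1 + r2

    def _mutate(self, ref, rng, n=5):
        s = list(ref)
        for pos in rng.choice(np.arange(50, len(ref) - 50, 7), size=n, replace=False):
            s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1 + int(rng.integers(0, 3))) % 4]
        return "".join(s)

    def test_polish_recovers_haplotype_from_reference_start(self, rng):
        ref = _random_seq(rng, 1500)
        hap = self._mutate(ref, rng, n=5)
        reads = self._reads_for(hap, rng, error=0.0)
        result = cz.polish(reads, ref)
        assert result.sequence == hap

    def test_polish_with_sequencing_errors(self, rng):
        ref = _random_seq(rng, 1500)
        hap = self._mutate(ref, rng, n=5)
        for seed in (11, 22, 33):
            reads = self._reads_for(hap, np.random.default_rng(seed), error=0.01)
            assert cz.polish(reads, ref).sequence == hap

    def test_polish_idempotent_on_truth(self, rng):
        hap = _random_seq(rng, 1200)
        reads = self._reads_for(hap, rng, error=0.0)
        result = cz.polish(reads, hap)
        assert result.sequence == hap
        assert all(row["n_kept"] == 0 for row in result.iteration_report)

    def test_kept_calls_non_increasing_on_clean_data(self, rng):
        ref = _random_seq(rng, 1500)
        hap = self._mutate(ref, rng, n=6)
        reads = self._reads_for(hap, rng, error=0.0)
        result = cz.polish(reads, ref, cz.PolishConfig(early_stop=False))
        kept = [row["n_kept"] for row in result.iteration_report]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_reconstruct_end_to_end(self, rng):
        ref = _random_seq(rng, 1800)
        hap = self._mutate(ref, rng, n=8)
        reads = self._reads_for(hap, rng, error=0.01)
        result = cz.reconstruct(_fastq([r.sequence for r in reads]), ref)
        assert result.sequence == hap
        assert set(result.sequence) <= set("ACGTN")
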