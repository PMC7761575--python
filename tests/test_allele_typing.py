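import pytest

from amplihap import allele_typing as at
from amplihap.io_formats import AlleleRegistry, ValidationError
from amplihap.synthetic_data import apply_variants


def gotoh_score(a, b, scoring):
    """Cubic-style reference DP for global affine-gap alignment score
    (gap of length L costs open + (L-1)*extend)."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = scoring.gap_open + (i - 1) * scoring.gap_extend
    for j in range(1, m + 1):
        Y[0][j] = scoring.gap_open + (j - 1) * scoring.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + scoring.gap_open, X[i - 1][j] + scoring.gap_extend,
                          Y[i - 1][j] + scoring.gap_open)
            Y[i][j] = max(M[i][j - 1] + scoring.gap_open, Y[i][j - 1] + scoring.gap_extend,
                          X[i][j - 1] + scoring.gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


class TestGlobalAlign:
    def test_identity(self):
        aln = at.global_align("ACGT", "ACGT")
        assert aln.query == aln.subject == "ACGT"
        assert aln.score == 4 * at.Scoring().match

    def test_single_gap(self):
        aln = at.global_align("AGT", "ACGT")
        assert aln.query.replace("-", "") == "AGT"
        assert aln.query.count("-") == 1 and aln.subject == "ACGT"

    def test_score_matches_reference_dp(self, rng):
        scoring = at.Scoring()
        for _ in range(50):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 81)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 81)))
            assert at.global_align(a, b, scoring).score == pytest.approx(
                gotoh_score(a, b, scoring)
            )

    def test_degapped_rows_equal_inputs(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        b = a[:20] + a[28:]
        aln = at.global_align(a, b)
        assert aln.query.replace("-", "") == a
        assert aln.subject.replace("-", "") == b


class TestEnumerateVariants:
    def test_cds_substitution_gets_cds_position(self, preset):
        """The DELLA-gene Ser variant: G->A at coding position 1000."""
        gene = preset.gene_models["Rht-D1"]
        hap = next(h for h in preset.panels["Rht-D1"] if h.name == "Rht-D1a_8")
        seq = apply_variants(gene, hap.variants)
        variants = at.enumerate_variants(at.global_align(seq, gene.sequence), gene)
        cds_vars = [v for v in variants if v.region == "exon-CDS"]
        assert len(cds_vars) == 1
        v = cds_vars[0]
        assert (v.cds_position, v.var_class, v.ref, v.alt) == (1000, "SNS", "G", "A")
        assert at.cds_pos_to_codon(v.cds_position)[0] == 334

    def test_adjacent_substitutions_merge_to_mns(self, toy_gene):
        seq = list(toy_gene.sequence)
        i = 45  # inside the CDS
        ref2 = "".join(seq[i : i + 2])
        alt2 = "".join("ACGT"[("ACGT".index(c) + 1) % 4] for c in ref2)
        seq[i : i + 2] = alt2
        variants = at.enumerate_variants(
            at.global_align("".join(seq), toy_gene.sequence), toy_gene
        )
        assert [(v.var_class, v.ref, v.alt, v.frameshift) for v in variants] == [
            ("MNS", ref2, alt2, False)
        ]

    def test_intron_deletion_not_frameshift(self, preset):
        """The 18 nt deletion sits in an intron: InDel, no frameshift flag."""
        gene = preset.gene_models["Gid2-D"]
        hap = next(h for h in preset.panels["Gid2-D"] if h.name == "Gid2-D1e")
        seq = apply_variants(gene, hap.variants)
        variants = at.enumerate_variants(at.global_align(seq, gene.sequence), gene)
        assert [(v.var_class, v.region, len(v.ref), v.frameshift) for v in variants] == [
            ("InDel", "intron", 18, False)
        ]

    def test_identical_sequences_no_variants(self, toy_gene):
        aln = at.global_align(toy_gene.sequence, toy_gene.sequence)
        assert at.enumerate_variants(aln, toy_gene) == []

    def test_frameshift_flag_in_cds(self, toy_gene):
        seq = toy_gene.sequence[:50] + toy_gene.sequence[52:]  # 2 bp CDS deletion
        variants = at.enumerate_variants(at.global_align(seq, toy_gene.sequence), toy_gene)
        indels = [v for v in variants if v.var_class == "InDel"]
        assert len(indels) == 1 and indels[0].frameshift

    def test_promoter_region_assignment(self, toy_gene):
        seq = list(toy_gene.sequence)
        seq[10] = "A" if seq[10] != "A" else "C"
        variants = at.enumerate_variants(
            at.global_align("".join(seq), toy_gene.sequence), toy_gene
        )
        assert variants[0].region == "promoter" and variants[0].cds_position is None


class TestGroupAlleles:
    def _samples(self, counts, seqs):
        out = {}
        i = 0
        for c, s in zip(counts, seqs):
            for _ in range(c):
                out[f"s{i:02d}"] = s
                i += 1
        return out

    def test_frequency_table_shape(self, rng):
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 50)) for _ in range(7)]
        samples = self._samples((20, 16, 4, 2, 2, 2, 2), seqs)
        catalog = at.group_alleles(samples, name_prefix="g")
        freqs = [at.round_half_up(e.frequency, 2) for e in catalog.entries]
        assert freqs == [0.42, 0.33, 0.08, 0.04, 0.04, 0.04, 0.04]
        assert [e.name for e in catalog.entries] == [f"g{c}" for c in "abcdefg"]

    def test_registry_names_kept_and_numbering_continues(self, rng):
        known = ["".join("ACGT"[i] for i in rng.integers(0, 4, 40)) for _ in range(7)]
        registry = AlleleRegistry(
            gene_id="Rht-D1",
            entries=[(f"Rht-D1a_{i+1}", s) for i, s in enumerate(known)],
        )
        novel1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        novel2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        samples = self._samples((3, 2, 1), [known[4], novel1, novel2])
        catalog = at.group_alleles(samples, scheme="numbered-continuation",
                                  registry=registry, name_prefix="Rht-D1a_")
        assert [e.name for e in catalog.entries] == ["Rht-D1a_5", "Rht-D1a_8", "Rht-D1a_9"]

    def test_all_identical_single_allele(self):
        catalog = at.group_alleles({"a": "ACGT", "b": "ACGT", "c": "ACGT"}, name_prefix="x")
        assert len(catalog.entries) == 1
        assert catalog.entries[0].frequency == 1.0

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            at.group_alleles([("a", "ACGT"), ("a", "ACGG")])

    def test_naming_stable_under_rerun_and_extension(self, rng):
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 30)) for _ in range(3)]
        samples = self._samples((5, 3, 1), seqs)
        c1 = at.group_alleles(samples, name_prefix="g")
        c2 = at.group_alleles(samples, name_prefix="g")
        assert [(e.name, e.sequence) for e in c1.entries] == [
            (e.name, e.sequence) for e in c2.entries
        ]
        # adding one sample of the rarest allele never renames anything above it
        extended = dict(samples)
        extended["extra"] = seqs[2]
        c3 = at.group_alleles(extended, name_prefix="g")
        names_by_seq_before = {e.sequence: e.name for e in c1.entries}
        names_by_seq_after = {e.sequence: e.name for e in c3.entries}
        assert names_by_seq_before == names_by_seq_after


class TestExtractCdsAndTranslate:
    def test_reference_round_trip(self, toy_gene):
        assert at.extract_cds(toy_gene.sequence, toy_gene) == toy_gene.cds_sequence()

    def test_promoter_variant_leaves_cds_unchanged(self, toy_gene):
        seq = list(toy_gene.sequence)
        seq[5] = "A" if seq[5] != "A" else "C"
        assert at.extract_cds("".join(seq), toy_gene) == toy_gene.cds_sequence()

    def test_in_frame_insertion_lengthens_cds(self, toy_gene):
        cds_start = toy_gene.cds_spans[0][0]
        i = cds_start + 9  # after the third codon
        seq = toy_gene.sequence[:i] + "GGG" + toy_gene.sequence[i:]
        cds = at.extract_cds(seq, toy_gene)
        assert len(cds) == len(toy_gene.cds_sequence()) + 3
        want = toy_gene.cds_sequence()
        assert cds == want[:9] + "GGG" + want[9:]

    def test_broken_cds_flagged_with_partial(self, toy_gene):
        cds_start = toy_gene.cds_spans[0][0]
        seq = toy_gene.sequence[: cds_start + 5] + toy_gene.sequence[cds_start + 6 :]
        with pytest.raises(at.CdsError) as err:
            at.extract_cds(seq, toy_gene)
        assert len(err.value.partial) == len(toy_gene.cds_sequence()) - 1

    def test_translate_minimal(self):
        assert at.translate("ATGGGCTAA") == "MG"

    def test_translate_internal_stop_flagged_not_dropped(self):
        protein = at.translate("ATGTAAGGCTAA")
        assert protein == "M*G"

    def test_translate_rejects_bad_input(self):
        with pytest.raises(at.TranslationError):
            at.translate("ATGG")
        with pytest.raises(at.TranslationError):
            at.translate("ATGNNNTAA")
        with pytest.raises(at.TranslationError):
            at.translate("ATGGGCGGC")  # no trailing stop

    def test_codon_change_at_residue_334(self, preset):
        """G->A at CDS position 1000 replaces Gly334 with Ser."""
        gene = preset.gene_models["Rht-D1"]
        hap = next(h for h in preset.panels["Rht-D1"] if h.name == "Rht-D1a_8")
        seq = apply_variants(gene, hap.variants)
        ref_protein = at.translate(gene.cds_sequence())
        protein = at.translate(at.extract_cds(seq, gene))
        assert ref_protein[333] == "G" and protein[333] == "S"


@pytest.mark.parametrize(
    "cds_pos,codon,offset",
    [(1000, 334, 0), (926, 309, 1), (1, 1, 0), (3, 1, 2), (4, 2, 0)],
)
def test_cds_pos_to_codon(cds_pos, codon, offset):
    assert at.cds_pos_to_codon(cds_pos) == (codon, offset)


class TestIsoforms:
    def test_preset_isoform_partitions(self, preset):
        """Allele->isoform partitions match the panel truth (letters may
        permute within exact frequency ties)."""
        for gene, model in preset.gene_models.items():
            samples = {}
            i = 0
            for h in preset.panels[gene]:
                seq = apply_variants(model, h.variants)
                for _ in range(round(h.target_frequency * 24)):
                    samples[f"s{i}"] = seq
                    i += 1
            scheme, prefix = preset.naming[gene]
            catalog = at.group_alleles(samples, scheme=scheme,
                                       registry=preset.registries[gene],
                                       name_prefix=prefix, gene_id=gene)
            isos = at.group_isoforms(catalog, model)
            got = {frozenset(iso.member_alleles) for iso in isos}
            truth: dict[str, set] = {}
            for hap, iso in preset.isoform_of[gene].items():
                truth.setdefault(iso, set()).add(hap)
            # registry-named alleles keep names; novel names may differ, so
            # compare partitions through sequences
            seq_of = {h.name: apply_variants(model, h.variants) for h in preset.panels[gene]}
            got_seqs = {
                frozenset(catalog.sequence_of(a) for a in part) for part in got
            }
            want_seqs = {
                frozenset(seq_of[h] for h in part) for part in truth.values()
            }
            assert got_seqs == want_seqs

    def test_all_synonymous_is_one_isoform(self, toy_gene):
        seq = list(toy_gene.sequence)
        # third position of codon 2 (GGT -> GGC), synonymous
        i = toy_gene.cds_spans[0][0] + 5
        assert seq[i] == "T"
        seq[i] = "C"
        catalog = at.group_alleles({"a": toy_gene.sequence, "b": "".join(seq)},
                                   name_prefix="t")
        isos = at.group_isoforms(catalog, toy_gene)
        assert len(isos) == 1 and isos[0].isoform_name == "A"
        assert isos[0].frequency == pytest.approx(1.0)


class TestAaVariants:
    def test_single_substitution_label(self):
        assert [v.label for v in at.call_aa_variants("MGSK", "MGGK")] == ["G3S"]

    def test_receptor_f_box_double_change(self, preset):
        """GID2 isoforms differ by E157G and R158Q."""
        gene = preset.gene_models["Gid2-D"]
        ref_protein = at.translate(gene.cds_sequence())
        hap = next(h for h in preset.panels["Gid2-D"] if h.name == "Gid2-D1b")
        protein = at.translate(at.extract_cds(apply_variants(gene, hap.variants), gene))
        assert [v.label for v in at.call_aa_variants(protein, ref_protein)] == [
            "E157G", "R158Q"
        ]

    def test_identical_proteins_empty(self):
        assert at.call_aa_variants("MGK", "MGK") == []

    def test_unequal_lengths_align_first(self):
        variants = at.call_aa_variants("MGAKL", "MGKL")  # one inserted residue
        assert all(v.ref_aa != v.alt_aa for v in variants)


class TestPresenceMatrix:
    def test_preset_pattern_and_distinct_columns(self, preset):
        """The DELLA-protein variation pattern: G334S alone marks one common
        isoform; T162V+G622A the other; T162V alone the rare ancestral-like
        isoform; the reference-like isoform carries none.  Four distinct
        column patterns = four isoforms."""
        gene = preset.gene_models["Rht-D1"]
        ref_protein = at.translate(gene.cds_sequence())
        samples = {}
        i = 0
        for h in preset.panels["Rht-D1"]:
            seq = apply_variants(gene, h.variants)
            for _ in range(round(h.target_frequency * 24)):
                samples[f"s{i}"] = seq
                i += 1
        catalog = at.group_alleles(samples, scheme="numbered-continuation",
                                   registry=preset.registries["Rht-D1"],
                                   name_prefix="Rht-D1a_", gene_id="Rht-D1")
        isos = at.group_isoforms(catalog, gene)
        matrix = at.variant_presence_matrix(isos, ref_protein)
        assert list(matrix.index) == ["T162V", "G334S", "G622A"]
        patterns = {tuple(matrix[c]) for c in matrix.columns}
        assert len(patterns) == 4
        by_member = {frozenset(iso.member_alleles): iso.isoform_name for iso in isos}
        g334s_col = by_member[frozenset({"Rht-D1a_5", "Rht-D1a_8", "Rht-D1a_9"})]
        other_col = by_member[frozenset({"Rht-D1a_7", "Rht-D1a_11"})]
        ancestral_col = by_member[frozenset({"Rht-D1a_12"})]
        wheat_like_col = by_member[frozenset({"Rht-D1a_10"})]
        assert list(matrix[g334s_col]) == ["-", "+", "-"]
        assert list(matrix[other_col]) == ["+", "-", "+"]
        assert list(matrix[ancestral_col]) == ["+", "-", "-"]
        assert list(matrix[wheat_like_col]) == ["-", "-", "-"]

    def test_no_variants_empty_matrix(self, toy_gene):
        catalog = at.group_alleles({"a": toy_gene.sequence}, name_prefix="t")
        isos = at.group_isoforms(catalog, toy_gene)
        ref_protein = at.translate(toy_gene.cds_sequence())
        matrix = at.variant_presence_matrix(isos, ref_protein)
        assert matrix.empty or len(matrix.index) == 0
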