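import numpy as np
import pytest

from hybriddetect import (ENZYME_PANEL, GroupedAlignment, RflpProfile,
                          find_diagnostic_indels, find_diagnostic_snps,
                          haplotype_group_table, read_fasta, restriction_digest,
                          rflp_haplotypes, score_clone, simulate_alignment,
                          simulate_cpdna, write_fasta)
from hybriddetect.errors import AlignmentError, DigestError


def grouped(a_seqs, b_seqs, queries=()):
    ids, seqs, groups = [], [], {}
    for i, s in enumerate(a_seqs):
        ids.append(f"A{i}"); seqs.append(s); groups[f"A{i}"] = "parent_A"
    for i, s in enumerate(b_seqs):
        ids.append(f"B{i}"); seqs.append(s); groups[f"B{i}"] = "parent_B"
    for i, s in enumerate(queries):
        ids.append(f"Q{i}"); seqs.append(s); groups[f"Q{i}"] = "query"
    return GroupedAlignment(ids, seqs, groups)


class TestFasta:
    def test_round_trip_and_uppercasing(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s1\nacgtn\n>s2\nACGTA\n")
        recs = read_fasta(p)
        assert recs == [("s1", "ACGTN"), ("s2", "ACGTA")]
        q = tmp_path / "y.fasta"
        write_fasta(recs, q)
        assert read_fasta(q) == recs

    def test_alignment_length_check(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">s1\nACGT\n>s2\nACG\n")
        with pytest.raises(AlignmentError, match="length"):
            read_fasta(p, require_alignment=True)


class TestDiagnosticSnps:
    def test_single_fixed_difference(self):
        aln = grouped(["ACGTACGT", "ACGTACGT"], ["ACGAACGT", "ACGAACGT"])
        sites = find_diagnostic_snps(aln)
        assert sites.snp_sites == [(3, "T", "A")]

    def test_within_group_polymorphism_excluded_at_strict_fixation(self):
        aln = grouped(["ACGT", "ACGA"], ["ACCT", "ACCT"])
        sites = find_diagnostic_snps(aln)
        assert [p for p, _, _ in sites.snp_sites] == [2]

    def test_query_sequences_do_not_affect_discovery(self):
        aln1 = grouped(["ACGT"], ["ACCT"])
        aln2 = grouped(["ACGT"], ["ACCT"], queries=["AAAA", "TTTT"])
        assert find_diagnostic_snps(aln1).snp_sites == find_diagnostic_snps(aln2).snp_sites

    def test_planted_sites_recovered_among_decoys(self):
        aln, truth = simulate_alignment(
            n_A=4, n_B=4, length=550, n_diag_snps=9,
            within_group_poly_rate=0.05, seed=5,
        )
        sites = find_diagnostic_snps(aln)
        assert sorted(p for p, _, _ in sites.snp_sites) == sorted(truth["snp_positions"])

    def test_relaxed_fixation_accepts_one_off_state(self):
        aln = grouped(["ACGT", "ACGT", "ACGA"], ["ACCT", "ACCT", "ACCT"])
        strict = find_diagnostic_snps(aln, 1.0)
        relaxed = find_diagnostic_snps(aln, 0.6)
        assert (3, "T", "T") not in strict.snp_sites
        assert [p for p, _, _ in strict.snp_sites] == [2]
        assert [p for p, _, _ in relaxed.snp_sites] == [2]

    def test_group_swap_symmetry(self):
        aln = grouped(["AC-TAA", "AC-TAA"], ["ACCTAT", "ACCTAT"])
        fwd = find_diagnostic_snps(aln)
        swapped = GroupedAlignment(
            aln.ids, aln.seqs,
            {i: {"parent_A": "parent_B", "parent_B": "parent_A"}.get(g, g)
             for i, g in aln.groups.items()},
        )
        rev = find_diagnostic_snps(swapped)
        assert [(p, b, a) for p, a, b in fwd.snp_sites] == rev.snp_sites
        fwd_ind = find_diagnostic_indels(aln).indel_sites
        rev_ind = find_diagnostic_indels(swapped).indel_sites
        flip = {"parent_A": "parent_B", "parent_B": "parent_A"}
        assert [(s, l, flip[c]) for s, l, c in fwd_ind] == rev_ind


class TestDiagnosticIndels:
    def test_group_specific_gap_run(self):
        aln = grouped(
            ["ACGTACGTAC", "ACGTACGTAC"],
            ["A--------C", "A--------C"],
        )
        sites = find_diagnostic_indels(aln)
        assert sites.indel_sites == [(1, 8, "parent_B")]

    def test_shared_gap_not_diagnostic(self):
        aln = grouped(["A--T"], ["A--T"])
        assert find_diagnostic_indels(aln).indel_sites == []

    def test_partial_gap_not_diagnostic(self):
        aln = grouped(["A--T", "ACGT"], ["ACGT", "ACGT"])
        assert find_diagnostic_indels(aln).indel_sites == []

    def test_planted_indel_lengths_recovered(self):
        aln, truth = simulate_alignment(
            n_A=3, n_B=3, length=550, n_diag_snps=9,
            indel_lengths=[("A", 8), ("B", 6), ("B", 2), ("B", 1)],
            within_group_poly_rate=0.05, seed=11,
        )
        sites = find_diagnostic_indels(aln)
        found = sorted((l, c) for _, l, c in sites.indel_sites)
        assert found == [(1, "parent_B"), (2, "parent_B"), (6, "parent_B"), (8, "parent_A")]


class TestCloneScoring:
    def test_parental_clone_scores_all_one_side(self):
        aln = grouped(["ACGTAA", "ACGTAA"], ["ACCTAT", "ACCTAT"])
        sites = find_diagnostic_snps(aln)
        sc = score_clone("c", "ACGTAA", sites, aln.length)
        assert (sc.n_A, sc.n_B, sc.n_novel) == (2, 0, 0)

    def test_mosaic_clone_counts_match_construction(self):
        origins = ["B"] * 8 + ["A"]
        aln, truth = simulate_alignment(
            n_A=3, n_B=3, length=550, n_diag_snps=9,
            clone_origins=[origins], seed=2,
        )
        sites = find_diagnostic_snps(aln)
        clone_seq = aln.seqs[aln.ids.index("H_1")]
        sc = score_clone("H_1", clone_seq, sites, aln.length)
        assert (sc.n_A, sc.n_B, sc.n_novel) == (1, 8, 0)

    def test_third_state_called_novel(self):
        aln, truth = simulate_alignment(
            n_A=2, n_B=2, length=200, n_diag_snps=5,
            clone_origins=[["A"] * 5], clone_novel_sites={0: [1]}, seed=9,
        )
        sites = find_diagnostic_snps(aln)
        sc = score_clone("H_1", aln.seqs[-1], sites, aln.length)
        assert (sc.n_A, sc.n_B, sc.n_novel) == (4, 0, 1)

    def test_counts_always_sum_to_site_count(self, rng):
        aln = grouped(["ACGTAA-CC", "ACGTAA-CC"], ["ACCTAT-CC", "ACCTAT-CC"])
        sites = find_diagnostic_snps(aln)
        sites.indel_sites = find_diagnostic_indels(aln).indel_sites
        for _ in range(20):
            clone = "".join(rng.choice(list("ACGT-")) for _ in range(9))
            sc = score_clone("c", clone, sites, 9)
            assert sc.n_A + sc.n_B + sc.n_novel == sites.n_sites

    def test_length_mismatch_rejected(self):
        aln = grouped(["ACGT"], ["ACCT"])
        sites = find_diagnostic_snps(aln)
        with pytest.raises(AlignmentError):
            score_clone("c", "AC", sites, aln.length)


class TestDigest:
    def test_hand_digest_alui(self):
        assert restriction_digest("AAAAGCTTTT", "AluI") == [5, 5]

    def test_no_site_returns_whole_length(self):
        assert restriction_digest("AAAAAAAA", "MboI") == [8]

    def test_hinfi_ambiguous_recognition_position(self):
        # GANTC with N matching any base; cut after the G
        assert restriction_digest("AAGACTCAA", "HinfI") == [3, 6]

    def test_sequence_n_never_matches(self):
        assert restriction_digest("AAGANTCAA", "HinfI") == [9]

    def test_fragment_lengths_sum_to_input_length(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT")) for _ in range(rng.integers(20, 200)))
            for enzyme in ENZYME_PANEL:
                frags = restriction_digest(seq, enzyme)
                assert sum(frags) == len(seq)
                assert all(f > 0 for f in frags)

    def test_matches_biopython_reference_digest(self, rng):
        """Cut positions agree with the Bio.Restriction implementation."""
        from Bio.Restriction import Restriction
        from Bio.Seq import Seq

        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT")) for _ in range(300))
            for name in ENZYME_PANEL:
                enzyme = getattr(Restriction, name)
                ref_cuts = sorted(p - 1 for p in enzyme.search(Seq(seq), linear=True))
                ref = np.diff([0, *ref_cuts, len(seq)]).tolist()
                assert restriction_digest(seq, name) == ref

    def test_unknown_enzyme_lists_panel(self):
        with pytest.raises(DigestError, match="EcoRI.*AluI|panel"):
            restriction_digest("ACGT", "EcoRI")


class TestRflp:
    def test_identical_sequences_one_haplotype(self):
        seq = "AAGATCAAGGCCTT" * 3
        profiles = [RflpProfile.from_sequence(s, seq) for s in ("x", "y", "z")]
        haps = rflp_haplotypes(profiles)
        assert len(set(haps.values())) == 1

    def test_mboi_site_loss_separates_haplotypes(self):
        with_site = "AAAGATCAAA"        # GATC at position 3
        without = "AAAGTTCAAA"
        profiles = [
            RflpProfile.from_sequence("h1", with_site, ["MboI"]),
            RflpProfile.from_sequence("h2", without, ["MboI"]),
        ]
        haps = rflp_haplotypes(profiles)
        assert haps["h1"] != haps["h2"]

    def test_haplotype_ids_stable_under_reordering(self):
        seqs = {"a": "AAAGATCAAA", "b": "AAAGTTCAAA", "c": "AAAGATCAAA"}
        fwd = rflp_haplotypes(
            [RflpProfile.from_sequence(s, seqs[s]) for s in ("a", "b", "c")]
        )
        rev = rflp_haplotypes(
            [RflpProfile.from_sequence(s, seqs[s]) for s in ("c", "b", "a")]
        )
        assert fwd == rev

    def test_inconsistent_panels_rejected(self):
        p1 = RflpProfile.from_sequence("x", "ACGT", ["MboI"])
        p2 = RflpProfile.from_sequence("y", "ACGT", ["AluI"])
        with pytest.raises(DigestError, match="panels"):
            rflp_haplotypes([p1, p2])

    def test_maternal_inheritance_groups_hybrid_with_seed_parent(self):
        """An F1 whose maternal parent is lineage B digests like lineage B."""
        specimens, hap_seqs = simulate_cpdna(
            length=800,
            haplotype_edits={"hapA": [], "hapB": [(100, "G"), (101, "A"),
                                                  (102, "T"), (103, "C")]},
            inheritance={"pa1": "hapA", "pa2": "hapA", "pb1": "hapB",
                         "f1": "hapB"},
            seed=21,
        )
        profiles = [
            RflpProfile.from_sequence(sid, seq) for sid, seq in specimens.items()
        ]
        haps = rflp_haplotypes(profiles)
        assert haps["f1"] == haps["pb1"]
        table = haplotype_group_table(
            haps, {"pa1": "parent_A", "pa2": "parent_A", "pb1": "parent_B",
                   "f1": "query"}
        )
        assert table[haps["pb1"]] == {"parent_B": 1, "query": 1}

    def test_cpdna_simulation_deterministic(self):
        kw = dict(length=300, haplotype_edits={"h": [(5, "A")]},
                  inheritance={"s": "h"}, seed=4)
        assert simulate_cpdna(**kw) == simulate_cpdna(**kw)
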