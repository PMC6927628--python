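"""Diagnostic SNPs/indels between parental alignments, clone scoring,
and plastid PCR-RFLP haplotyping.

Plants nine fixed SNP differences and the 8/6/2/1-bp group-specific
indels into a 550-bp alignment, rediscovers them against decoy
within-group polymorphism, scores a hybrid clone mosaic, and shows how a
restriction-site difference traces the maternal parent of an F1.
"""

from hybriddetect import (RflpProfile, find_diagnostic_indels,
                          find_diagnostic_snps, haplotype_group_table,
                          rflp_haplotypes, score_clone, simulate_alignment,
                          simulate_cpdna)

# ------------------------------------------------ nuclear alignment
alignment, truth = simulate_alignment(
    n_A=3, n_B=3, length=550, n_diag_snps=9,
    indel_lengths=[("A", 8), ("B", 6), ("B", 2), ("B", 1)],
    within_group_poly_rate=0.05,
    clone_origins=[["B"] * 8 + ["A"] + ["A"] * 4],  # 8 B-type + 1 A-type SNPs
    seed=19,
)
sites = find_diagnostic_snps(alignment)
indels = find_diagnostic_indels(alignment)
print(f"diagnostic SNPs found: {len(sites.snp_sites)} (planted: 9)")
print("diagnostic indels (length, gap carrier):",
      sorted((l, c) for _, l, c in indels.indel_sites))

sites.indel_sites = indels.indel_sites
clone_seq = alignment.seqs[alignment.ids.index("H_1")]
score = score_clone("H_1", clone_seq, sites, alignment.length)
print(f"hybrid clone H_1: {score.n_A} A-type, {score.n_B} B-type, "
      f"{score.n_novel} novel states over {sites.n_sites} sites")

# ------------------------------------------------ plastid RFLP
specimens, _ = simulate_cpdna(
    length=900,
    haplotype_edits={"hapA": [], "hapB": [(200, "G"), (201, "A"),
                                          (202, "T"), (203, "C")]},
    inheritance={"A1": "hapA", "A2": "hapA", "B1": "hapB", "B2": "hapB",
                 "F1": "hapB"},   # the F1's seed parent is lineage B
    seed=3,
)
profiles = [RflpProfile.from_sequence(s, seq) for s, seq in specimens.items()]
haplotypes = rflp_haplotypes(profiles)
groups = {"A1": "parent_A", "A2": "parent_A", "B1": "parent_B",
          "B2": "parent_B", "F1": "query"}
print("\nplastid haplotypes:", haplotypes)
print("haplotype x group table:", haplotype_group_table(haplotypes, groups))
print("The F1 shares the parent-B chlorotype: species B is its maternal parent.")
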