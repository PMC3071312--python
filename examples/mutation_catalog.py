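"""Work with the packaged mutation catalogs and resequencing triage.

Counts mutations per sequenced clone, tallies parallel evolution across
endpoint populations, orders the X3-lineage mutations by first detection,
and runs the variant-triage filters on planted candidates.
"""

from evotol import genotype, synth

print("mutations per sequenced clone:",
      genotype.count_mutations(genotype.load_table1()))
print("total discovered mutations:",
      genotype.total_mutations(genotype.load_class_totals()))

t2 = genotype.load_table2()
for locus, merge in [("marC", False), ("acrAB", True), ("mdh", False)]:
    n = genotype.parallel_evolution_tally(t2, locus, merge_acrAB=merge)
    print(f"populations with a {locus} mutation: {n}")

order = genotype.mutation_order(genotype.load_x3_trajectory())
print("\nX3 lineage mutation order:")
print(order.to_string(index=False))

# triage of planted variant candidates: true variants sit at or above the
# (quality 150, frequency 0.4) thresholds, decoys strictly below
cands, truth, coverage, reads = synth.gen_variant_candidates(
    n_true_snps=4, n_decoy_snps=4, n_true_indels=2, n_decoy_indels=2,
    cfg=synth.SimConfig(seed=2), gap_intervals=[(2_000_000, 2_009_900)])
kept = genotype.filter_variants(cands)
print(f"\ntriage kept {len(kept)}/{len(cands)} candidates "
      f"(exact: {set(kept['coordinate']) == truth})")
track = genotype.CoverageTrack(coverage, 4_600_000)
print("coverage gaps >= 1 kb:", genotype.detect_coverage_gaps(track))
print("reads after homopolymer filter:",
      len(genotype.homopolymer_filter(reads)), "of", len(reads))
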