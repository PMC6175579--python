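"""Classify genetic requirements across alone / pairwise / community growth.

Runs the full five-condition study design with all interaction categories
planted, then classifies the recovered significant-negative gene sets:
conserved vs induced vs alleviated requirements, the pairwise-vs-community
cross-classification, the core set and the higher-order decomposition.
"""

import barseqfit as bf
from barseqfit.interactions import classify_vs_alone, cross_classify, higher_order_summary

genome = bf.make_genome(n_genes=400, scaffold_length=800_000, seed=20)
pool = bf.make_pool(genome, n_mutants=8_000, seed=21)
design = bf.SimDesign(replicates=3, depth=600_000, seed=22)  # 5 conditions, 3 days
fractions = {c: 0.02 for c in bf.simulate.CATEGORIES if c != "neutral"}
truth = bf.make_truth(genome, design, fractions, effect_size=-3.0, seed=23)
counts = bf.simulate_counts(pool, truth, design, genome.scaffold_lengths)
records = bf.run_fitness(counts, pool, bf.FitnessConfig(window=101))

sets = bf.significant_sets(records)  # per condition, pooled over timepoints
for cond in design.conditions:
    print(f"required in {cond:11s}: {len(sets[cond].genes):3d} genes")

alone = sets["alone"]
pairwise = [sets[c] for c in design.conditions[1:-1]]
community = sets[design.conditions[-1]]

cons_pw, ind_pw, alv_pw = classify_vs_alone(alone, pairwise)
print(f"\nvs all pairwise partners: {len(cons_pw)} conserved, "
      f"{len(ind_pw)} induced, {len(alv_pw)} alleviated")

_, ind_c, alv_c = classify_vs_alone(alone, [community])
cross_ind = cross_classify(ind_pw, ind_c)
cross_alv = cross_classify(alv_pw, alv_c)
print(f"induced:    {len(cross_ind.conserved)} conserved pairwise->community, "
      f"{len(cross_ind.pairwise_specific)} pairwise-specific, "
      f"{len(cross_ind.community_specific)} community-specific")
print(f"alleviated: {len(cross_alv.conserved)} conserved pairwise->community, "
      f"{len(cross_alv.pairwise_specific)} pairwise-specific, "
      f"{len(cross_alv.community_specific)} community-specific")

summary = higher_order_summary(cross_ind, cross_alv)
print(f"\ncommunity interactions: {summary.fraction_pairwise}% derived from "
      f"pairwise interactions, {summary.fraction_higher}% higher-order")
core = bf.core_set([alone, *pairwise, community])
print(f"core set (required in every condition): {len(core)} genes")
# higher-order interactions are requirement changes seen only at full
# community complexity, not predictable from any pairwise co-culture
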