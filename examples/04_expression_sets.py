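"""Classify differential-expression tables and test category enrichment.

Consumes DE result tables (gene, log2FC, adjusted p) as produced by any DE
tool, applies the padj < 1% and |log2FC| >= 1 thresholds, compares pairwise
vs community responses, finds amplified responders and runs hypergeometric
pathway enrichment.
"""

import barseqfit as bf

genes = [f"g{i:04d}" for i in range(1000)]

# three pairwise contrasts and one community contrast with overlapping
# planted responses
planted = {
    "ha_vs_alone": set(genes[0:120]),
    "gc_vs_alone": set(genes[40:200]),
    "pc_vs_alone": set(genes[80:220]),
    "community_vs_alone": set(genes[60:180]) | set(genes[900:920]),
}
tables = [
    bf.simulate_de_table(genes, planted_up=up, seed=i, contrast=c)
    for i, (c, up) in enumerate(planted.items())
]

sets = {c: bf.de_sets(t)[c] for c, t in zip(planted, tables)}
for c in planted:
    print(f"upregulated in {c:20s}: {len(sets[c]['up']):3d} genes")

cross = bf.compare_de_sets(
    {c: sets[c]["up"] for c in list(planted)[:3]}, sets["community_vs_alone"]["up"]
)
print(f"\nconserved up in pairwise and community: {len(cross.conserved)}")
print(f"pairwise-specific up: {len(cross.pairwise_specific)}; "
      f"community-specific up: {len(cross.community_specific)}")

# which conserved responders are amplified by the full community?
amplified_truth = sorted(cross.conserved)[:25]
contrast = bf.simulate_de_table(sorted(cross.conserved), planted_up=amplified_truth,
                                seed=9, contrast="community_vs_pairwise")
amplified = bf.amplified_genes(cross.conserved, contrast)
print(f"amplified in community vs pairwise: {len(amplified)} of {len(cross.conserved)}")

# enrichment of the community-specific set in a made-up pathway map
categories = {g: ["nitrogen_starvation"] for g in genes[900:940]}
categories.update({g: ["glycolysis"] for g in genes[500:540]})
table = bf.hypergeometric_enrichment(cross.community_specific, genes, categories)
for _, row in table.iterrows():
    print(f"pathway {row['category']:20s} overlap {row['overlap']:2d}/{row['category_size']}"
          f"  padj {row['padj']:.2e}  enriched: {row['enriched']}")
# the community-specific responders were planted inside the nitrogen-
# starvation pathway, so only that category should test enriched
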