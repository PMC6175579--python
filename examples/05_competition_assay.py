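"""Competitive fitness of individual knockouts from CFU plate counts.

A knockout and the wild type are co-inoculated 1:1; plate counts at T0 and
day 1 give the mutant's population fraction, fitness is the log2 fold
change of that fraction, and a z-score across replicates calls defects
with 95% one-sided confidence — the assay used to validate pooled-library
fitness calls gene by gene.
"""

import numpy as np
import pandas as pd

import barseqfit as bf

rng = np.random.default_rng(30)
rows = []
# three mutants: a strong defect, a mild defect, and a neutral control
for mutant, day1_fraction in [("mutant_strong", 0.12), ("mutant_mild", 0.33),
                              ("mutant_neutral", 0.50)]:
    for rep in (1, 2, 3):
        p1 = min(0.95, max(0.02, day1_fraction + rng.normal(0, 0.02)))
        for tp, frac in (("T0", 0.5), ("day1", p1)):
            total = 200
            rows.append(dict(mutant=mutant, replicate=rep, timepoint=tp,
                             plate="selective", colonies=int(round(total * frac)),
                             dilution=1e-3, volume_ul=100))
            rows.append(dict(mutant=mutant, replicate=rep, timepoint=tp,
                             plate="total", colonies=total, dilution=1e-3,
                             volume_ul=100))

results = bf.analyze_competition(pd.DataFrame(rows))
print(results.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
n_sig = int(results["significant"].sum())
print(f"\n{n_sig}/{len(results)} mutants below zero fitness with >= 95% confidence")
# fitness ~ log2(p_day1/p_T0): -2 means the mutant's share of the
# population dropped fourfold against the wild type in one day
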