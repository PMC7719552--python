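"""Downstream set statistics: enrichment, overlap, chi-squared, orthologs."""

import pandas as pd

from poeseq import (
    chisq_gof_equal,
    chisq_independence_2x2,
    hypergeom_enrichment,
    overlap_test,
    reciprocal_best_hits,
)

# Are similar numbers of maternally and paternally biased genes found in
# each reproductive phenotype?  (counts of maternal vs paternal calls)
stat, df, p = chisq_gof_equal((89, 74))
print(f"goodness of fit 89 vs 74:  chi2={stat:.4f}, df={df}, p={p:.4f}")
stat, df, p = chisq_independence_2x2([[89, 74], [93, 77]])
print(f"independence 2x2 (Yates):  chi2={stat:.4f}, df={df}, p={p:.4f}")
# A statistic of 0 after continuity correction means the two phenotypes'
# maternal/paternal splits are indistinguishable.

universe = {f"g{i}" for i in range(500)}
list_rep = {f"g{i}" for i in range(90)}
list_ster = {f"g{i}" for i in range(30, 120)}
k, p = overlap_test(list_rep, list_ster, universe)
print(f"\noverlap of phenotype gene lists: {k} shared, hypergeometric p={p:.3e}")

annot = {f"g{i}": {"oogenesis" if i < 60 else "metabolism"} for i in range(500)}
enr = hypergeom_enrichment(list_rep, universe, annot)
print("\nterm enrichment in the reproductive list:")
print(enr.to_string(index=False))

hits_ab = pd.DataFrame(
    [("bt1", "am1", 1e-50, 500), ("bt2", "am2", 1e-40, 400), ("bt3", "am9", 1e-2, 60)],
    columns=["query", "subject", "evalue", "score"],
)
hits_ba = pd.DataFrame(
    [("am1", "bt1", 1e-50, 500), ("am2", "bt7", 1e-45, 420)],
    columns=["query", "subject", "evalue", "score"],
)
print("\nreciprocal best hits (e<=1e-3, both directions must agree):")
print(reciprocal_best_hits(hits_ab, hits_ba).to_string(index=False))
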