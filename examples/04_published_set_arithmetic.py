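"""Direction-split and cross-tab arithmetic on published site counts.

The set operations take probe-id sets as inputs, so the published counts of
age-differential sites can be fed in directly: 785 hyper- and 846
hypo-hydroxymethylated sites, 3708 hyper- and 9851 hypo-methylated sites,
with 428 of the hyper-5hmC sites among the 5mC losers.
"""

from oxbs5hmc import crosstab_sets, split_from_sets

hyper5hmc = [f"h{i}" for i in range(785)]
hypo5hmc = [f"l{i}" for i in range(846)]
d5hmc = split_from_sets(hyper5hmc, hypo5hmc)
print(f"d5hmC: {d5hmc.n_total} sites, {d5hmc.pct_hyper:.2f}% hyper, "
      f"{d5hmc.pct_hypo:.2f}% hypo")

hyper5mc = [f"H{i}" for i in range(3708)]
hypo5mc = hyper5hmc[:428] + [f"L{i}" for i in range(9851 - 428)]
d5mc = split_from_sets(hyper5mc, hypo5mc)
print(f"d5mC:  {d5mc.n_total} sites, {d5mc.pct_hyper:.2f}% hyper, "
      f"{d5mc.pct_hypo:.2f}% hypo")

tab = crosstab_sets(hyper5hmc, hypo5hmc, hyper5mc, hypo5mc,
                    a_labels=("hyper5hmC", "hypo5hmC"),
                    b_labels=("hyper5mC", "hypo5mC"))
pct = tab.row_pct.loc["hyper5hmC", "hypo5mC"]
print(f"share of hyper-5hmC sites that lose 5mC with age: {pct:.2f}%")
# Sites gaining 5hmC during aging largely coincide with sites losing 5mC —
# consistent with 5hmC acting as an intermediate of active demethylation.
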