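"""Select relevant genes from a simulated two-class expression study.

Simulates 500 genes x 40 samples (20 case / 20 control) with 20
informative genes shifted by 2 within-group SDs, runs the bootstrap
selection pipeline, and prints the top of the result table.
"""

from bsmselect import SimulationSpec, bsm_select, simulate_expression

spec = SimulationSpec(N=500, M1=20, M2=20, n_info=20, delta=2.0, seed=1)
dataset, informative = simulate_expression(spec)

table = bsm_select(dataset, B=200, beta=0.5, alpha=0.05, seed=1)
top = table.sorted().head(10)

print(top[["gene_id", "W", "z_score", "p_value", "adj_p_value", "selected"]]
      .to_string(index=False))
print(f"\n{len(table.selected_genes)} genes selected at adj. p <= 0.05")
hits = len(set(table.sorted()['gene_id'][:20]) & set(informative))
print(f"{hits}/20 of the truly informative genes rank in the top 20")
# W near its maximum B(B+1)/2 = 20100 means the gene sat above the rank-score
# third quartile in essentially every bootstrap replicate; a small adjusted
# p-value flags it as relevant after multiple-testing control.
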