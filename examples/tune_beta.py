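"""Choose the integration tradeoff beta by cross-validation.

beta weighs the MRMR filter side of the quadratic integration score
against the linear-SVM wrapper side; it is picked from a grid by the
mean 5-fold CV accuracy of a linear SVM on the top-50 scored genes.
"""

from bsmselect import SimulationSpec, select_beta, simulate_expression

spec = SimulationSpec(N=200, M1=15, M2=15, n_info=10, delta=1.5, seed=5)
dataset, _ = simulate_expression(spec)

beta = select_beta(dataset, grid=[0.2, 0.35, 0.5, 0.65, 0.8],
                   n_top=50, folds=5, seed=5)
print(f"selected beta = {beta}")
# beta > 0.5 leans on the MRMR (redundancy-adjusted relevance) ranking,
# beta < 0.5 on the SVM margin weights; ties go to the smaller beta.
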