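"""Ancestral state reconstruction on a small tree.

Fits the binary Mk model (ER) and reconstructs marginal ancestral
states by the re-rooting method, then does the Brownian-motion
equivalent for a continuous trait.
"""

from phyloarb import (Tree, ancestral_estimates, fit_bm, fit_mk, marginal_asr)

tree = Tree.from_newick(
    "(((sp1:1,sp2:1):1,(sp3:1,sp4:1):1):1,(sp5:2,sp6:2):1);")

# -- binary trait: present in the (sp1..sp4) clade only ---------------------
states = {"sp1": 1, "sp2": 1, "sp3": 1, "sp4": 1, "sp5": 0, "sp6": 0}
fit = fit_mk(tree, states)
print(f"ER rate q = {fit.model.rates[0]:.4f}, "
      f"root marginal logL = {fit.log_likelihood:.4f}")
asr = marginal_asr(tree, states, fit)
print(asr.to_frame().round(4))
# p_state1 is the marginal posterior probability that the ancestor carried
# the trait; the logL above is the tree's goodness-of-fit score for it.

# -- continuous trait -------------------------------------------------------
x = {"sp1": 3.1, "sp2": 2.9, "sp3": 3.6, "sp4": 3.4, "sp5": 1.0, "sp6": 1.4}
bm = fit_bm(tree, x)
print(f"\nBM rate sigma^2 = {bm.sigma2:.4f}, root estimate = {bm.root_estimate:.4f}")
print(ancestral_estimates(tree, x, bm).to_frame().round(4))
# each row: ML ancestral estimate with its variance and 95% CI; the mean
# of the variance column is the continuous-trait tree-fit score.
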