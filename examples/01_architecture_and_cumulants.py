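"""Build a trait architecture and inspect its cumulants and locus classes.

A quantitative trait is controlled additively by n diallelic loci; the "+"
allele at locus i adds gamma_i/2 to the phenotype.  Effect sizes are drawn
i.i.d. exponential with mean gamma_bar.  Loci split into "minor" effects
(gamma < gamma_hat = 2 sqrt(2 mu/s), equilibrating near frequency 1/2) and
"major" effects (mutation-selection balance near 0 or 1).
"""

import numpy as np

import polytrait as pt

arch = pt.sample_architecture(n=200, mean_effect=0.01, mutation_rate=1e-5, seed=1)
regime = pt.SelectionRegime(s=0.1, optimum_before=0.2)

gamma_hat = pt.effect_threshold(arch.mutation_rate, regime.s)
print(f"n = {arch.n_loci} loci, mean effect {arch.mean_effect}, "
      f"attainable trait range +-{arch.trait_range:.3f}")
print(f"minor/major threshold gamma_hat = {gamma_hat:.4f}")
print(f"minor loci: {arch.n_minor(regime.s)} "
      f"(exponential tail predicts {200 * np.exp(-gamma_hat / 0.01):.1f} major)")

# cumulants with every locus at frequency 1/2: mean 0, maximal variance
cs = pt.compute_cumulants(arch, np.full(200, 0.5), optimum=regime.optimum_before)
print(f"at p = 1/2:  c1 = {cs.c1:.3f}, c2 = {cs.c2:.5f} "
      f"(max = sum gamma^2 / 2), c3 = {cs.c3:.1e}, Delta_c1 = {cs.delta_c1:.3f}")

# Gaussian stabilizing fitness around the optimum
for z in (0.2, 0.5, 1.2):
    print(f"fitness at z = {z}: w = {pt.fitness(z, regime):.5f}")
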