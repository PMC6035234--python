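"""Flory--Stockmayer statistics of the A2 + B5 mixture.

The branching criterion p^2 (f_A - 1)(f_B - 1) = 1 puts the gel point of
the stoichiometric mixture at exactly p = 1/2.  The cluster-size
distribution below follows from the bipartite tree generating functions
and is cross-checked by an explicit random-bond Monte-Carlo oracle.
"""
import numpy as np

from patchykin import (FloryMixtureSpec, flory_cluster_distribution,
                       gel_point, random_graph_oracle)

spec = FloryMixtureSpec(f_A=2, f_B=5, N_A=1200, N_B=480)
print(f"gel point p_gel = {gel_point(spec)}")
p = 0.3
theory = flory_cluster_distribution(p, spec, s_max=6)
rng = np.random.default_rng(1)
acc = np.zeros(7)
for _ in range(40):
    dist, _ = random_graph_oracle(p, spec, rng)
    acc += dist.as_array(6)
print(f"expected cluster counts at p = {p} (theory | oracle mean):")
for s, nth in zip(theory.sizes, theory.counts):
    print(f"  s = {s}: {nth:8.2f} | {acc[s] / 40:8.2f}")
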