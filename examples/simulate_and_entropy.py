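"""Simulate the benchmark latent-index panel and measure its entropy.

Builds a 50-node, 15-period panel from the preferential/homophily/fixed-effect
formation rule, then prints the dynamic-network entropy H(C) next to the two
reference measures.  Lower H(C) per dyad-period means the realized links were
better predicted by the model."""
import numpy as np

from latentlink import (
    degree_shannon_entropy,
    dgp_section4,
    entropy_HC,
    erdos_renyi_entropy,
    summarize,
    theorem1_deviation,
)

panel, params, effects = dgp_section4(50, T=15, q=10, seed=1)
s = summarize(panel)
print(f"final-period mean degree {s.mean_degree:.2f}, density {s.density:.3f}, "
      f"clustering {s.clustering_mean:.3f}")

rep = entropy_HC(panel, params, effects)
print(f"H(C) raw = {rep.H_raw:.2f} over {rep.n_dyad_periods} dyad-periods "
      f"({rep.H_per_dyad_period:.4f} per dyad-period; closed vs series gap "
      f"{abs(rep.H_raw - rep.H_series):.1e})")
print(f"degree-distribution Shannon entropy = {degree_shannon_entropy(panel):.3f}")
print(f"Erdos-Renyi reference entropy at the same density = "
      f"{erdos_renyi_entropy(50, s.density):.1f}")

stat, bound = theorem1_deviation(panel, params, effects)
print(f"link-frequency concentration: {stat:.3f} < ln(NT) = {bound:.3f} "
      "(realized links track their probabilities)")
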