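"""Small replicated generator comparison (descriptive + entropy tables).

Runs the Monte Carlo harness at desk scale: 10 replicates of the
latent-index benchmark DGP, Erdos-Renyi and Barabasi-Albert networks at
two sizes, and prints both report tables with Monte Carlo standard errors."""
from latentlink import benchmark

tables = benchmark(sizes=[30, 60], n_replicates=10, seed=0)
for name, df in tables.items():
    print(f"== {name} ==")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print()
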