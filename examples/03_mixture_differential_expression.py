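"""Composition-corrected differential expression via in-silico mixtures.

Simulates baseline (in vitro) expression for each line and in vivo brain
metastasis profiles with 100 genes shifted +2 log2 units, pairs each in
vivo sample with the composition-weighted mixture of its constituent
lines' baselines, and runs the paired moderated t-test.
"""

from metpool.experiments import de_experiment

null = de_experiment(seed=1, n_genes=2000, n_de=0)
print(f"null run (in vivo = exact mixture + noise): "
      f"{null['null_fraction']:.4f} of {null['n_null']} genes at q<0.05")

power = de_experiment(seed=2, n_genes=2000, n_de=100, de_lfc=2.0)
print(f"spiked run (+2 log2 in 100 genes): {power['recovered']}/100 recovered "
      f"at q<0.05; median estimated LFC {power['median_de_lfc']:.2f}")

print("\nPairing each in vivo profile with its matched in-silico mixture "
      "removes composition differences between organs, so calls reflect "
      "in vivo induction rather than which lines colonized the organ.")
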