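"""Generate a synthetic three-pool plasma methylome study.

Builds a 2 Mb genome with 200 CpG islands, simulates healthy (H),
disease-free survivor (DFS) and metastatic-cancer-analog (MBC) pools —
the MBC pool carries a global hypomethylation shift plus 10 planted
hypermethylated islands — and prints the basic shape of the data.
"""

import numpy as np

from cfmeth.simulate import default_pool_params, make_genome, simulate_study

genome, tracks = make_genome(seed=7)
params = default_pool_params(depths=(10.0, 10.0, 17.0))
data = simulate_study(genome, params, seed=7, n_planted=10)

print(f"genome: {genome.chromosomes[0][0]} ({genome.chromosomes[0][1]:,} bp), "
      f"{len(genome.islands)} islands, {len(data.cpgs):,} CpG dyads")
for label, pool in data.pools.items():
    pct = pool.percent_methylation.dropna()
    print(f"pool {label:>3}: {len(pool):,} cytosines, "
          f"mean coverage {pool.coverage.mean():.1f}, "
          f"mean methylation {pct.mean():.1f}%, "
          f"fraction of loci below 50%: {(pct < 50).mean():.3f}")
print(f"planted hotspot islands: "
      f"{[iv.name for iv in data.truth.planted_hotspot_islands]}")

# The H and DFS pools share a bimodal landscape (background ~85%
# methylated, islands ~5%); the MBC pool's background is shifted down and
# its planted islands are pushed to ~90%, so its mean is lower and its
# below-50% mass larger — the global-hypomethylation signature.
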