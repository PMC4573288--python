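"""Pool-level similarity: Pearson, Ward clustering, PCA, histograms.

Computes percent-methylation profiles over the loci covered >= 5x in all
three pools and shows that H and DFS resemble each other while the
cancer-analog pool separates on every analysis.
"""

import pandas as pd

from cfmeth.similarity import similarity_report
from cfmeth.simulate import default_pool_params, make_genome, simulate_study

genome, _ = make_genome(seed=7)
data = simulate_study(genome, default_pool_params(depths=(10.0, 10.0, 17.0)),
                      seed=7, n_planted=10)

report = similarity_report(data.pools.values(), min_coverage=5)
print(f"{report['n_common_loci']:,} loci covered >= 5x in every pool")
print("pairwise Pearson r:")
print(pd.DataFrame(report["pearson"]).round(3))

labels = report["ward_linkage"]["labels"]
a, b = (int(i) for i in report["ward_linkage"]["merges"][0][:2])
print(f"Ward clustering merges {labels[a]} and {labels[b]} first")

scores = pd.DataFrame(report["pca"]["scores"])
evr = report["pca"]["explained_variance_fractions"]
print(f"PCA scores (PC1 explains {evr[0]:.0%} of variance):")
print(scores.round(1))

for label, h in report["histograms"].items():
    low = sum(h["counts"][:10]) / sum(h["counts"])
    print(f"  {label:>3}: fraction of loci below 50% methylation = {low:.3f}")

# H and DFS correlate most strongly and merge first; the shifted pool is
# the PC1 extreme and carries more mass below 50% — the group structure a
# case/control/survivor plasma comparison is expected to show.
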