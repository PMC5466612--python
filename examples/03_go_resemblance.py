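"""KS-rank GO enrichment and resemblance clustering of comparisons.

Two organ-pair comparisons built from the same planted term set should
cluster together before joining a comparison with a disjoint planted set;
the dendrogram below shows exactly that.
"""

import numpy as np
import pandas as pd

from whorlspec import build_comparison_matrix, cluster_comparisons, ks_enrichment

rng = np.random.default_rng(3)
results = []
for comp, planted in [("sepal_vs_petal", {"GO:flower", "GO:pigment"}),
                      ("sepal_vs_stamen", {"GO:flower", "GO:pigment"}),
                      ("petal_vs_stamen", {"GO:pollen", "GO:cellwall"})]:
    genes = [f"g{i}" for i in range(400)]
    scores = pd.Series(rng.uniform(size=400), index=genes)  # DEG p-values
    annotation = {g: {f"GO:bg{rng.integers(0, 12)}"} for g in genes}
    for term in planted:
        for k in rng.choice(400, size=25, replace=False):
            annotation[genes[k]].add(term)
            scores.iloc[k] = min(scores.iloc[k], rng.uniform(0, 0.05))
    res = ks_enrichment(scores, annotation, comparison=comp)
    sig = res.significant_terms(0.05)
    print(f"{comp}: significant terms {sorted(sig)}")
    results.append(res)

matrix = build_comparison_matrix(results, alpha=0.05)
dendro = cluster_comparisons(matrix)
print("resemblance dendrogram:", dendro.to_newick())
print("the two comparisons sharing planted terms merge first")
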