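"""Delta-delta-Ct quantification and qPCR vs RNA-seq agreement.

Builds a small Ct table (target vs a reference gene, calibrated on the
sepal sample), computes relative quantities RQ = 2^(-ddCt), and correlates
them with matching RNA-seq abundances per gene.
"""

import numpy as np
import pandas as pd

from whorlspec import ddct, platform_correlation

rng = np.random.default_rng(7)
samples = ["sepal", "petal", "stamen", "carpel"]
rpkm = pd.DataFrame({s: [2 ** i, 2 ** (3 - i)]
                     for i, s in enumerate(samples)},
                    index=["geneA", "geneB"], dtype=float) * 10

rows = []
for gene in rpkm.index:
    for sample in samples:
        ct_target = 30 - np.log2(rpkm.loc[gene, sample] + 1)
        for _ in range(3):  # technical replicates, averaged on the Ct scale
            rows.append((gene, sample, ct_target + rng.normal(0, 0.1),
                         20.0 + rng.normal(0, 0.05)))
ct = pd.DataFrame(rows, columns=["gene", "sample", "ct_target", "ct_reference"])

rq_long = ddct(ct, calibrator="sepal")
rq = rq_long.pivot(index="gene", columns="sample", values="rq")
print("relative quantities (calibrator sepal, RQ there = 1):")
print(rq.round(2).to_string())

corr = platform_correlation(rq, rpkm, alpha=0.05)
print("\nper-gene Pearson agreement with RNA-seq (log2 scale):")
print(corr.round(4).to_string())
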