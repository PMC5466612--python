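# whorlspec

Comparative transcriptomics of floral whorl specification.

Double flowers in ornamental camellias replace stamens and carpels with
petals or petal-like organs. One way to interrogate how that happens is to
contrast gene expression between floral organs (the concentric whorls:
sepal, petal, stamen, carpel) of a wild single-flowered plant and of
double-flowered cultivars. In the wild flower, many regulators are
*canalized* — expressed in essentially one whorl; in cultivars that
specificity tends to *fade* into gradients spanning neighbouring whorls.
`whorlspec` implements the full analysis chain for this kind of study and a
synthetic-data generator that plants known truth into every input, so each
stage is testable without any sequencing data.

## What it computes

- **Normalization & QC** — RPKM (`count / (length_kb × mapped_millions)`),
  miRNA TPM (`count × 10⁶ / mapped_total`), row z-scores (population sd);
  replicate QC by pairwise Pearson correlation (outlier if *r* < 0.2 to every
  sibling, low-agreement if *r* < 0.73 to any); Euclidean-distance
  complete-linkage clustering of organ mean profiles.
- **Differential expression** — per-gene two-sided exact test of equal NB
  means conditioned on the pooled count (with variance μ + φμ²; the φ = 0
  conditional law is exactly binomial), method-of-moments dispersion shrunk
  toward a conditional-ML common value, Benjamini–Hochberg step-up FDR, and
  the triple calling rule |log₂ RPKM ratio| ≥ 1, p < 0.05, FDR < 0.001;
  shared/private DEG overlap summaries with direction concordance.
- **GO enrichment & resemblance** — per term, a one-sided two-sample
  Kolmogorov–Smirnov test comparing DEG p-value ranks of annotated genes
  against the rest; BH-significant terms consolidated into a
  comparisons × terms matrix of −log₁₀(adjusted p), clustered by furthest-
  neighbor linkage; a stringent raw-p screen (KS ≤ 10⁻⁵) for the most
  enriched processes.
- **Whorl specificity & collapse** — the ten-fold rule (specific to organ
  *o* iff mean(*o*) > 10 × max over other organs, with a 0.1-RPKM floor),
  the tissue-specificity index τ = Σ(1 − xᵢ/x_max)/(n−1), and retention of
  wild specificity in cultivar organ means mapped by positional homology.
- **Degradome (PARE) target scanning** — antiparallel miRNA/transcript
  alignment with position-weighted penalties (mismatch 1, G:U 0.5, gap 1,
  doubled at positions 2–13), slice site at the base paired to miRNA
  position 10, degradome categories 0–4 from the 5′-end pileup, empirical
  p-values from mononucleotide-shuffled miRNAs, T-plot tables, and
  per-library / merged-library target comparison.
- **Orthology & phylogeny** — reciprocal-best-hit ortholog detection and a
  classical Saitou–Nei Neighbor-Joining tree (exact on additive matrices).
- **qPCR validation** — ΔΔCt relative quantification (RQ = 2^(−ΔΔCt))
  against a reference gene and calibrator sample, and per-gene Pearson
  agreement between qPCR and RNA-seq profiles.

## Worked example

```python
from whorlspec import SimConfig, simulate_expression, call_degs

config = SimConfig(n_genes=1000, organs=("sepal", "petal"), n_replicates=3,
                   dispersion=0.1, frac_specific=0.1, specificity_fold=8.0,
                   seed=2)
matrix, truth = simulate_expression(config)
table = call_degs(matrix, matrix.samples_for("sepal"),
                  matrix.samples_for("petal"))
print((table["call"] != "ns").sum())
```

Running `python examples/02_differential_expression.py` (the same analysis
with the confusion against truth) prints:

```
100 DEGs called (50 up, 50 down) of 1000 genes
planted 8-fold genes: 100; recovered: 100 (sensitivity 1.00); false calls: 0
```

i.e. at these study conditions (3 vs 3 replicates, dispersion 0.1, 8-fold
planted effects) the triple rule recovers every planted gene with no false
calls. The other scripts in `examples/` walk through enrichment
resemblance, whorl-specificity collapse, degradome scanning, orthology/NJ
and qPCR validation the same way, each printing the numbers it computes and
what they mean.

An end-to-end synthetic pipeline (simulate → QC → DEG → enrichment → whorl
→ degradome → phylogeny → qPCR) is available both from Python
(`whorlspec.run_pipeline`) and from the shell:

```sh
whorlspec run --seed 7 out/          # writes TSV/newick/JSON + manifest
whorlspec simulate --n-genes 2000 simdata/
whorlspec scan mirnas.fa transcripts.fa pileup.tsv hits.tsv
```

Reruns with the same seed are byte-identical (the manifest records SHA-256
checksums of every output).

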