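# Methods

This note documents the statistical models, parameter choices and
numerical conventions behind `whorlspec`, and what the synthetic-data
experiments do and do not demonstrate.

## Synthetic data model

`synth.simulate_expression` draws gene-level counts for every
organ × cultivar × replicate sample from a negative binomial with mean μ
and dispersion φ (variance μ + φμ², the parameterization of the DEG
literature), via the gamma–Poisson mixture; φ = 0 degenerates to Poisson.
Per-gene baseline means are log-normal around `baseline_mean` (default 100
counts, log-sd 1), giving the heavy-tailed abundance distribution typical
of RNA-seq. Library depths are log-normal (log-sd 0.2), a realistic
±20% depth variation that exercises the RPKM and library-equalization
paths. Replicates are i.i.d.

A fraction `frac_specific` (default 0.1) of genes is planted as
organ-specific: in its home whorl the gene's mean is elevated
`specificity_fold`-fold (default 20). **Fading** is the one knob that
separates wild from cultivar expression architecture: under fading *f*,
the excess (fold − 1) decays geometrically into neighbouring whorls with
ratio *f* per whorl of distance in the concentric organ order. *f* = 0 is
full canalization (sharply bounded expression); *f* = 1 spreads the excess
equally across all whorls (fully faded, organ-uniform). The study's
narrative gives no quantitative fading value for real cultivars, so the
demo pipeline fixes mid-range values once (formal 0.75, anemone 0.5) as
plausible "strongly" and "moderately" faded architectures; no conclusion
in this package depends on those two numbers.

A consequence of this model worth stating: with a 20-fold planted
elevation and the ten-fold specificity rule, the home-to-adjacent mean
ratio at fading *f* is 20/(1 + 19 *f*), which drops below 10 already at
*f* ≈ 0.05. Retention of specificity in a faded cultivar is therefore
essentially a step function — near 1 at *f* = 0 and near 0 for *f* ≥ 0.25
— rather than a smooth gradient; the tests assert monotone non-increasing
retention, which is the property the model actually delivers. The
continuous signal of fading is visible instead in the mean τ shift, which
grows smoothly with *f* (see `examples/04_whorl_collapse.py`).

The GO generator assigns every gene ≥ 1 background term uniformly
(1 + Poisson(1) terms per gene) and plants `n_enriched` terms whose
members are drawn with `enrichment_odds` : 1 preference for genes carrying
planted expression effects; odds 1 reduces exactly to the null. The
degradome generator inserts the reverse complement of each target miRNA
into its target transcript and puts a read peak (default 50 × the NB
background mean) at the slice position; background counts are clipped just
below the peak so that planted sites are category 0 by construction — the
simulator's contract is "category-0 truth", not "probably category 0".
The protein-family generator mutates a common ancestor independently into
the two proteomes (5% substitution rate over 120 aa), which makes shared
k-mer similarity of true pairs dominate by a wide margin, and emits an
exactly additive distance matrix from a random binary tree with
uniform(0.1, 1) branch lengths.

What the simulator does **not** model: read-level noise, mapping
ambiguity, gene-length biases beyond the RPKM denominator, correlated
replicates, GO-term dependency structure (the DAG), isoforms, or
sequence composition biases in transcripts. Passing recovery tests on
this data demonstrates the *algorithms* are correct and calibrated under
their stated assumptions, not that real Camellia libraries satisfy those
assumptions.

## Differential expression

Counts are library-equalized by mean scaling (every column scaled to the
mean column sum) — a deliberate simplification of quantile-based
pseudocount equalization; it is exact when library size is a pure scale
factor, which is how the simulator generates depth variation.

The test conditions on the pooled per-gene count: if both groups share a
mean and counts are NB(μ, φ), the A-group share of the total follows a
closed-form conditional law (two NB sums with sizes n_A/φ, n_B/φ), and
the two-sided p-value sums the probabilities of all splits no more likely
than the observed one (ties included, so identical groups give p = 1 and
p ∈ (0, 1] always). At φ = 0 this is exactly the two-sided binomial split
test, which the test suite checks by exhaustive enumeration for every
total ≤ 200.

Dispersion: per gene, a method-of-moments estimate pooled over groups,
φ̂ = Σ df·(s² − μ̂) / Σ df·(μ̂² − s²/n), floored at 0 — the denominator
uses the unbiased estimate of μ² (E[μ̂²] = μ² + σ²/n), which removes a
≈ −25% bias visible at 3 replicates. The common dispersion maximizes the
conditional (Dirichlet-multinomial given group totals) likelihood summed
over genes — the approach of the quantile-adjusted conditional ML
tradition — because moment-based common estimators proved unstable at 3
replicates (±20% across seeds, dominated by the few highest-expression
genes). The per-gene value used by the test shrinks the MoM estimate
toward the common value with weight prior_df/(prior_df + residual_df),
prior_df = 20: at 3 + 3 replicates (4 residual df) that is 0.83 — heavy
moderation is appropriate because a 4-df MoM estimate is mostly noise.
Measured calibration at the study conditions (2000 genes, 3 vs 3, φ = 0.1):
null rejection 0.047–0.059 at α = 0.05 and 0.004–0.013 at α = 0.01 across
seeds, inside the binomial 99% band.

DEG calling uses group-mean RPKM ratios with a pseudocount equal to the
RPKM of one read at the mean library size (avoids infinite ratios at zero
counts), and the triple rule |log₂ ratio| ≥ 1 ∧ p < 0.05 ∧ FDR < 0.001.
The FDR cut at 0.001 with a separate raw-p cut at 0.05 is redundant in
most regimes (the FDR gate is almost always the binding one); both are
enforced as stated, and the looser fold-change + p rule is available by
raising the `fdr` threshold in `Thresholds`. BH adjustment is the step-up
definition, verified against both a literal implementation and
statsmodels.

## Enrichment and resemblance

The gene ranking score is the DEG raw p-value (smaller = more enriched),
the topGO-KS convention; any other per-gene score (e.g. |log₂ ratio|,
negated) can be passed instead since the function takes an arbitrary
score vector. Annotation is flat — no ancestor propagation along the GO
graph; a caller wanting propagation can expand the gene→term map before
passing it in. Terms under `min_genes` (default 5) annotated genes are
dropped; a term covering the entire universe has no complement and is
skipped with a log entry. The KS test is one-sided (annotated scores
stochastically smaller), asymptotic by default with scipy's exact
small-sample path available via `method="exact"`.

The comparison matrix stores −log₁₀(BH-adjusted p) for significant terms
(0 elsewhere): clustering then respects both *presence* and *strength* of
enrichment; a binary mode exists for presence-only resemblance. The
stringent screen applies its cutoff (default 10⁻⁵) to the **raw** KS p,
while significance uses the adjusted p — on the same input the screen is
therefore a subset of the significant set whenever the term count is
below ~5 × 10³ (and the suite asserts the containment on random inputs).

Resemblance clustering and the organ dendrogram both use the same
complete-linkage ("furthest neighbor") agglomeration on Euclidean row
distances. The implementation is a direct O(n³) agglomeration — the inputs
are ≤ a few dozen comparisons/organs — with a fixed tie-break: among
equally close cluster pairs, merge the lexicographically smallest pair of
sorted leaf-label tuples. This makes output independent of input row
order, which scipy's linkage does not guarantee under ties; on tie-free
inputs the cophenetic matrices agree with scipy exactly (tested).
Organ profiles are compared on log₂(RPKM + 1) by default (variance
stabilization); a raw-scale option exists, where the highlight distance
(default 20 000) for flagging close merges is on the natural scale of the
data.

## Whorl specificity

"Ten-fold above the rest" is read conservatively: the denominator is the
**maximum** over the other organs (plus a 0.1-RPKM floor guarding zeros),
with strict inequality; `against="mean"`/`"sum"` switch to laxer
readings. Any gene passing the rule with floor 0 has
τ ≥ 1 − 1/factor ≈ 0.9, connecting the rule to the tissue-specificity
index; τ is undefined (NaN) for all-zero genes. Collapse maps cultivar
organs onto wild whorls through an explicit homology map (e.g. inner
petal → stamen whorl), averages cultivar organs landing on the same whorl,
and re-applies the identical rule; it reports per-whorl retention, the
mean τ drop, and a z-scored matrix ready for heatmap plotting.

## Degradome scanning

Scoring follows the classical plant-target penalty scheme: mismatch 1.0,
G:U wobble 0.5, single-nucleotide gap 1.0, each doubled at miRNA
positions 2–13 from the 5′ end; a perfect complement scores 0 and sites
score ≤ 5 by default (scores are penalties, so *lower* is better; the
cutoff flag accepts any value). At most one bulge is allowed: a bulged
miRNA base is charged at its own position weight; a bulged transcript base
between miRNA positions g and g+1 is charged the doubled weight whenever
it touches the 2–13 region. Alignments placing the cleavage register
(position 10) in a gap are not reported, since their slice position is
undefined. The slice site is the transcript base paired to miRNA position
10 (1-based, so an ungapped site starting at s maps to s + L − 10 for an
L-nt miRNA). The scanner is vectorized over all window offsets via
cumulative penalty sums; the two outermost offsets of each gapped family
are not scanned (they would index outside the transcript), a negligible
edge effect.

Categories follow the conventional degradome classes: 4 = the position
holds exactly one read; else 0 = unique transcript-wide maximum,
1 = tied maximum, 2 = above the per-position median, 3 = otherwise; a
position with no read gets no category and cannot be called a target.
Significance is empirical: n mononucleotide shuffles of the miRNA
(default 99) are each re-scanned over the whole transcript set, a success
being any site with score ≤ observed and category ≤ observed;
p = (1 + successes)/(1 + n), so the best attainable p at 99 shuffles is
0.01 and at least 19 shuffles are required for any resolution at
α = 0.05. Shuffling the miRNA rather than the transcripts preserves the
target-space composition and is orders of magnitude cheaper. Merged-
library analysis sums pileups position-wise and re-categorizes — two
libraries contributing one read each can upgrade a category-4 site to a
read-supported class, which is the point of merging.

## Phylogeny, orthology, qPCR

NJ is the classical Saitou–Nei algorithm (Q-criterion, standard branch
lengths, final three-node star solved exactly); ties in Q break by label
order and negative branch lengths are clamped to 0 with a log entry (a
presentation convention; clamping never triggers on additive input, where
path lengths reproduce the input distances to < 10⁻⁹, tested on random
additive trees and cross-checked topologically against scikit-bio's NJ).
RBH requires *unique* mutual best hits; tied best scores disqualify a
query and are logged. Similarity scores are taken as input — there is no
aligner here; the bundled shared-k-mer scorer (k = 3 multiset
intersection) is a deliberately simple similarity adequate for simulated
proteomes and demos, not a BLAST substitute for real data.

ΔΔCt averages technical replicates on the Ct scale (the standard
convention), so RQ of the calibrator is exactly 1 per gene and any
sample-wide Ct shift cancels. Platform agreement is per-gene Pearson on
log₂(RQ) vs log₂(RPKM + 1) over ≥ 3 shared samples (linear-scale option
available); note the +1 pseudocount makes "r = 1 for proportional
profiles" exact only on the linear scale. No amplification-efficiency
correction is applied.

## Pipeline and reproducibility

`run_pipeline` wires the stages in dependency order over a nested config
(unknown keys rejected before anything runs). One global seed fans out to
fixed per-stage seeds; all randomness flows through numpy Generators, and
every output file's SHA-256 is recorded in a manifest — the suite asserts
byte-identical reruns. The demo configuration uses 800 genes, 3 cultivars
× 3 organs × 3 replicates, 6 miRNAs/20 transcripts and 39 shuffles: sizes
chosen so the full pipeline completes in seconds while every stage still
has enough signal to produce non-trivial output (39 rather than the
minimum 19 shuffles because 19 makes the best attainable p exactly 0.05,
which the strict p < 0.05 confidence cut can never pass). The qPCR stage
derives synthetic Ct values from the simulated expression of a few genes
(one cycle per doubling of abundance, ±0.15 cycles of noise), since Ct
tables are an input format with no upstream generator of their own.

## Known limitations

- The exact test assumes equalized library sizes; mean scaling is exact
  under pure depth scaling but not under composition bias (no TMM).
- Dispersion moderation uses a fixed prior_df rather than estimating it;
  with many replicates the heavy shrinkage is merely harmless.
- KS enrichment p-values are asymptotic by default and slightly
  conservative for very small terms; use `method="exact"` for those.
- The degradome empirical null is the package's own construction;
  analytic nulls from dedicated PARE pipelines will differ in detail.
- No bootstrap support values on NJ trees.
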