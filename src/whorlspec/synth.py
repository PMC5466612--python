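"""Synthetic data with planted ground truth for every pipeline stage.

The expression simulator draws negative-binomial counts (variance
mu + phi * mu^2) for organ x cultivar x replicate samples and plants a
fraction of genes as organ-specific.  Whorl canalization versus fading is
one explicit knob: a gene specific to organ o has its expression elevated
``specificity_fold``-fold in o, and under fading f the excess decays
geometrically into neighbouring whorls with ratio f per whorl of distance
(f = 0: fully canalized, sharply bounded expression; f = 1: the excess
spreads across every whorl, i.e. fully faded specification).

The companion generators plant enriched GO terms among effect genes,
miRNA complementary sites with degradome read peaks at the slice position,
and paired proteomes with known ortholog pairs plus an additive distance
matrix drawn from a random tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TruthLabels
from .phylo import similarity_table

AA = "ACDEFGHIKLMNPQRSTVWY"
_RNA_COMPLEMENT_DNA = {"A": "T", "C": "G", "G": "C", "U": "A"}


@dataclass
class SimConfig:
    """Study-design and generative parameters of the simulator."""

    n_genes: int = 2000
    organs: tuple[str, ...] = ("sepal", "petal", "stamen")
    cultivars: tuple[str, ...] = ("wild",)
    n_replicates: int = 3
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    frac_specific: float = 0.1
    specificity_fold: float = 20.0
    fading: float | dict[str, float] = 0.0
    seed: int = 0
    gene_length_range: tuple[int, int] = (200, 3000)
    gene_mean_sigma: float = 1.0       # log-normal spread of per-gene baselines
    library_size_sigma: float = 0.2    # log-normal spread of library depths

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.frac_specific <= 1:
            raise ValueError("frac_specific must lie in [0, 1]")
        if self.specificity_fold <= 1:
            raise ValueError("specificity_fold must exceed 1")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        for f in self.fading_map().values():
            if not 0 <= f <= 1:
                raise ValueError("fading must lie in [0, 1]")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid gene_length_range")

    def fading_map(self) -> dict[str, float]:
        if isinstance(self.fading, dict):
            missing = set(self.cultivars) - set(self.fading)
            if missing:
                raise ValueError(f"fading missing for cultivars: {sorted(missing)}")
            return {c: float(self.fading[c]) for c in self.cultivars}
        return {c: float(self.fading) for c in self.cultivars}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) with variance mean + phi * mean^2 via gamma-Poisson."""
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Simulate an organ x cultivar x replicate count matrix with planted
    organ-specific genes; reproducible for a fixed config and seed."""
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    lo, hi = config.gene_length_range
    lengths = pd.Series(rng.integers(lo, hi + 1, size=config.n_genes),
                        index=genes, name="length")
    base = config.baseline_mean * rng.lognormal(
        mean=-0.5 * config.gene_mean_sigma ** 2, sigma=config.gene_mean_sigma,
        size=config.n_genes)

    n_spec = int(round(config.frac_specific * config.n_genes))
    spec_idx = rng.choice(config.n_genes, size=n_spec, replace=False)
    organs = list(config.organs)
    specific_map = {genes[g]: organs[k % len(organs)]
                    for k, g in enumerate(sorted(spec_idx))}

    fading = config.fading_map()
    excess = config.specificity_fold - 1.0
    sample_ids, meta_rows, cols = [], [], {}
    for cultivar in config.cultivars:
        f = fading[cultivar]
        for organ in organs:
            fold = np.ones(config.n_genes)
            for gi, g in enumerate(genes):
                home = specific_map.get(g)
                if home is None:
                    continue
                dist = abs(organs.index(home) - organs.index(organ))
                fold[gi] = 1.0 + excess * (f ** dist if dist > 0 else 1.0)
            for rep in range(1, config.n_replicates + 1):
                sid = f"{cultivar}_{organ}_r{rep}"
                lib = rng.lognormal(mean=0.0, sigma=config.library_size_sigma)
                mu = base * fold * lib
                cols[sid] = _nb_draw(rng, mu, config.dispersion)
                sample_ids.append(sid)
                meta_rows.append((sid, organ, cultivar, rep))
    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(meta_rows, columns=["sample", "organ", "cultivar",
                                               "replicate"]).set_index("sample")
    matrix = ExpressionMatrix(values=values, lengths=lengths, samples=samples,
                              unit="counts")
    truth = TruthLabels(specific_gene_map=specific_map)
    return matrix, truth


def simulate_go_annotation(config: SimConfig, truth: TruthLabels,
                           n_terms: int = 50, n_enriched: int = 5,
                           enrichment_odds: float = 10.0,
                           term_size: int = 30,
                           mean_terms_per_gene: float = 2.0,
                           seed: int | None = None) -> dict[str, set[str]]:
    """Random gene -> GO annotation with ``n_enriched`` terms planted to
    preferentially annotate genes carrying planted effects.

    Background terms are assigned uniformly (every gene receives at least
    one); each planted term annotates ``term_size`` genes drawn with odds
    ``enrichment_odds`` : 1 in favour of effect genes.  Planted term ids are
    recorded in ``truth.enriched_terms`` under the key ``"*"``.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 GO terms")
    if n_enriched > n_terms:
        raise ValueError("n_enriched cannot exceed n_terms")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    bg_terms = [f"GO:{i:07d}" for i in range(n_terms - n_enriched)]
    planted = [f"GO:{9000000 + i}" for i in range(n_enriched)]

    annotation: dict[str, set[str]] = {}
    for g in genes:
        k = 1 + rng.poisson(max(mean_terms_per_gene - 1.0, 0.0))
        chosen = rng.choice(len(bg_terms), size=min(k, len(bg_terms)),
                            replace=False)
        annotation[g] = {bg_terms[i] for i in chosen}

    effect = np.array([g in truth.specific_gene_map for g in genes])
    weights = np.where(effect, float(enrichment_odds), 1.0)
    for term in planted:
        p = weights / weights.sum()
        chosen = rng.choice(len(genes), size=term_size, replace=False, p=p)
        for i in chosen:
            annotation[genes[i]].add(term)
    truth.enriched_terms["*"] = set(planted)
    return annotation


@dataclass
class DegradomeSim:
    mirnas: dict[str, str]                  # RNA alphabet
    transcripts: dict[str, str]             # DNA alphabet
    profiles: dict[str, dict[str, dict[int, int]]]  # library -> pileup
    truth: TruthLabels


def _random_seq(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def simulate_degradome(config: SimConfig, n_mirnas: int = 10,
                       n_targets: int = 5, n_transcripts: int = 50,
                       transcript_length: int = 400, mirna_length: int = 21,
                       peak_fold: float = 50.0, background_mean: float = 2.0,
                       background_dispersion: float = 0.5,
                       libraries: tuple[str, ...] = ("L1",),
                       seed: int | None = None) -> DegradomeSim:
    """Plant miRNA complementary sites in transcripts with degradome peaks.

    The first ``n_targets`` miRNAs each target one distinct transcript: the
    reverse complement of the miRNA is inserted and every library's pileup
    receives ``peak_fold x background_mean`` reads at the slice position
    (the base paired to miRNA position 10) over NB background noise.
    """
    if n_mirnas < 1:
        raise ValueError("need at least one miRNA")
    if n_targets > min(n_mirnas, n_transcripts):
        raise ValueError("more planted targets than miRNAs/transcripts")
    if peak_fold <= 0:
        raise ValueError("peak_fold must be positive for category-0 truth")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)

    mirnas = {f"miR{i + 1:03d}": _random_seq(rng, mirna_length, "ACGU")
              for i in range(n_mirnas)}
    transcripts = {f"tx{i + 1:03d}": _random_seq(rng, transcript_length, "ACGT")
                   for i in range(n_transcripts)}

    truth = TruthLabels()
    mirna_ids = sorted(mirnas)
    tx_ids = sorted(transcripts)
    slice_sites: list[tuple[str, int]] = []
    for k in range(n_targets):
        mid, tid = mirna_ids[k], tx_ids[k]
        m = mirnas[mid]
        site_dna = "".join(_RNA_COMPLEMENT_DNA[c] for c in reversed(m))
        start0 = int(rng.integers(20, transcript_length - mirna_length - 20))
        tx = transcripts[tid]
        transcripts[tid] = (tx[:start0] + site_dna
                            + tx[start0 + mirna_length:])
        slice_pos = start0 + 1 + mirna_length - 10  # 1-based, miRNA position 10
        truth.true_targets.append((mid, tid, slice_pos))
        slice_sites.append((tid, slice_pos))

    peak = max(int(round(peak_fold * background_mean)), 2)
    profiles: dict[str, dict[str, dict[int, int]]] = {}
    for lib in libraries:
        prof: dict[str, dict[int, int]] = {}
        for tid in tx_ids:
            counts = _nb_draw(rng, np.full(transcript_length, background_mean),
                              background_dispersion)
            # keep background strictly below the planted peak
            counts = np.minimum(counts, peak - 1)
            prof[tid] = {int(p + 1): int(c) for p, c in enumerate(counts) if c > 0}
        for tid, pos in slice_sites:
            prof[tid][pos] = peak
        profiles[lib] = prof
    return DegradomeSim(mirnas=mirnas, transcripts=transcripts,
                        profiles=profiles, truth=truth)


@dataclass
class ProteinFamilySim:
    proteome_a: dict[str, str]
    proteome_b: dict[str, str]
    scores_ab: pd.DataFrame
    scores_ba: pd.DataFrame
    distances: pd.DataFrame
    truth: TruthLabels


def _random_additive_tree(rng: np.random.Generator, labels: list[str]
                          ) -> tuple[str, pd.DataFrame]:
    """Random unrooted binary tree with uniform(0.1, 1) branch lengths;
    returns (newick, exact path-length distance matrix)."""
    # adjacency: node -> list of (neighbor, length); leaves are label strings
    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"_n{next_internal[0]}"

    adj: dict[str, list[tuple[str, float]]] = {}

    def connect(a, b, ln):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    def bl():
        return float(rng.uniform(0.1, 1.0))

    center = new_internal()
    for lab in labels[:3]:
        connect(center, lab, bl())
    for lab in labels[3:]:
        # split a random edge with a new internal node and attach the leaf
        edges = [(a, b) for a in adj for b, _ in adj[a] if a < b]
        a, b = edges[rng.integers(0, len(edges))]
        ln = next(l for nb, l in adj[a] if nb == b)
        adj[a] = [(nb, l) for nb, l in adj[a] if nb != b]
        adj[b] = [(nb, l) for nb, l in adj[b] if nb != a]
        mid = new_internal()
        cut = float(rng.uniform(0.2, 0.8)) * ln
        connect(a, mid, cut)
        connect(mid, b, ln - cut)
        connect(mid, lab, bl())

    def distances_from(start: str) -> dict[str, float]:
        seen = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, l in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + l
                    stack.append(v)
        return seen

    dm = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        d = distances_from(a)
        for b in labels:
            dm.loc[a, b] = d[b]

    def to_newick(node: str, parent: str | None) -> str:
        children = [(v, l) for v, l in adj[node] if v != parent]
        if not children:
            return node
        parts = [f"{to_newick(v, node)}:{l:.12g}" for v, l in children]
        return "(" + ",".join(parts) + ")"

    return to_newick(center, None) + ";", dm


def simulate_protein_families(config: SimConfig, n_families: int = 8,
                              seq_length: int = 120,
                              mutation_rate: float = 0.05,
                              seed: int | None = None) -> ProteinFamilySim:
    """Paired proteomes with known ortholog pairs and an additive tree.

    Each family has an ancestral protein; the two proteomes carry
    independently mutated copies, so shared k-mer similarity is highest
    between true ortholog pairs.  A random additive distance matrix over the
    family labels is emitted alongside for NJ testing.
    """
    if n_families < 4:
        raise ValueError("need at least 4 families")
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    labels = [f"fam{i + 1:02d}" for i in range(n_families)]

    def mutate(seq: str) -> str:
        out = list(seq)
        n_mut = rng.binomial(len(seq), mutation_rate)
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            choices = AA.replace(out[pos], "")
            out[pos] = choices[rng.integers(0, len(choices))]
        return "".join(out)

    proteome_a, proteome_b = {}, {}
    pairs = []
    for fam in labels:
        ancestor = _random_seq(rng, seq_length, AA)
        a_id, b_id = f"{fam}_A", f"{fam}_B"
        proteome_a[a_id] = mutate(ancestor)
        proteome_b[b_id] = mutate(ancestor)
        pairs.append((a_id, b_id))

    scores_ab = similarity_table(proteome_a, proteome_b)
    scores_ba = similarity_table(proteome_b, proteome_a)
    newick, dm = _random_additive_tree(rng, labels)
    truth = TruthLabels(ortholog_pairs=pairs, tree_newick=newick)
    return ProteinFamilySim(proteome_a=proteome_a, proteome_b=proteome_b,
                            scores_ab=scores_ab, scores_ba=scores_ba,
                            distances=dm, truth=truth)
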