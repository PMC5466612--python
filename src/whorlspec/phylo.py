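"""Reciprocal-best-hit orthology and Neighbor-Joining tree construction.

The NJ implementation is the classical Saitou-Nei algorithm with the
standard Q-criterion and branch-length formulas; on an additive distance
matrix the returned tree's path lengths reproduce the input distances
exactly.  Ties in the Q matrix resolve deterministically by label order and
negative branch lengths are clamped to zero (with a log entry), a common
presentation convention.

Similarity scores for RBH are taken as precomputed tables; a simple shared
k-mer scorer is included so the module is usable end to end on plain FASTA
input without an external aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# -- reciprocal best hits ------------------------------------------------------

def rbh_orthologs(scores_ab: pd.DataFrame, scores_ba: pd.DataFrame
                  ) -> list[tuple[str, str]]:
    """Reciprocal best hits between two protein sets.

    Both tables need columns query, subject, score (higher is better).
    A pair (a, b) is reported iff b is a's unique best hit in B and a is
    b's unique best hit in A; tied best scores disqualify the query.
    """
    if scores_ab.empty or scores_ba.empty:
        raise ValueError("similarity tables must be non-empty")

    def unique_best(table: pd.DataFrame) -> dict[str, str]:
        best: dict[str, str] = {}
        for query, grp in table.groupby("query"):
            mx = grp["score"].max()
            tops = grp.loc[grp["score"] == mx, "subject"].tolist()
            if len(tops) == 1:
                best[str(query)] = str(tops[0])
            else:
                log.info("query %s has tied best hits %s; excluded", query, tops)
        return best

    ab = unique_best(scores_ab)
    ba = unique_best(scores_ba)
    pairs = [(a, b) for a, b in ab.items() if ba.get(b) == a]
    return sorted(pairs)


def kmer_similarity(seq_a: str, seq_b: str, k: int = 3) -> float:
    """Shared k-mer count (multiset intersection) — a lightweight stand-in
    similarity for demos and simulations."""
    from collections import Counter

    ca = Counter(seq_a[i:i + k] for i in range(len(seq_a) - k + 1))
    cb = Counter(seq_b[i:i + k] for i in range(len(seq_b) - k + 1))
    return float(sum((ca & cb).values()))


def similarity_table(set_a: dict[str, str], set_b: dict[str, str],
                     k: int = 3) -> pd.DataFrame:
    """All-vs-all shared k-mer similarity table (query in A, subject in B)."""
    rows = [(qa, sb, kmer_similarity(sa, ssb, k))
            for qa, sa in set_a.items() for sb, ssb in set_b.items()]
    return pd.DataFrame(rows, columns=["query", "subject", "score"])


# -- distances -----------------------------------------------------------------

def p_distance(aligned: dict[str, str]) -> pd.DataFrame:
    """Proportion of differing non-gap columns between aligned protein strings."""
    names = list(aligned)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    arr = {n: np.frombuffer(aligned[n].upper().encode(), dtype="S1")
           for n in names}
    gap = np.frombuffer(b"-", dtype="S1")[0]
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ok = (arr[a] != gap) & (arr[b] != gap)
            if not ok.any():
                raise ValueError(f"no comparable columns between {a} and {b}")
            d = float((arr[a][ok] != arr[b][ok]).mean())
            out.loc[a, b] = out.loc[b, a] = d
    return out


# -- neighbor joining ----------------------------------------------------------

@dataclass
class _Node:
    label: str                  # smallest contained leaf name (tie-break key)
    newick: str                 # subtree in newick, without trailing length


def nj_tree(dm: pd.DataFrame) -> str:
    """Classical Neighbor-Joining tree from a symmetric distance matrix.

    Returns an unrooted tree as newick with branch lengths (trifurcating
    root).  Ties in the Q criterion are broken by the lexicographic order of
    node labels; negative branch lengths are clamped to 0 and logged.
    """
    labels = [str(x) for x in dm.index]
    if len(labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    d = dm.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (np.abs(np.diag(d)) > 1e-12).any():
        raise ValueError("distance matrix diagonal must be zero")

    nodes = [_Node(label=lab, newick=lab) for lab in labels]

    def clamp(x: float, where: str) -> float:
        if x < 0:
            if x < -1e-9:
                log.info("negative branch length %.3g at %s clamped to 0", x, where)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = [(tuple(sorted((nodes[i].label, nodes[j].label))), i, j)
                 for i, j in zip(*np.nonzero(np.isclose(q, qmin, rtol=0.0,
                                                        atol=1e-9)))
                 if i < j]
        _, i, j = min(cands)
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2)),
                   f"{nodes[i].label}")
        lj = clamp(d[i, j] - li, f"{nodes[j].label}")
        new = _Node(
            label=min(nodes[i].label, nodes[j].label),
            newick=f"({nodes[i].newick}:{li:.12g},{nodes[j].newick}:{lj:.12g})",
        )
        du = 0.5 * (d[:, i] + d[:, j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = np.maximum(du[keep], 0.0)
        nodes = [nodes[k] for k in keep] + [new]
        d = d_new

    # final trifurcation: solve the three pairwise equations
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = clamp(0.5 * (dab + dac - dbc), a.label)
    lb = clamp(0.5 * (dab + dbc - dac), b.label)
    lc = clamp(0.5 * (dac + dbc - dab), c.label)
    return (f"({a.newick}:{la:.12g},{b.newick}:{lb:.12g},"
            f"{c.newick}:{lc:.12g});")


def tree_path_distances(newick: str) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a newick tree (internal helper used
    to verify additivity and round-trips)."""
    tree = _parse_newick(newick)
    leaves: list[tuple[str, list[tuple[int, float]]]] = []

    def walk(node, path):
        name, length, children = node
        path = path + [(id(node), length)]
        if not children:
            leaves.append((name, path))
        for ch in children:
            walk(ch, path)

    walk(tree, [])
    names = [n for n, _ in leaves]
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, (na, pa) in enumerate(leaves):
        ancestors = {nid: k for k, (nid, _) in enumerate(pa)}
        for nb, pb in leaves[i + 1:]:
            shared = 0
            for k, (nid, _) in enumerate(pb):
                if nid in ancestors and ancestors[nid] == k:
                    shared = k
                else:
                    break
            dist = sum(l for _, l in pa[shared + 1:]) + sum(
                l for _, l in pb[shared + 1:])
            out.loc[na, nb] = out.loc[nb, na] = dist
    return out


def _parse_newick(s: str):
    """Minimal newick parser -> (name, branch_length, children) tuples."""
    s = s.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        children = []
        name = ""
        if s[pos] == "(":
            pos += 1
            while True:
                children.append(parse())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        while pos < len(s) and s[pos] not in ":,()":
            name += s[pos]
            pos += 1
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            num = ""
            while pos < len(s) and s[pos] not in ",()":
                num += s[pos]
                pos += 1
            length = float(num)
        return (name, length, children)

    return parse()


def leaf_splits(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions (as leaf sets on one side) of an unrooted
    tree; used for Robinson-Foulds comparisons."""
    tree = _parse_newick(newick)
    all_leaves: set[str] = set()
    splits: list[set] = []

    def walk(node):
        name, _, children = node
        if not children:
            all_leaves.add(name)
            return {name}
        below = set()
        for ch in children:
            below |= walk(ch)
        splits.append(set(below))
        return below

    walk(tree)
    out = set()
    for sp in splits:
        if 1 < len(sp) < len(all_leaves) - 1:
            side = frozenset(sp)
            other = frozenset(all_leaves - sp)
            out.add(min(side, other, key=lambda x: sorted(x)))
    return out


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds distance (symmetric difference of bipartitions)."""
    return len(leaf_splits(newick_a) ^ leaf_splits(newick_b))
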