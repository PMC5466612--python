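"""Readers and writers for the plain-text formats used across the pipeline.

Conventions: TSV with a header row, UTF-8, no quoting; FASTA wrapped at 70
columns (via Biopython); newick with branch lengths and unquoted labels;
ground-truth labels as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ExpressionMatrix, TruthLabels


# -- expression matrices -------------------------------------------------------

def write_counts(matrix: ExpressionMatrix, counts_path, metadata_path) -> None:
    df = matrix.values.copy()
    df.insert(0, "length", matrix.lengths)
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t")
    meta = matrix.samples.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


def read_counts(counts_path, metadata_path, unit: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="gene")
    lengths = df.pop("length")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    return ExpressionMatrix(values=df, lengths=lengths, samples=meta, unit=unit)


# -- annotation ----------------------------------------------------------------

def write_annotation(gene_to_terms: dict[str, set[str]], path) -> None:
    rows = [(g, t) for g in sorted(gene_to_terms) for t in sorted(gene_to_terms[g])]
    pd.DataFrame(rows, columns=["gene", "go_id"]).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["go_id"]):
        out.setdefault(str(gene), set()).add(str(term))
    return out


# -- FASTA ---------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- degradome pileups ---------------------------------------------------------

def write_pileup(profile: dict[str, dict[int, int]], path) -> None:
    rows = [
        (tx, pos, profile[tx][pos])
        for tx in sorted(profile)
        for pos in sorted(profile[tx])
    ]
    pd.DataFrame(rows, columns=["transcript", "position", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_pileup(path) -> dict[str, dict[int, int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, int]] = {}
    for tx, pos, count in zip(df["transcript"], df["position"], df["count"]):
        out.setdefault(str(tx), {})[int(pos)] = int(count)
    return out


# -- similarity tables ---------------------------------------------------------

def write_similarity(table: pd.DataFrame, path) -> None:
    table[["query", "subject", "score"]].to_csv(path, sep="\t", index=False)


def read_similarity(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- truth / JSON --------------------------------------------------------------

def write_truth(truth: TruthLabels, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_truth(path) -> TruthLabels:
    return TruthLabels.from_dict(json.loads(Path(path).read_text()))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
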