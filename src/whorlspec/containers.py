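"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a genes x samples table of
counts or normalized abundances together with per-gene lengths and per-sample
(organ, cultivar, replicate) labels.  Units are tracked explicitly so that
operations can refuse inputs on the wrong scale (e.g. RPKM computed twice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "RPKM", "TPM", "zscore")

SAMPLE_COLUMNS = ("organ", "cultivar", "replicate")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with gene lengths and sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    lengths
        Per-gene length in bp, indexed like ``values``.
    samples
        DataFrame indexed by sample id with columns ``organ``, ``cultivar``
        and ``replicate``; the index must match the columns of ``values``.
    unit
        One of ``counts``, ``RPKM``, ``TPM`` or ``zscore``.
    """

    values: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not self.samples.index.is_unique:
            raise ValueError("sample ids must be unique")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and sample table index disagree")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        self.lengths = self.lengths.reindex(self.values.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.unit != "zscore" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def group_key(self) -> pd.Series:
        """organ|cultivar composite label per sample."""
        return self.samples["organ"].astype(str) + "|" + self.samples["cultivar"].astype(str)

    def samples_for(self, organ: str, cultivar: str | None = None) -> list[str]:
        mask = self.samples["organ"] == organ
        if cultivar is not None:
            mask &= self.samples["cultivar"] == cultivar
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            lengths=self.lengths.copy(),
            samples=self.samples.loc[sample_ids].copy(),
            unit=self.unit,
        )

    def with_values(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values, lengths=self.lengths.copy(), samples=self.samples.copy(), unit=unit
        )

    def group_means(self, by: tuple[str, ...] = ("organ", "cultivar")) -> pd.DataFrame:
        """Mean expression per gene for each sample group (default organ x cultivar).

        Column labels are ``organ`` when a single grouping field is used, else
        ``organ|cultivar`` composites, in first-appearance order.
        """
        keys = self.samples[list(by)].astype(str).agg("|".join, axis=1)
        out = {}
        for key in keys.drop_duplicates():
            cols = list(keys.index[keys == key])
            out[key] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out, index=self.values.index)


@dataclass
class TruthLabels:
    """Ground truth emitted by the simulator for downstream recovery tests."""

    specific_gene_map: dict[str, str] = field(default_factory=dict)
    enriched_terms: dict[str, set[str]] = field(default_factory=dict)
    true_targets: list[tuple[str, str, int]] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    tree_newick: str | None = None

    def to_dict(self) -> dict:
        return {
            "specific_gene_map": dict(self.specific_gene_map),
            "enriched_terms": {k: sorted(v) for k, v in self.enriched_terms.items()},
            "true_targets": [list(t) for t in self.true_targets],
            "ortholog_pairs": [list(p) for p in self.ortholog_pairs],
            "tree_newick": self.tree_newick,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthLabels":
        return cls(
            specific_gene_map=dict(d.get("specific_gene_map", {})),
            enriched_terms={k: set(v) for k, v in d.get("enriched_terms", {}).items()},
            true_targets=[tuple(t) for t in d.get("true_targets", [])],
            ortholog_pairs=[tuple(p) for p in d.get("ortholog_pairs", [])],
            tree_newick=d.get("tree_newick"),
        )


def organ_distance(organs: list[str], a: str, b: str) -> int:
    """Whorl distance between two organs in their concentric order."""
    return abs(organs.index(a) - organs.index(b))
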