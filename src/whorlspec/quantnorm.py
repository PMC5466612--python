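"""Normalization and sample-level QC.

RPKM (reads per kilobase per million mapped reads) with mapped reads taken
as the column sum of the count matrix; miRNA TPM as count x 1e6 / total
mapped reads; per-gene row z-scores (population sd); replicate QC by
pairwise Pearson correlation with the 0.2 (outlier) / 0.73 (low-agreement)
thresholds; and Euclidean-distance complete-linkage clustering of organ mean
profiles with an optional highlight distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import Dendrogram, agglomerate, euclidean_distance_matrix
from .containers import ExpressionMatrix

log = logging.getLogger(__name__)

OUTLIER_THRESHOLD = 0.2
WITHIN_THRESHOLD = 0.73
HIGHLIGHT_DISTANCE = 20000.0


def rpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts -> RPKM: count / (length_kb * mapped_millions), with
    mapped_millions = column sum / 1e6."""
    if counts.unit != "counts":
        raise ValueError(f"rpkm expects counts, got unit {counts.unit!r}")
    colsums = counts.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero) > 0:
        raise ValueError(f"zero mapped reads in sample(s): {list(zero.index)}")
    length_kb = counts.lengths / 1000.0
    vals = counts.values.div(colsums / 1e6, axis=1).div(length_kb, axis=0)
    return counts.with_values(vals, unit="RPKM")


def mirna_tpm(mirna_counts: pd.Series | np.ndarray, mapped_total: float):
    """miRNA abundance: reads mapped to the miRNA x 1e6 / total mapped reads."""
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    arr = np.asarray(mirna_counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative miRNA counts")
    out = arr * 1e6 / float(mapped_total)
    if isinstance(mirna_counts, pd.Series):
        return pd.Series(out, index=mirna_counts.index)
    return out


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Row z-scores with population (divisor n) standard deviation.

    Rows with zero spread map to all-zeros.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("z-score needs at least 2 columns")
    x = matrix.values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    vals = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(vals, unit="zscore")


@dataclass
class QCReport:
    """Replicate agreement report: pairwise Pearson correlations over samples
    plus the flags the removal narrative is based on (removal is reported,
    never applied silently)."""

    correlations: pd.DataFrame
    flagged: pd.DataFrame  # sample, group, flag, detail
    outlier_threshold: float
    within_threshold: float
    warnings: list[str] = field(default_factory=list)

    @property
    def outliers(self) -> list[str]:
        return list(self.flagged.loc[self.flagged["flag"] == "outlier", "sample"])

    @property
    def low_agreement(self) -> list[str]:
        return list(self.flagged.loc[self.flagged["flag"] == "low-agreement", "sample"])

    @property
    def removed(self) -> list[str]:
        return sorted(set(self.flagged["sample"]))


def _correlation_input(matrix: ExpressionMatrix, log_transform: bool) -> pd.DataFrame:
    vals = matrix.values
    if log_transform:
        if matrix.unit == "counts":
            vals = rpkm(matrix).values
        vals = np.log2(vals + 1.0)
    return vals


def replicate_qc(matrix: ExpressionMatrix,
                 within_threshold: float = WITHIN_THRESHOLD,
                 outlier_threshold: float = OUTLIER_THRESHOLD,
                 log_transform: bool = True) -> QCReport:
    """Flag replicates that disagree with their siblings.

    A replicate is an "outlier" when its Pearson correlation with EVERY
    sibling replicate of the same organ x cultivar group is below
    ``outlier_threshold``; it is "low-agreement" when ANY sibling correlation
    falls below ``within_threshold``.  Correlations default to the
    log2(RPKM+1) scale.
    """
    vals = _correlation_input(matrix, log_transform)
    corr = vals.corr(method="pearson")
    rows = []
    warnings: list[str] = []
    groups = matrix.group_key()
    for group in groups.drop_duplicates():
        members = list(groups.index[groups == group])
        if len(members) < 2:
            raise ValueError(f"group {group} has fewer than 2 replicates")
        flagged_here = []
        for s in members:
            sib = [corr.loc[s, t] for t in members if t != s]
            if all(c < outlier_threshold for c in sib):
                rows.append((s, group, "outlier",
                             f"all sibling correlations < {outlier_threshold}"))
                flagged_here.append(s)
            elif any(c < within_threshold for c in sib):
                rows.append((s, group, "low-agreement",
                             f"a sibling correlation < {within_threshold}"))
                flagged_here.append(s)
        if len(members) - len(flagged_here) < 2:
            if flagged_here:
                msg = (f"group {group} would drop below 2 replicates if flagged "
                       f"samples {flagged_here} were removed")
                warnings.append(msg)
                log.warning(msg)
    flagged = pd.DataFrame(rows, columns=["sample", "group", "flag", "detail"])
    return QCReport(correlations=corr, flagged=flagged,
                    outlier_threshold=outlier_threshold,
                    within_threshold=within_threshold, warnings=warnings)


def organ_dendrogram(matrix: ExpressionMatrix,
                     highlight_below: float = HIGHLIGHT_DISTANCE,
                     log_transform: bool = True,
                     method: str = "complete") -> Dendrogram:
    """Cluster organ x cultivar mean expression profiles.

    Replicate means are computed per organ x cultivar group, pairwise
    Euclidean distances taken between the mean profiles (on log2(RPKM+1)
    by default), and the profiles agglomerated with complete linkage.
    Merges below ``highlight_below`` are flagged in the result.
    """
    vals = _correlation_input(matrix, log_transform)
    groups = matrix.group_key()
    profiles = {}
    for group in groups.drop_duplicates():
        cols = list(groups.index[groups == group])
        profiles[group] = vals[cols].mean(axis=1)
    prof = pd.DataFrame(profiles)
    if prof.shape[1] < 2:
        raise ValueError("need at least 2 organ groups to cluster")
    dist = euclidean_distance_matrix(prof)
    return agglomerate(dist, method=method, highlight_below=highlight_below)
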