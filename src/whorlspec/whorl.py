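"""Whorl-specific genes, the tissue-specificity index tau, and the
quantification of specificity collapse in double-flower cultivars.

A gene is whorl-specific when its mean abundance in one organ exceeds
``factor`` (default 10) times the maximum over the other organs (plus a
small floor guarding zero denominators).  The canalization index is the
classical tissue-specificity tau: tau = sum(1 - x_i / x_max) / (n - 1) over
organ means, 0 for uniform expression and 1 for single-organ expression.
Collapse is measured by re-applying the same rule to cultivar organ means
mapped onto wild whorls by positional homology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SPECIFICITY_FACTOR = 10.0
SPECIFICITY_FLOOR = 0.1


def whorl_specific_genes(mean_expr: pd.DataFrame, factor: float = SPECIFICITY_FACTOR,
                         floor: float = SPECIFICITY_FLOOR,
                         against: str = "max") -> pd.DataFrame:
    """Assign genes to organs by the ten-fold rule.

    ``mean_expr`` is genes x organs of organ-mean abundances (RPKM scale).
    A gene is assigned to organ o iff mean(o) > factor * agg(other means +
    floor), strict inequality, with agg the maximum over other organs by
    default ("mean" and "sum" are alternatives).  Returns a table with the
    assigned organ (empty string if none), per-organ means and tau.
    """
    x = mean_expr.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative organ means")
    if mean_expr.shape[1] < 2:
        raise ValueError("need at least 2 organs")
    organs = list(mean_expr.columns)
    n = len(organs)
    assigned = np.full(x.shape[0], "", dtype=object)
    for j, organ in enumerate(organs):
        others = np.delete(x, j, axis=1) + floor
        if against == "max":
            ref = others.max(axis=1)
        elif against == "mean":
            ref = others.mean(axis=1)
        elif against == "sum":
            ref = others.sum(axis=1)
        else:
            raise ValueError(f"unknown aggregation {against!r}")
        hit = x[:, j] > factor * ref
        assigned[hit] = organ
    out = mean_expr.copy()
    out.insert(0, "organ", assigned)
    out["tau"] = canalization_index(mean_expr)
    return out


def canalization_index(mean_expr: pd.DataFrame) -> pd.Series:
    """Tissue-specificity tau per gene over organ means.

    tau = sum_i (1 - x_i / x_max) / (n - 1); NaN for all-zero genes.
    """
    if mean_expr.shape[1] < 2:
        raise ValueError("need at least 2 organs")
    x = mean_expr.to_numpy(dtype=float)
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (n - 1)
    tau[xmax == 0] = np.nan
    return pd.Series(tau, index=mean_expr.index, name="tau")


@dataclass
class CollapseReport:
    """Per-whorl retention of specificity in a cultivar plus the tau shift."""

    retention: pd.Series        # per wild whorl: fraction of specific genes retained
    delta_tau: pd.Series        # per wild whorl: mean (wild tau - cultivar tau)
    per_gene: pd.DataFrame      # gene, whorl, retained, tau_wild, tau_cultivar
    heatmap: pd.DataFrame       # row z-scores of cultivar means for specific genes

    def overall_retention(self) -> float:
        return float(self.per_gene["retained"].mean())


def specificity_collapse(wild_table: pd.DataFrame, cultivar_expr: pd.DataFrame,
                         homology_map: dict[str, str] | None = None,
                         factor: float = SPECIFICITY_FACTOR,
                         floor: float = SPECIFICITY_FLOOR) -> CollapseReport:
    """Measure how much of the wild whorl specificity a cultivar retains.

    ``wild_table`` is the output of :func:`whorl_specific_genes` on wild
    organ means; ``cultivar_expr`` is genes x cultivar-organs of means.
    ``homology_map`` maps cultivar organ -> wild whorl (identity when
    omitted); cultivar organs mapped to the same whorl are averaged.
    Retention: same rule, same factor, applied to the mapped cultivar means.
    """
    wild_organs = [c for c in wild_table.columns if c not in ("organ", "tau")]
    if homology_map is None:
        homology_map = {o: o for o in cultivar_expr.columns}
    unmapped = [o for o in cultivar_expr.columns if o not in homology_map]
    if unmapped:
        raise ValueError(f"cultivar organs without a whorl mapping: {unmapped}")
    bad = sorted(set(homology_map.values()) - set(wild_organs))
    if bad:
        raise ValueError(f"homology map targets unknown wild whorls: {bad}")

    mapped = {}
    for whorl in wild_organs:
        cols = [o for o in cultivar_expr.columns if homology_map[o] == whorl]
        if cols:
            mapped[whorl] = cultivar_expr[cols].mean(axis=1)
    mapped_expr = pd.DataFrame(mapped, index=cultivar_expr.index)
    if mapped_expr.shape[1] < 2:
        raise ValueError("cultivar maps onto fewer than 2 wild whorls")

    cultivar_table = whorl_specific_genes(mapped_expr, factor=factor, floor=floor)
    specific = wild_table[wild_table["organ"] != ""]
    genes = [g for g in specific.index if g in mapped_expr.index]

    rows = []
    for g in genes:
        whorl = specific.loc[g, "organ"]
        retained = (whorl in mapped_expr.columns
                    and cultivar_table.loc[g, "organ"] == whorl)
        rows.append((g, whorl, bool(retained),
                     float(specific.loc[g, "tau"]),
                     float(cultivar_table.loc[g, "tau"])))
    per_gene = pd.DataFrame(rows, columns=["gene", "whorl", "retained",
                                           "tau_wild", "tau_cultivar"]
                            ).set_index("gene")
    grp = per_gene.groupby("whorl")
    retention = grp["retained"].mean()
    delta_tau = (per_gene["tau_wild"] - per_gene["tau_cultivar"]).groupby(
        per_gene["whorl"]).mean()

    # heatmap-ready row z-scores (population sd) of cultivar means
    sub = mapped_expr.loc[genes].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    heatmap = pd.DataFrame(z, index=genes, columns=mapped_expr.columns)
    return CollapseReport(retention=retention, delta_tau=delta_tau,
                          per_gene=per_gene, heatmap=heatmap)
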