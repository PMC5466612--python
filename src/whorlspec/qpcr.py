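"""Relative quantification of qPCR data and comparison with RNA-seq.

The comparative-Ct (delta-delta-Ct) method against an internal reference
gene: technical replicates are averaged on the Ct scale, delta Ct =
Ct_target - Ct_reference, delta-delta Ct subtracts the calibrator sample's
delta Ct, and the relative quantity is RQ = 2^(-delta-delta Ct), so the
calibrator's RQ is exactly 1 for every gene.  Platform agreement is a
per-gene Pearson correlation between qPCR RQ and RNA-seq abundance over
shared samples, on the log2 scale by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

log = logging.getLogger(__name__)


def ddct(ct: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Delta-delta-Ct relative quantities.

    ``ct`` needs columns gene, sample, ct_target, ct_reference (and
    optionally replicate; technical replicates are averaged on the Ct
    scale first).  Returns a table with delta_ct, ddct and rq per
    gene x sample.
    """
    required = {"gene", "sample", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if ct[["ct_target", "ct_reference"]].isna().any().any():
        bad = ct.loc[ct[["ct_target", "ct_reference"]].isna().any(axis=1),
                     ["gene", "sample"]]
        raise ValueError(f"missing Ct values for {bad.to_dict('records')}")
    if (ct[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    if calibrator not in set(ct["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} not in Ct table")

    mean_ct = (ct.groupby(["gene", "sample"])[["ct_target", "ct_reference"]]
                 .mean().reset_index())
    mean_ct["delta_ct"] = mean_ct["ct_target"] - mean_ct["ct_reference"]
    cal = mean_ct[mean_ct["sample"] == calibrator].set_index("gene")["delta_ct"]
    no_cal = sorted(set(mean_ct["gene"]) - set(cal.index))
    if no_cal:
        raise ValueError(f"genes without calibrator measurement: {no_cal}")
    mean_ct["ddct"] = mean_ct["delta_ct"] - mean_ct["gene"].map(cal)
    mean_ct["rq"] = np.power(2.0, -mean_ct["ddct"])
    return mean_ct[["gene", "sample", "delta_ct", "ddct", "rq"]]


def platform_correlation(rq: pd.DataFrame, rnaseq: pd.DataFrame,
                         alpha: float = 0.05, log_scale: bool = True
                         ) -> pd.DataFrame:
    """Per-gene Pearson correlation between qPCR RQ and RNA-seq abundance.

    ``rq`` and ``rnaseq`` are genes x samples tables; correlations use
    shared samples only (genes with fewer than 3 shared samples are skipped
    with a log entry).  By default RQ is log2-transformed and RNA-seq
    log2(x + 1).  Returns r, pvalue and a significance flag per gene.
    """
    rows = []
    for gene in rq.index:
        if gene not in rnaseq.index:
            log.info("gene %s absent from RNA-seq table; skipped", gene)
            continue
        shared = [s for s in rq.columns if s in rnaseq.columns
                  and pd.notna(rq.loc[gene, s]) and pd.notna(rnaseq.loc[gene, s])]
        if len(shared) < 3:
            log.info("gene %s has %d shared samples (<3); skipped",
                     gene, len(shared))
            continue
        x = rq.loc[gene, shared].to_numpy(dtype=float)
        y = rnaseq.loc[gene, shared].to_numpy(dtype=float)
        if log_scale:
            x = np.log2(x)
            y = np.log2(y + 1.0)
        r, p = pearsonr(x, y)
        rows.append((gene, float(r), float(p), bool(p < alpha), len(shared)))
    out = pd.DataFrame(rows, columns=["gene", "r", "pvalue", "significant",
                                      "n_samples"]).set_index("gene")
    return out
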