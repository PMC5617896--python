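"""FPKM quantification, expression-status calls and averaged-log matrices.

FPKM (fragments per kilobase of transcript per million mapped fragments) for
gene g in sample s is::

    FPKM_gs = counts_gs / (length_g / 1000) / (total_s / 1e6)

with ``total_s`` the column sum of the count matrix (multi-mapped removal is
assumed to have happened upstream; counts are the pipeline's entry point).
Summed over genes, ``FPKM * length_kb`` is exactly 1e6 per sample.

Expression status is anchored on the reference strain: a gene is called
``not_expressed`` when the reference replicate-mean FPKM at a timepoint is
below 1, ``low`` for values in [1, 20], and ``expressed`` above 20.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CountMatrix, ExpressionMatrix, GENOTYPE_ORDER, REFERENCE


def compute_fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """FPKM from integer counts and gene lengths."""
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total count in sample(s): {list(zero.index)}")
    len_kb = counts.lengths / 1000.0
    fpkm = counts.counts.div(len_kb, axis=0).div(totals / 1e6, axis=1)
    return ExpressionMatrix(fpkm, counts.lengths, counts.design)


def reference_means(expr: ExpressionMatrix, timepoint: str) -> pd.Series:
    """Replicate-mean FPKM of the reference strain at a timepoint."""
    samples = expr.design.samples_for(REFERENCE, timepoint)
    if not samples:
        raise ValueError(f"no reference replicates at timepoint {timepoint!r}")
    return expr.fpkm[samples].mean(axis=1)


def expression_status(
    expr: ExpressionMatrix,
    thresholds: tuple[float, float] = (1.0, 20.0),
) -> pd.DataFrame:
    """Per gene x timepoint status in {not_expressed, low, expressed}.

    Boundary convention: FPKM exactly at either threshold is classed ``low``
    (the not-expressed cut is strict: FPKM < 1).
    """
    lo, hi = thresholds
    if not 0 < lo < hi:
        raise ValueError("thresholds must satisfy 0 < low < high")
    out = {}
    for tp in expr.design.timepoints:
        m = reference_means(expr, tp)
        out[tp] = pd.Series(
            np.where(m < lo, "not_expressed", np.where(m <= hi, "low", "expressed")),
            index=m.index,
        )
    return pd.DataFrame(out)


def mean_log_matrix(
    expr: ExpressionMatrix, base: float = 2.0
) -> pd.DataFrame:
    """log_base(replicate-mean FPKM + 1), one column per genotype x timepoint.

    This is the matrix the expression heatmaps cluster: duplicates are
    averaged first, then shifted by one pseudo-FPKM and logged.
    """
    cols = {}
    groups = expr.design.groups()
    order = [
        (g, tp)
        for g in GENOTYPE_ORDER
        for tp in expr.design.timepoints
        if (g, tp) in groups
    ]
    # keep any non-factorial groups too, after the canonical ones
    order += [k for k in groups if k not in order]
    for g, tp in order:
        mean = expr.fpkm[groups[(g, tp)]].mean(axis=1)
        cols[f"{g}_{tp}"] = np.log(mean + 1.0) / np.log(base)
    return pd.DataFrame(cols)
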