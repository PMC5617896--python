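"""Negative-binomial differential expression between mutants and reference.

A self-contained NB Wald test: counts are normalised by median-of-ratios
size factors, the gene-wise dispersion alpha (Var = mu + alpha * mu**2) is
estimated by method of moments from within-group residuals, and the log2
fold change (with pseudocount 0.5) is tested against zero with a delta-method
standard error and a two-sided normal p-value.  Benjamini–Hochberg adjustment
is applied within each contrast and calls use the study cut-offs: fold change
strictly greater than ``fc_threshold`` and adjusted p at most ``alpha``.

Gene-level numbers from this test are not expected to be bit-identical to
any particular external DE package; the calling thresholds, not the engine,
are what downstream dependency classification consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, MUTANT_ORDER, REFERENCE

_LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios normalisation factors.

    For each sample, the factor is the median over genes (restricted to
    genes with no zero count in any sample) of the ratio of the gene's count
    to its geometric mean across samples.
    """
    c = counts.counts
    nonzero = c[(c > 0).all(axis=1)]
    if nonzero.empty:
        raise ValueError("no gene has nonzero counts in every sample")
    log_geomean = np.log(nonzero).mean(axis=1)
    ratios = np.exp(np.log(nonzero).sub(log_geomean, axis=0))
    return ratios.median(axis=0).rename("size_factor")


def _mom_alpha(groups: list[np.ndarray]) -> float:
    """Pooled method-of-moments NB dispersion from within-group residuals."""
    df = 0.0
    ss = 0.0
    w_mu = 0.0
    w_mu2 = 0.0
    for y in groups:
        n = y.size
        if n < 2:
            continue
        m = y.mean()
        ss += ((y - m) ** 2).sum()
        df += n - 1
        w_mu += (n - 1) * m
        w_mu2 += (n - 1) * m * m
    if df <= 0 or w_mu2 <= 0:
        return DISPERSION_FLOOR
    s2 = ss / df
    alpha = (s2 - w_mu / df) / (w_mu2 / df)
    return float(max(alpha, DISPERSION_FLOOR))


def estimate_dispersions(
    counts: CountMatrix, factors: pd.Series | None = None
) -> pd.Series:
    """Gene-wise MoM dispersion pooled over all genotype x timepoint groups.

    Using every replicated group (rather than only the two groups of one
    contrast) stabilises the estimate at small replicate numbers; the
    factorial design makes all groups share the gene's dispersion.
    """
    if factors is None:
        factors = size_factors(counts)
    y = counts.counts / factors
    groups = counts.design.groups()
    out = {}
    arrays = [y[s].values for s in groups.values()]
    for i, gene in enumerate(counts.gene_ids):
        out[gene] = _mom_alpha([a[i] for a in arrays])
    return pd.Series(out, name="dispersion")


def nb_test(
    counts: CountMatrix,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    dispersion_df: int | None = None,
) -> pd.DataFrame:
    """Wald test of one mutant genotype against the reference at a timepoint.

    ``contrast = (genotype, timepoint)``.  When ``dispersions`` is omitted the
    gene dispersion is estimated from the two groups of the contrast alone.
    Genes with zero counts in both groups get ``p = 1``.

    Because the dispersion enters the Wald denominator as an inverse
    variance, its moment estimate is scaled by the unbiasedness factor
    ``df / (df - 2)`` (for df > 2) of the inverse chi-square; without it the
    normal reference for z is noticeably anticonservative at small replicate
    numbers.  ``dispersion_df`` is the residual degrees of freedom behind
    ``dispersions`` when they were estimated elsewhere.
    """
    genotype, timepoint = contrast
    if factors is None:
        factors = size_factors(counts)
    mut_samples = counts.design.samples_for(genotype, timepoint)
    ref_samples = counts.design.samples_for(REFERENCE, timepoint)
    if not mut_samples or not ref_samples:
        raise ValueError(f"empty group in contrast {contrast}")
    y = counts.counts / factors
    y_mut = y[mut_samples].values
    y_ref = y[ref_samples].values
    n_mut, n_ref = y_mut.shape[1], y_ref.shape[1]
    m_mut = y_mut.mean(axis=1)
    m_ref = y_ref.mean(axis=1)

    if dispersions is not None:
        alpha = dispersions.reindex(counts.gene_ids).fillna(DISPERSION_FLOOR).values
        df = dispersion_df if dispersion_df is not None else (n_mut - 1) + (n_ref - 1)
    else:
        alpha = np.array(
            [
                _mom_alpha([y_mut[i], y_ref[i]])
                for i in range(len(counts.gene_ids))
            ]
        )
        df = (n_mut - 1) + (n_ref - 1)
    correction = df / (df - 2) if df > 2 else 1.0

    log2fc = np.log2((m_mut + 0.5) / (m_ref + 0.5))
    var_mut = (m_mut + correction * alpha * m_mut**2) / n_mut
    var_ref = (m_ref + correction * alpha * m_ref**2) / n_ref
    se2 = (
        var_mut / ((m_mut + 0.5) ** 2) + var_ref / ((m_ref + 0.5) ** 2)
    ) / (_LN2**2)
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (m_mut == 0) & (m_ref == 0)
    p = np.where(both_zero, 1.0, p)
    z = np.where(both_zero, 0.0, z)
    log2fc = np.where(both_zero, 0.0, log2fc)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "genotype": genotype,
            "timepoint": timepoint,
            "baseMean_ref": m_ref,
            "baseMean_mut": m_mut,
            "log2FC": log2fc,
            "wald_z": z,
            "p": np.clip(p, 0.0, 1.0),
        }
    ).set_index("gene_id")


def adjust_and_call(
    results: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Add BH-adjusted p-values and the regulation call to one contrast table.

    ``down`` requires log2FC < 0, fold change strictly > ``fc_threshold`` and
    padj <= ``alpha`` (inclusive); ``up`` is symmetric; everything else is
    ``ns``.
    """
    out = results.copy()
    p = out["p"].values
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out["padj"] = multipletests(p, method="fdr_bh")[1] if len(p) else p
    fc = 2.0 ** np.abs(out["log2FC"].values)
    sig = (fc > fc_threshold) & (out["padj"].values <= alpha)
    call = np.where(
        sig & (out["log2FC"].values < 0),
        "down",
        np.where(sig & (out["log2FC"].values > 0), "up", "ns"),
    )
    out["call"] = call
    return out


def run_contrasts(
    counts: CountMatrix,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pool_dispersions: bool = True,
) -> dict[tuple[str, str], pd.DataFrame]:
    """All seven mutant-vs-reference contrasts at every timepoint.

    With ``pool_dispersions`` (default) the gene dispersion is estimated once
    from all groups of the design and shared across contrasts.
    """
    factors = size_factors(counts)
    disp = disp_df = None
    if pool_dispersions:
        disp = estimate_dispersions(counts, factors)
        disp_df = sum(
            len(s) - 1 for s in counts.design.groups().values() if len(s) > 1
        )
    out = {}
    present = set(counts.design.table["genotype"])
    for tp in counts.design.timepoints:
        for g in MUTANT_ORDER:
            if g not in present:
                continue
            res = nb_test(counts, (g, tp), factors, disp, disp_df)
            out[(g, tp)] = adjust_and_call(res, fc_threshold, alpha)
    return out


def write_contrasts(results: dict, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (g, tp), df in results.items():
        df.to_csv(outdir / f"de_{g}_vs_ref_{tp}.tsv", sep="\t", float_format="%.6g")
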