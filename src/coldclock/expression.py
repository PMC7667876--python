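"""Differential expression and time-series summaries for fractionated counts.

The study design is genes x samples count tables where samples carry a
subcellular fraction (nucleus or cytoplasm), a temperature condition, a
timepoint and a replicate label. Because nuclear export stalls in the cold,
the informative contrasts are run separately per fraction and then compared
across fractions: a cold-response gene can rise in the nucleus while staying
flat in the cytoplasm ("nuclear-restricted" upregulation).

The differential test is a deliberately simple negative-binomial Wald test:
median-of-ratios size factors, per-gene method-of-moments dispersion with a
floor, and a t reference for the Wald statistic (small replicate numbers make
the plug-in dispersion noisy, so the normal reference is anticonservative).
It is a stand-in validated by its error-rate behaviour, not a reimplementation
of any particular DE tool.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

_LOG2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth normalization factors, one per sample.

    Each sample's factor is the median over genes of
    count / geometric-mean-count, using only genes expressed in every sample
    (geometric mean of zero counts is zero and would be uninformative).
    """
    mat = counts.to_numpy(dtype=float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[expressed]
    geo = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class DEResult:
    """Per-gene differential-expression summary (group B relative to A)."""

    table: pd.DataFrame  # columns: base_mean, log2fc, se, stat, p, padj

    def significant(self, alpha: float = 0.05) -> pd.Index:
        t = self.table
        return t.index[t["padj"] < alpha]


def nb_wald_de(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    dispersion_floor: float = 1e-8,
) -> DEResult:
    """Negative-binomial Wald test of group B vs group A, gene by gene.

    Counts are depth-normalized with shared size factors over the samples in
    the contrast. For each gene the log2 fold change of group means is tested
    with a Wald statistic whose standard error comes from the NB variance
    ``mu + alpha * mu**2`` with a per-gene method-of-moments dispersion
    (pooled within-group residual variance), floored at ``dispersion_floor``.
    P-values use a t reference with ``nA + nB - 2`` degrees of freedom and
    are BH-adjusted across the tested genes; genes with zero counts in every
    sample of the contrast are reported untested (NaN p/padj).
    """
    for g, name in ((group_a, "group_a"), (group_b, "group_b")):
        if len(g) < 2:
            raise ValueError(f"{name} needs >=2 replicates for a dispersion estimate")
    sub = counts[list(group_a) + list(group_b)]
    sf = size_factors(sub)
    norm = sub / sf
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]

    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # moderate ratio with half-unit pseudocount on the normalized scale
    eps = 0.5
    log2fc = np.log2(mu_b + eps) - np.log2(mu_a + eps)

    # pooled within-group residual variance -> NB dispersion alpha
    ss = ((a - mu_a[:, None]) ** 2).sum(axis=1) + ((b - mu_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = ss / df
    mu_pool = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu_pool) / mu_pool**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, dispersion_floor)

    var_mu_a = (mu_a + alpha * mu_a**2) / na
    var_mu_b = (mu_b + alpha * mu_b**2) / nb
    se = np.sqrt(var_mu_a / (mu_a + eps) ** 2 + var_mu_b / (mu_b + eps) ** 2) / _LOG2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(z), df)

    untested = (sub.to_numpy() == 0).all(axis=1)
    p = np.where(untested, np.nan, p)
    # zero fold change has zero SE only in the degenerate all-equal case
    p = np.where(np.isnan(p) & ~untested, 1.0, p)
    padj = bh_adjust(p)

    tab = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(untested, np.nan, log2fc),
            "se": np.where(untested, np.nan, se),
            "stat": np.where(untested, np.nan, z),
            "p": p,
            "padj": padj,
        },
        index=counts.index,
    )
    return DEResult(tab)


@dataclass
class StandardizedSeries:
    """Per-gene standardized trajectories plus gene-set boxplot summaries."""

    values: pd.DataFrame  # genes x timepoints, mean 0 / SD 1 per gene
    summary: pd.DataFrame  # per timepoint: median, q1, q3, iqr, notch_lo/hi
    dropped: list[str]


def standardize_series(
    counts: pd.DataFrame,
    timepoints: pd.Series,
    pseudocount: float = 1.0,
) -> StandardizedSeries:
    """Standardize each gene's trajectory across a time series to mean 0, SD 1.

    Counts are depth-normalized (median-of-ratios), log2(x + pseudocount)
    transformed as a variance-stabilizing step, averaged over replicates per
    timepoint, then z-scored per gene across timepoints (sample SD, ddof=1).
    Genes constant across all timepoints have no scale and are dropped with
    a record. The summary gives, per timepoint, the gene-set median, IQR and
    the notch median +- IQR/sqrt(n_genes).
    """
    tps = pd.Series(timepoints)
    if tps.nunique() < 2:
        raise ValueError("need at least two timepoints")
    sf = size_factors(counts)
    logn = np.log2(counts / sf + pseudocount)
    per_tp = logn.T.groupby(tps).mean().T  # genes x timepoints

    sd = per_tp.std(axis=1, ddof=1)
    # constant up to floating-point dust has no meaningful scale
    tol = 1e-10 * (per_tp.abs().mean(axis=1) + 1.0)
    constant = sd <= tol
    dropped = per_tp.index[constant].tolist()
    kept = per_tp.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)

    med = z.median(axis=0)
    q1, q3 = z.quantile(0.25, axis=0), z.quantile(0.75, axis=0)
    iqr = q3 - q1
    notch = iqr / np.sqrt(len(z))
    summary = pd.DataFrame(
        {
            "median": med,
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "notch_lo": med - notch,
            "notch_hi": med + notch,
        }
    )
    return StandardizedSeries(values=z, summary=summary, dropped=dropped)


@dataclass
class HalfLifeBinSummary:
    bins: pd.DataFrame  # per bin: mean_log2fc, mean_log2_halflife, n
    slope: float
    intercept: float
    r: float
    p: float
    n_genes: int
    n_excluded: int


def half_life_binning(
    log2fc: pd.Series,
    half_lives: pd.Series,
    n_bins: int = 10,
) -> HalfLifeBinSummary:
    """Relate mRNA half-life to cold-induced cytoplasmic fold change by binning.

    Genes missing either value are excluded, then genes whose log2 half-life
    lies more than 2 SD from the mean log2 half-life. Survivors are sorted by
    log2 fold change and split into ``n_bins`` equal-sized groups (first bins
    take the remainder); per-bin means of both quantities are regressed and
    correlated (Pearson, with the usual t-test on r over the bins).
    """
    df = pd.DataFrame({"lfc": log2fc, "hl": half_lives}).dropna()
    df = df[df["hl"] > 0]
    log_hl = np.log2(df["hl"])
    mu, sd = log_hl.mean(), log_hl.std(ddof=1)
    keep = (log_hl - mu).abs() <= 2 * sd
    n_excluded = int((~keep).sum())
    df = df[keep]
    if len(df) < n_bins:
        raise ValueError(f"need at least {n_bins} genes after exclusions, have {len(df)}")

    df = df.sort_values("lfc", kind="mergesort")
    groups = np.array_split(np.arange(len(df)), n_bins)
    rows = []
    for idx in groups:
        sel = df.iloc[idx]
        rows.append(
            {
                "mean_log2fc": sel["lfc"].mean(),
                "mean_log2_halflife": float(np.log2(sel["hl"]).mean()),
                "n": len(sel),
            }
        )
    bins = pd.DataFrame(rows)
    lr = stats.linregress(bins["mean_log2fc"], bins["mean_log2_halflife"])
    return HalfLifeBinSummary(
        bins=bins,
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r=float(lr.rvalue),
        p=float(lr.pvalue),
        n_genes=len(df),
        n_excluded=n_excluded,
    )


def nk_scatter_classes(
    de_nuc: DEResult,
    de_cyt: DEResult,
    base_mean_min: float = 30.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Classify genes by nuclear-vs-cytoplasmic significance pattern.

    Genes with base mean below ``base_mean_min`` in either compartment (or
    untested in either) are excluded. Each survivor is labeled
    'nucleus_only', 'cytoplasm_only', 'both' or 'neither' at padj < alpha,
    and the Pearson correlation between compartment log2 fold changes is
    returned for the density-scatter comparison.
    """
    n, c = de_nuc.table, de_cyt.table
    common = n.index.intersection(c.index)
    n, c = n.loc[common], c.loc[common]
    ok = (
        (n["base_mean"] >= base_mean_min)
        & (c["base_mean"] >= base_mean_min)
        & n["padj"].notna()
        & c["padj"].notna()
    )
    n, c = n[ok], c[ok]
    sig_n = n["padj"] < alpha
    sig_c = c["padj"] < alpha
    label = np.where(
        sig_n & sig_c, "both",
        np.where(sig_n, "nucleus_only", np.where(sig_c, "cytoplasm_only", "neither")),
    )
    out = pd.DataFrame(
        {
            "log2fc_nuc": n["log2fc"],
            "log2fc_cyt": c["log2fc"],
            "padj_nuc": n["padj"],
            "padj_cyt": c["padj"],
            "class": label,
        }
    )
    if len(out) >= 2:
        r, rp = stats.pearsonr(out["log2fc_nuc"], out["log2fc_cyt"])
    else:
        r, rp = np.nan, np.nan
    summary = {
        "n_genes": len(out),
        "pearson_r": float(r),
        "pearson_p": float(rp),
        "counts": out["class"].value_counts().to_dict(),
    }
    return out, summary
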