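"""Per-subset negative-binomial Wald differential expression.

The stage mirrors the standard NB GLM workflow for flight-vs-ground
contrasts: spike-in/zero-count gene filtering, median-of-ratios size
factors, method-of-moments dispersion estimation with an α(μ) = a0/μ + a1
trend and shrinkage toward it, per-gene IRLS fits of a log-link NB GLM
(intercept + condition) with the dispersion held fixed, a two-sided Wald
test on the condition coefficient, and Benjamini–Hochberg adjustment.
No outlier-based p-value removal and no mean-based independent filtering
are applied: every gene that enters the test stage is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._utils import ValidationError
from .io import ERCC_PREFIX, validate_counts, validate_samples

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
_MAX_BETA = 30.0  # natural-log scale; caps divergent fits (all-zero groups)


@dataclass
class DispersionEstimates:
    raw: pd.Series        # per-gene method-of-moments dispersion
    trend_a0: float
    trend_a1: float
    final: pd.Series      # shrunken dispersion used by the Wald test


@dataclass
class SubsetResult:
    """Per-subset differential-expression table (flight vs ground)."""

    subset_id: str
    mission: str
    table: pd.DataFrame  # gene, baseMean, log2FoldChange, lfcSE, stat, pvalue, padj

    def significant(self, fdr_threshold: float = 0.1) -> set:
        padj = self.table["padj"]
        return set(self.table.loc[padj.notna() & (padj <= fdr_threshold),
                                  "gene"])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering

def filter_genes(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Remove spike-in genes and genes detected in too few samples.

    Drops genes whose id starts with ``ERCC-`` and genes whose number of
    samples with nonzero counts is below the size of the smallest condition
    group in ``samples`` (so a gene expressed in every sample of one
    condition always survives).
    """
    counts = validate_counts(counts)
    samples = validate_samples(samples, counts)
    counts = counts[samples["sample_id"].to_numpy()]
    keep = ~counts.index.str.startswith(ERCC_PREFIX)
    n_ercc = int((~keep).sum())
    min_group = int(samples.groupby(["subset_id", "condition"]).size().min())
    nonzero = (counts.to_numpy() > 0).sum(axis=1)
    keep &= nonzero >= min_group
    out = counts.loc[keep]
    logger.info("filter_genes: %d ERCC removed, %d low-detection removed, "
                "%d retained", n_ercc, len(counts) - n_ercc - len(out),
                len(out))
    if len(out) == 0:
        raise ValidationError("filtering removed every gene")
    return out


# ---------------------------------------------------------------------------
# normalization

def estimate_size_factors(counts: pd.DataFrame,
                          pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean across samples, computed
    over genes with nonzero counts in every sample. If no such gene exists
    an error is raised advising ``pseudo_reference=True``, which instead
    takes geometric means over the positive counts of each gene.
    """
    counts = validate_counts(counts)
    x = counts.to_numpy().astype(float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any() and not pseudo_reference:
        raise ValidationError(
            "no gene has nonzero counts in every sample; rerun with "
            "pseudo_reference=True to use positive-count geometric means"
        )
    with np.errstate(divide="ignore"):
        logx = np.where(x > 0, np.log(x), np.nan)
    # median over reference genes of the per-sample ratio; the
    # pseudo-reference fallback excludes zero counts from the median
    if pseudo_reference:
        usable = (x > 0).any(axis=1)
        ref = np.exp(np.nanmean(logx[usable], axis=1))
        ratios = np.where(x[usable] > 0, x[usable] / ref[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        ref = np.exp(np.mean(logx[all_positive], axis=1))
        factors = np.median(x[all_positive] / ref[:, None], axis=0)
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise ValidationError("degenerate size factors; check the counts")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion

def estimate_dispersions(counts: pd.DataFrame, factors: pd.Series,
                         samples: pd.DataFrame,
                         shrinkage_weight: float = 0.5) -> DispersionEstimates:
    """Method-of-moments dispersions with a fitted α(μ) = a0/μ + a1 trend.

    Raw per-gene dispersions are estimated from normalized counts pooled
    within condition groups (so planted condition effects do not inflate
    them), a non-negative least-squares trend is fitted across genes, and
    the final dispersion is the weighted mean
    ``w·raw + (1−w)·trend`` floored at 1e-8.
    """
    counts = validate_counts(counts)
    samples = validate_samples(samples, counts)
    if not (0.0 <= shrinkage_weight <= 1.0):
        raise ValidationError("shrinkage_weight must be in [0, 1]")
    sf = factors.loc[counts.columns].to_numpy()
    x = counts.to_numpy() / sf[None, :]

    groups = samples.set_index("sample_id").loc[counts.columns]
    keys = list(zip(groups["subset_id"], groups["condition"]))
    group_ids = {}
    labels = np.array([group_ids.setdefault(k, len(group_ids)) for k in keys])
    sizes = np.bincount(labels)
    if sizes.min() < 2:
        raise ValidationError(
            "dispersion estimation needs >=2 replicates per condition group"
        )

    # pooled within-group variance and weighted mean
    n, k = x.shape[1], len(group_ids)
    ss = np.zeros(x.shape[0])
    for gid in range(k):
        cols = labels == gid
        gm = x[:, cols].mean(axis=1, keepdims=True)
        ss += ((x[:, cols] - gm) ** 2).sum(axis=1)
    v_pool = ss / (n - k)
    m = x.mean(axis=1)
    xi = float(np.mean(1.0 / sf))  # E[1/sf]: Var(y/sf) = μ/sf + αμ²
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (v_pool - m * xi) / m**2
    mom = np.where(np.isfinite(mom), mom, 0.0)

    # trend fit on the signed moment estimates (nnls keeps a0, a1 >= 0)
    ok = m > 0
    A = np.column_stack([1.0 / m[ok], np.ones(ok.sum())])
    b = mom[ok]
    a, _ = scipy.optimize.nnls(A, b)
    resid = b - A @ a
    mad = np.median(np.abs(resid - np.median(resid))) + 1e-12
    inlier = np.abs(resid) <= 5 * 1.4826 * mad
    if inlier.sum() >= 10 and inlier.sum() < ok.sum():
        a, _ = scipy.optimize.nnls(A[inlier], b[inlier])
    a0, a1 = float(a[0]), float(a[1])

    raw = np.maximum(mom, DISPERSION_FLOOR)
    with np.errstate(divide="ignore"):
        trend = np.where(m > 0, a0 / np.maximum(m, 1e-12) + a1, a1)
    final = np.maximum(shrinkage_weight * raw + (1 - shrinkage_weight) * trend,
                       DISPERSION_FLOOR)
    idx = counts.index
    return DispersionEstimates(raw=pd.Series(raw, index=idx, name="raw"),
                               trend_a0=a0, trend_a1=a1,
                               final=pd.Series(final, index=idx, name="final"))


# ---------------------------------------------------------------------------
# Wald test

def _irls_nb(y: np.ndarray, flight: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, max_iter: int = 50, tol: float = 1e-10
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-gene NB GLMs with design (intercept, flight).

    ``y`` is genes×samples, ``offset`` the per-sample log size factor,
    ``alpha`` the fixed per-gene dispersion. Returns (beta0, beta1, se1,
    converged); beta on the natural-log scale.
    """
    g = y.shape[0]
    fl = flight.astype(float)
    norm = y / np.exp(offset)[None, :]
    mean_all = norm.mean(axis=1)
    mean_fl = norm[:, flight].mean(axis=1)
    mean_gr = norm[:, ~flight].mean(axis=1)
    eps = 1e-8
    beta0 = np.log(np.maximum(mean_gr, eps))
    beta1 = np.log(np.maximum(mean_fl, eps)) - beta0
    beta0 = np.clip(np.where(mean_all > 0, beta0, -_MAX_BETA),
                    -_MAX_BETA, _MAX_BETA)
    beta1 = np.clip(beta1, -_MAX_BETA, _MAX_BETA)

    active = np.ones(g, dtype=bool)
    converged = np.zeros(g, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = (beta0[active, None] + beta1[active, None] * fl[None, :]
               + offset[None, :])
        mu = np.exp(np.clip(eta, -300, 300))
        denom = 1.0 + alpha[active, None] * mu
        w = mu / denom
        u = (y[active] - mu) / denom
        sw = w.sum(axis=1)
        swf = (w * fl).sum(axis=1)
        r0 = u.sum(axis=1)
        r1 = (u * fl).sum(axis=1)
        det = swf * (sw - swf)
        det = np.where(det > 1e-300, det, np.nan)
        d1 = (-swf * r0 + sw * r1) / det
        d0 = (r0 - swf * d1) / sw
        d0 = np.where(np.isfinite(d0), d0, 0.0)
        d1 = np.where(np.isfinite(d1), d1, 0.0)
        step = np.clip(np.stack([d0, d1]), -5, 5)
        beta0[active] = np.clip(beta0[active] + step[0], -_MAX_BETA, _MAX_BETA)
        beta1[active] = np.clip(beta1[active] + step[1], -_MAX_BETA, _MAX_BETA)
        done = np.max(np.abs(step), axis=0) < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False

    # observed information at the final estimate
    eta = beta0[:, None] + beta1[:, None] * fl[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -300, 300))
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swf = (w * fl).sum(axis=1)
    det = swf * (sw - swf)
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(sw / det)
    # fits pinned at the clip bound are divergent (a group of all zeros):
    # report them with their capped estimate rather than dropping the gene
    at_bound = np.abs(beta1) >= _MAX_BETA - 1e-6
    converged |= at_bound
    return beta0, beta1, se1, converged


def wald_test(counts: pd.DataFrame, factors: pd.Series,
              dispersions: DispersionEstimates, samples: pd.DataFrame,
              subset_id: str) -> SubsetResult:
    """Two-sided Wald test of flight vs ground for one data subset.

    Fits, per gene, an NB log-link GLM (intercept + condition) by IRLS with
    the final dispersion fixed; log2FC is the condition coefficient divided
    by ln 2, its SE comes from the observed information, and the p-value is
    the two-sided normal tail of t = log2FC/SE. Every input gene appears in
    the output; IRLS failures are flagged with missing p-values.
    """
    counts = validate_counts(counts)
    samples = validate_samples(samples, counts)
    sub = samples[samples["subset_id"] == subset_id]
    if sub.empty:
        raise ValidationError(f"unknown subset {subset_id!r}")
    mission = sub["mission"].iloc[0]
    cols = sub["sample_id"].to_numpy()
    y = counts[cols].to_numpy().astype(float)
    flight = (sub["condition"] == "flight").to_numpy()
    if flight.all() or not flight.any():
        raise ValidationError(f"subset {subset_id!r} lacks both conditions")
    sf = factors.loc[cols].to_numpy()
    alpha = dispersions.final.loc[counts.index].to_numpy()

    beta0, beta1, se1, converged = _irls_nb(y, flight, np.log(sf), alpha)
    ln2 = np.log(2.0)
    lfc = beta1 / ln2
    se = se1 / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / se
    pval = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    bad = ~converged | ~np.isfinite(stat)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("wald_test[%s]: %d gene fits failed to converge; "
                       "p set missing", subset_id, n_bad)
    pval = np.where(bad, np.nan, pval)
    base_mean = (y / sf[None, :]).mean(axis=1)
    table = pd.DataFrame({
        "gene": counts.index,
        "baseMean": base_mean,
        "log2FoldChange": lfc,
        "lfcSE": se,
        "stat": stat,
        "pvalue": pval,
        "padj": adjust_bh(pval),
    }).reset_index(drop=True)
    return SubsetResult(subset_id=subset_id, mission=mission, table=table)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; missing values propagate and
    are excluded from the ranking denominator."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        bad = p[ok][(p[ok] < 0) | (p[ok] > 1)][0]
        raise ValidationError(f"p-value {bad} outside [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# convenience driver

def run_subset_dge(counts: pd.DataFrame, samples: pd.DataFrame,
                   subset_id: str, shrinkage_weight: float = 0.5,
                   pseudo_reference: bool = False) -> SubsetResult:
    """Full per-subset pipeline: restrict to the subset's samples, filter,
    normalize, estimate dispersions, and Wald-test flight vs ground."""
    sub = samples[samples["subset_id"] == subset_id].reset_index(drop=True)
    if sub.empty:
        raise ValidationError(f"unknown subset {subset_id!r}")
    counts_sub = counts[sub["sample_id"].to_numpy()]
    filtered = filter_genes(counts_sub, sub)
    factors = estimate_size_factors(filtered, pseudo_reference)
    disp = estimate_dispersions(filtered, factors, sub, shrinkage_weight)
    return wald_test(filtered, factors, disp, sub, subset_id)
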