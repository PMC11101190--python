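"""Negative-binomial Wald tests for differential transcription and a
transcription-conditioned differential-translation test.

Model
-----
Counts for feature *f* in sample *j* are NB2: ``Var = mu + alpha * mu**2``.
The mean follows a log-link GLM ``log mu_fj = log s_j + x_j' beta_f`` with
``s_j`` a median-of-ratios size factor.  For the two-group transcription
test the design is an intercept plus a group indicator (evolved vs
ancestor); the Wald statistic is ``beta1 / SE(beta1)`` with a two-sided
normal p-value, and p-values are Benjamini-Hochberg adjusted across the
tested family.  For differential translation, RNA-seq and Ribo-seq counts
are stacked and the design adds an assay indicator and an assay x group
interaction; the BH-adjusted interaction p-value is the q-value
(significance threshold q < 0.01 by default).

Dispersions are estimated per feature by method of moments on normalized
counts and shrunk toward a fitted mean-dispersion trend.  No posterior
effect-size shrinkage or outlier handling is applied; log2 fold changes are
the raw GLM coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


# ----------------------------------------------------------- normalization


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    Falls back to column-sum ratios when no feature has all-positive
    counts.  An all-zero matrix is an error.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.sum() == 0:
        raise ValueError("cannot estimate size factors from an all-zero matrix")
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        loga = np.log(arr[allpos])
        ref = loga.mean(axis=1, keepdims=True)  # log geometric-mean pseudo-reference
        logsf = np.median(loga - ref, axis=0)
    else:
        logsf = np.log(arr.sum(axis=0))
    logsf = logsf - logsf.mean()  # geometric mean 1
    return pd.Series(np.exp(logsf), index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series,
    trend_weight: float = 0.9,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-feature NB2 dispersion: method of moments plus trend shrinkage.

    The raw estimate is ``(within-group variance - mean) / mean**2`` on
    size-factor-normalized counts.  A hyperbolic mean-dispersion trend
    ``a0 + a1/mean`` is fitted across features and the final value is a
    weighted average pulling each raw estimate ``trend_weight`` of the way
    toward the trend.  Deterministic; floored at ``floor``.
    """
    q = counts.to_numpy(dtype=float) / size_factors.reindex(counts.columns).to_numpy()
    groups = pd.Series(groups).reindex(counts.columns)
    labels = groups.unique()
    ss = np.zeros(q.shape[0])
    m1w = np.zeros(q.shape[0])  # df-weighted group means (first moment)
    m2w = np.zeros(q.shape[0])  # df-weighted squared group means
    df = 0
    mean = q.mean(axis=1)
    for g in labels:
        cols = (groups == g).to_numpy()
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        sub = q[:, cols]
        gm = sub.mean(axis=1)
        ss += ((sub - gm[:, None]) ** 2).sum(axis=1)
        m1w += (n_g - 1) * gm
        m2w += (n_g - 1) * gm**2
        df += n_g - 1
    if df < 1:
        raise ValueError("need >= 2 replicates in at least one group")
    var = ss / df
    # within-group moments: E[var] = mean(mu_g) + alpha * mean(mu_g^2), so
    # the estimator stays unbiased when group means differ (true signal)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_signed = (var - m1w / df) / (m2w / df)
    raw_signed = np.where(np.isfinite(raw_signed), raw_signed, 0.0)
    raw = np.maximum(raw_signed, floor)

    # hyperbolic trend alpha(mean) = a0 + a1/mean; fitted on the *unfloored*
    # moment estimates so that Poisson-like data pulls the trend to zero
    # instead of inheriting the flooring bias
    use = mean > 0
    if use.sum() >= 10:
        X = np.column_stack([np.ones(int(use.sum())), 1.0 / mean[use]])
        coef, *_ = np.linalg.lstsq(X, raw_signed[use], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
        trend = a0 + np.divide(a1, mean, out=np.full_like(mean, np.inf), where=mean > 0)
    else:
        trend = np.full_like(mean, np.median(raw))
    trend = np.clip(trend, floor, 10.0)
    alpha = (1.0 - trend_weight) * raw + trend_weight * trend
    return pd.Series(np.maximum(alpha, floor), index=counts.index, name="dispersion")


# -------------------------------------------------------------- NB2 IRLS


def _nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for NB2 log-link GLMs, one model per feature row.

    Parameters: ``y`` (features x samples), ``X`` (samples x p design),
    ``log_sf`` (samples,) offsets, ``alpha`` (features,) dispersions.
    Returns ``(beta, se, converged)`` with shapes (F, p), (F, p), (F,).
    Convergence: relative deviance change < ``tol`` or ``max_iter``
    iterations.
    """
    F, S = y.shape
    p = X.shape[1]
    offset = np.broadcast_to(log_sf, (F, S))
    alpha = np.maximum(alpha, 0.0)[:, None]

    mu = np.maximum(y + 0.5, 1e-8)
    eta = np.log(mu)
    dev_old = np.full(F, np.inf)
    converged = np.zeros(F, dtype=bool)
    beta = np.zeros((F, p))
    eye = np.eye(p) * 1e-10

    def deviance(mu: np.ndarray) -> np.ndarray:
        a = np.maximum(alpha, 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
        return 2.0 * (t1 - t2).sum(axis=1)

    XtWX = None
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)  # (F, S) working weights
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("si,fs,sj->fij", X, w, X) + eye
        XtWz = np.einsum("si,fs->fi", X, w * z)
        beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        eta = np.clip(offset + beta @ X.T, -30.0, 30.0)
        mu = np.maximum(np.exp(eta), 1e-10)
        dev = deviance(mu)
        converged = np.abs(dev - dev_old) < tol * (np.abs(dev) + 0.1)
        if converged.all():
            break
        dev_old = dev

    w = mu / (1.0 + alpha * mu)
    XtWX = np.einsum("si,fs,sj->fij", X, w, X) + eye
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se, converged


# ------------------------------------------------------------- adjustment


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------ Wald models


@dataclass
class DEResults:
    """Results of a two-group NB Wald differential-expression fit."""

    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series
    alpha: float = 0.05
    coef_name: str = "group"

    @property
    def significant(self) -> pd.Index:
        t = self.table
        return t.index[(t["padj"] < self.alpha) & (t["status"] == "tested")]

    def summary(self) -> str:
        t = self.table
        tested = int((t["status"] == "tested").sum())
        lines = [
            "NB Wald differential expression",
            f"  features: {len(t)} ({tested} tested, {len(t) - tested} low-count-skipped)",
            f"  significant at padj < {self.alpha:g}: {len(self.significant)}",
            f"  size factors: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.size_factors.items()),
        ]
        return "\n".join(lines)


class NBWaldDE:
    """Two-group NB GLM Wald test (evolved vs ancestor), per feature.

    Parameters
    ----------
    counts : CountMatrix or DataFrame
        Features x samples integer counts.
    groups : mapping of sample -> label
        Exactly two labels; ``reference`` is the control (ancestor) level.
    reference : str
        The control group label.
    min_count : int
        Features with total count below this are skipped, not tested.
    """

    def __init__(
        self,
        counts,
        groups,
        reference: str = "ancestor",
        min_count: int = 2,
        alpha: float = 0.05,
        trend_weight: float = 0.9,
        pseudocount: float = 0.25,
    ) -> None:
        self.counts = counts.counts if hasattr(counts, "counts") else counts
        self.pseudocount = pseudocount
        self.groups = pd.Series(groups).reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        labels = [g for g in self.groups.unique()]
        if len(labels) != 2 or reference not in labels:
            raise ValueError(f"need exactly two groups including reference {reference!r}")
        self.reference = reference
        self.treatment = next(g for g in labels if g != reference)
        vc = self.groups.value_counts()
        if (vc < 2).any():
            raise ValueError("both groups need >= 2 replicates")
        self.min_count = min_count
        self.alpha = alpha
        self.trend_weight = trend_weight

    def fit(self) -> DEResults:
        counts = self.counts
        sf = estimate_size_factors(counts)
        disp = estimate_dispersion(counts, sf, self.groups, trend_weight=self.trend_weight)

        y = counts.to_numpy(dtype=float)
        keep = y.sum(axis=1) >= self.min_count
        X = np.column_stack(
            [np.ones(len(self.groups)), (self.groups == self.treatment).to_numpy(float)]
        )
        log_sf = np.log(sf.to_numpy())

        norm = y / sf.to_numpy()
        base_mean = norm.mean(axis=1)

        n = len(counts)
        lfc = np.full(n, np.nan)
        se_l = np.full(n, np.nan)
        stat = np.full(n, np.nan)
        pval = np.full(n, np.nan)
        status = np.where(keep, "tested", "low-count-skipped").astype(object)

        if keep.any():
            # a small pseudocount keeps the GLM finite when one group is
            # all-zero (the MLE is degenerate there); negligible at the
            # counts where p-values matter
            beta, se, conv = _nb_irls(
                y[keep] + self.pseudocount, X, log_sf, disp.to_numpy()[keep]
            )
            lfc[keep] = beta[:, 1] / LOG2
            se_l[keep] = se[:, 1] / LOG2
            with np.errstate(divide="ignore", invalid="ignore"):
                z = beta[:, 1] / se[:, 1]
            stat[keep] = z
            pk = 2.0 * stats.norm.sf(np.abs(z))
            pk[~conv] = np.nan
            pval[keep] = pk
            idx = np.flatnonzero(keep)
            status[idx[~conv]] = "not-converged"

        padj = np.full(n, np.nan)
        tested = ~np.isnan(pval)
        if tested.any():
            padj[tested] = bh_adjust(pval[tested])

        table = pd.DataFrame(
            {
                "baseMean": base_mean,
                "log2FoldChange": lfc,
                "lfcSE": se_l,
                "stat": stat,
                "pvalue": pval,
                "padj": padj,
                "status": status,
            },
            index=counts.index,
        )
        return DEResults(
            table=table,
            size_factors=sf,
            dispersions=disp,
            alpha=self.alpha,
            coef_name=f"{self.treatment}_vs_{self.reference}",
        )


@dataclass
class DTResults:
    """Results of the assay x group interaction (differential translation) fit."""

    table: pd.DataFrame
    q_threshold: float = 0.01

    @property
    def significant(self) -> pd.Index:
        t = self.table
        return t.index[(t["qvalue"] < self.q_threshold) & (t["status"] == "tested")]

    def summary(self) -> str:
        t = self.table
        return (
            "NB interaction test for differential translation\n"
            f"  features: {len(t)} ({int((t['status'] == 'tested').sum())} tested)\n"
            f"  significant at q < {self.q_threshold:g}: {len(self.significant)}"
        )


class DifferentialTranslation:
    """Joint NB GLM on stacked RNA + Ribo counts.

    Covariates: intercept, assay (Ribo vs RNA), group (evolved vs
    ancestor), and the assay x group interaction.  The interaction captures
    translation changes beyond what the transcriptional change predicts;
    its BH-adjusted Wald p-value is the q-value.
    """

    def __init__(
        self,
        rna_counts,
        ribo_counts,
        groups,
        reference: str = "ancestor",
        min_count: int = 2,
        q_threshold: float = 0.01,
        trend_weight: float = 0.9,
        pseudocount: float = 0.25,
    ) -> None:
        self.pseudocount = pseudocount
        rna = rna_counts.counts if hasattr(rna_counts, "counts") else rna_counts
        ribo = ribo_counts.counts if hasattr(ribo_counts, "counts") else ribo_counts
        if not rna.index.equals(ribo.index):
            raise ValueError("RNA and Ribo matrices must share the same features")
        self.rna = rna
        self.ribo = ribo
        self.groups = pd.Series(groups)
        self.reference = reference
        self.min_count = min_count
        self.q_threshold = q_threshold
        self.trend_weight = trend_weight

    def fit(self) -> DTResults:
        rna, ribo = self.rna, self.ribo
        g_rna = self.groups.reindex(rna.columns)
        g_ribo = self.groups.reindex(ribo.columns)
        if g_rna.isna().any() or g_ribo.isna().any():
            raise ValueError("every RNA and Ribo sample needs a group label")
        stacked = pd.concat(
            [rna.add_suffix(":rna"), ribo.add_suffix(":ribo")], axis=1
        )
        assay = np.r_[np.zeros(rna.shape[1]), np.ones(ribo.shape[1])]
        treat = np.r_[
            (g_rna != self.reference).to_numpy(float),
            (g_ribo != self.reference).to_numpy(float),
        ]
        X = np.column_stack([np.ones_like(assay), assay, treat, assay * treat])

        sf = estimate_size_factors(stacked)
        combo = pd.Series(
            [f"{a:.0f}:{t:.0f}" for a, t in zip(assay, treat)], index=stacked.columns
        )
        disp = estimate_dispersion(stacked, sf, combo, trend_weight=self.trend_weight)

        y = stacked.to_numpy(dtype=float)
        keep = y.sum(axis=1) >= self.min_count
        n = len(stacked)
        lfc = np.full(n, np.nan)
        pval = np.full(n, np.nan)
        status = np.where(keep, "tested", "low-count-skipped").astype(object)

        if keep.any():
            beta, se, conv = _nb_irls(
                y[keep] + self.pseudocount, X, np.log(sf.to_numpy()), disp.to_numpy()[keep]
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                z = beta[:, 3] / se[:, 3]
            lfc[keep] = beta[:, 3] / LOG2
            pk = 2.0 * stats.norm.sf(np.abs(z))
            pk[~conv] = np.nan
            pval[keep] = pk
            idx = np.flatnonzero(keep)
            status[idx[~conv]] = "not-converged"

        qval = np.full(n, np.nan)
        tested = ~np.isnan(pval)
        if tested.any():
            qval[tested] = bh_adjust(pval[tested])
        table = pd.DataFrame(
            {
                "log2FC_interaction": lfc,
                "pvalue": pval,
                "qvalue": qval,
                "status": status,
            },
            index=stacked.index,
        )
        return DTResults(table=table, q_threshold=self.q_threshold)


def nb_wald_test(counts, groups, reference: str = "ancestor", **kwargs) -> DEResults:
    """Functional wrapper around :class:`NBWaldDE`."""
    return NBWaldDE(counts, groups, reference=reference, **kwargs).fit()


def differential_translation(
    rna_counts, ribo_counts, groups, reference: str = "ancestor", **kwargs
) -> DTResults:
    """Functional wrapper around :class:`DifferentialTranslation`."""
    return DifferentialTranslation(
        rna_counts, ribo_counts, groups, reference=reference, **kwargs
    ).fit()
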