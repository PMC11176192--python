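"""Differential expression between metastasis and primary-tumor samples.

mRNA counts are normalized per sample with the upper-quartile (UQ) method —
the size factor is the 75th percentile of the sample's nonzero gene counts —
and transformed to ``Y = log2((K + 1) / s)``.  Each gene is then tested with
an ordinary least-squares regression of Y on tissue status adjusted for
batch, sex, and age; the tissue coefficient is the reported log2 fold change
and the two-sided t-test p-values are adjusted with the Benjamini-Hochberg
step-up procedure.  No dispersion moderation is applied: at the sample sizes
targeted here ordinary per-gene OLS is adequate.  A conditional variant adds
one focal gene's normalized expression as a covariate, which removes the
apparent tissue effect of genes whose association is mediated by the focal
locus.  For miRNA matrices the DESeq-style median-of-ratios size factors are
used instead and low-abundance rows (mean count < 1) are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "uq_size_factors",
    "log_normalize",
    "bh_adjust",
    "DifferentialExpressionModel",
    "de_linear_model",
    "conditional_de",
    "mor_size_factors_and_filter",
]


def uq_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Upper-quartile size factor per sample.

    75th percentile (linear interpolation between order statistics) of
    the sample's nonzero counts.  All-zero samples are an error.
    """
    factors = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        nz = col[col > 0]
        if len(nz) == 0:
            raise ValueError(f"sample {sample!r} has no nonzero counts")
        factors[sample] = float(np.percentile(nz, 75))
    return pd.Series(factors, name="size_factor")


def log_normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """``Y[g, i] = log2((K[g, i] + 1) / s[i])``, elementwise and exact.

    The division by the raw size factor (no rescaling to the cohort mean)
    shifts each sample's profile by a constant that is absorbed by the
    regression intercept downstream.
    """
    s = size_factors.reindex(counts.columns)
    if s.isna().any() or (s <= 0).any():
        bad = s.index[s.isna() | (s <= 0)].tolist()
        raise ValueError(f"non-positive or missing size factors for samples {bad}")
    return np.log2((counts + 1.0).div(s, axis=1))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``p_adj[(i)] = min_{j >= i} p[(j)] * m / j`` over the sorted vector,
    capped at 1; NaNs propagate (they do not count toward ``m``).
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _design_matrix(meta: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Intercept + tissue indicator + dummy/numeric covariate columns."""
    X = pd.DataFrame(index=meta.index)
    X["const"] = 1.0
    X["tissue_met"] = (meta["tissue"] == "met").astype(float)
    for cov in covariates:
        col = meta[cov]
        if col.dtype.kind in "fiu":
            X[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    return X


@dataclass
class DEResults:
    """Per-gene differential-expression table plus fit metadata."""

    table: pd.DataFrame  # log2fc, se, p, p_adj, flag
    design_columns: list[str]
    nobs: int

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("p_adj").head(n)


class DifferentialExpressionModel:
    """Per-gene OLS of normalized expression on tissue status.

    Parameters
    ----------
    Y : DataFrame, genes x samples
        Log-normalized expression.
    meta : DataFrame indexed by sample id
        Must carry ``tissue`` in {"met", "pt"} plus the covariate columns.
    covariates : names of adjustment columns (categorical ones are dummy
        coded).  Default batch + sex + age.
    """

    def __init__(
        self,
        Y: pd.DataFrame,
        meta: pd.DataFrame,
        covariates: tuple[str, ...] = ("batch", "sex", "age"),
    ):
        missing = set(Y.columns) - set(meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        self.Y = Y
        self.meta = meta.loc[Y.columns]
        self.X = _design_matrix(self.meta, covariates)
        rank = np.linalg.matrix_rank(self.X.to_numpy())
        if rank < self.X.shape[1]:
            # typically tissue collinear with batch
            raise ValueError(
                "confounded design: columns "
                f"{list(self.X.columns)} are rank-deficient (rank {rank})"
            )

    def fit(self, extra_covariate: pd.Series | None = None) -> DEResults:
        """Vectorized OLS across genes; two-sided t-test on the tissue term.

        Genes with zero variance across samples are flagged
        ``degenerate`` and excluded from testing (NaN p).
        """
        X = self.X
        if extra_covariate is not None:
            X = X.copy()
            X["focal_expression"] = extra_covariate.reindex(X.index).astype(float)
        Xm = X.to_numpy()
        n, p = Xm.shape
        Ym = self.Y.to_numpy(dtype=float)

        XtX_inv = np.linalg.inv(Xm.T @ Xm)
        H = XtX_inv @ Xm.T  # p x n
        B = Ym @ H.T  # genes x p
        resid = Ym - B @ Xm.T
        dof = n - p
        sigma2 = (resid ** 2).sum(axis=1) / dof
        j = list(X.columns).index("tissue_met")
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        beta = B[:, j]

        degenerate = self.Y.var(axis=1).to_numpy() < 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, beta / se, np.nan)
        pval = 2.0 * stats.t.sf(np.abs(tval), dof)
        pval[degenerate] = np.nan
        beta = np.where(degenerate, np.nan, beta)

        table = pd.DataFrame(
            {
                "log2fc": beta,
                "se": np.where(degenerate, np.nan, se),
                "p": pval,
                "p_adj": bh_adjust(pval),
                "flag": np.where(degenerate, "degenerate", ""),
            },
            index=self.Y.index,
        )
        return DEResults(table=table, design_columns=list(X.columns), nobs=n)


def de_linear_model(
    Y: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = ("batch", "sex", "age"),
) -> DEResults:
    """One-call per-gene DE: build the model and fit it."""
    return DifferentialExpressionModel(Y, meta, covariates).fit()


def conditional_de(
    Y: pd.DataFrame,
    meta: pd.DataFrame,
    focal_gene: str,
    covariates: tuple[str, ...] = ("batch", "sex", "age"),
) -> DEResults:
    """DE adjusted for one focal gene's expression.

    The focal gene's normalized expression row enters the design as a
    covariate and the gene itself is excluded from the tested set.
    """
    if focal_gene not in Y.index:
        raise ValueError(f"focal gene {focal_gene!r} not in expression matrix")
    focal = Y.loc[focal_gene]
    rest = Y.drop(index=focal_gene)
    model = DifferentialExpressionModel(rest, meta, covariates)
    return model.fit(extra_covariate=focal)


def mor_size_factors_and_filter(
    counts: pd.DataFrame, min_mean: float = 1.0, filter_on: str = "normalized"
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors plus a low-abundance row filter.

    The reference profile is the per-gene geometric mean over genes
    nonzero in every sample; each sample's factor is the median ratio of
    its counts to the reference.  Rows whose mean normalized (or raw,
    with ``filter_on='raw'``) count falls below ``min_mean`` are removed.
    Returns ``(size_factors, filtered_counts)``.
    """
    if counts.shape[1] < 2:
        raise ValueError("median-of-ratios normalization needs >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene is nonzero in every sample; cannot form reference")
    ref = np.exp(np.mean(np.log(mat[all_nonzero]), axis=1))
    ratios = mat[all_nonzero] / ref[:, None]
    factors = pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")

    normalized = counts.div(factors, axis=1)
    basis = normalized if filter_on == "normalized" else counts
    keep = basis.mean(axis=1) >= min_mean
    return factors, counts[keep]
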