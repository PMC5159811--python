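"""Per-series gene filtering: minimum sample count, one-way ANOVA across
replicate groups (p < 0.01, with a top-3000-by-p fallback) and the
abundance filter (present in at least one sample AND above the TE
90th-percentile abundance floor in at least one sample)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DesignError
from .types import ExpressionSeries, FilterReport


def check_min_samples(series: ExpressionSeries, min_samples: int = 20) -> bool:
    """True iff the series has at least ``min_samples`` samples."""
    return series.n_samples >= min_samples


def anova_p_values(matrix: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Vectorized one-way fixed-effects F-test p-value per gene row.

    ``groups`` maps each column of ``matrix`` to a replicate-group label.
    Genes with zero total variance get p = 1 (constant rows carry no
    between-group signal); genes with zero within-group variance but
    non-zero between-group variance get p = 0.
    """
    labels = groups.loc[matrix.columns]
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise DesignError("ANOVA requires at least 2 replicate groups")
    sizes = labels.value_counts()
    small = [g for g in group_names if sizes[g] < 2]
    if small:
        raise DesignError(
            f"replicate group {small[0]!r} has fewer than 2 samples")

    x = matrix.to_numpy(dtype=float)
    n = x.shape[1]
    k = len(group_names)
    grand = x.mean(axis=1, keepdims=True)
    sst = ((x - grand) ** 2).sum(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for g in group_names:
        cols = (labels == g).to_numpy()
        xg = x[:, cols]
        mg = xg.mean(axis=1, keepdims=True)
        ssb += cols.sum() * (mg[:, 0] - grand[:, 0]) ** 2
        ssw += ((xg - mg) ** 2).sum(axis=1)

    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    p = np.where(ssw == 0, np.where(ssb == 0, 1.0, 0.0), p)
    p = np.where(sst == 0, 1.0, p)
    return pd.Series(p, index=matrix.index, name="anova_p")


def anova_filter(series: ExpressionSeries, alpha: float = 0.01,
                 fallback_n: int = 3000
                 ) -> tuple[frozenset[str], pd.Series, bool]:
    """Genes differentially expressed between replicate groups.

    Returns ``(selected, p_values, fallback_used)``.  If fewer than
    ``fallback_n`` genes reach ``p < alpha``, the ``fallback_n`` genes with
    the smallest p-values are taken instead (all genes if fewer exist),
    with ties at the boundary broken by gene identifier.
    """
    gm = series.gene_matrix()
    p = anova_p_values(gm, series.replicate_group)
    significant = p.index[p.to_numpy() < alpha]
    if len(significant) >= fallback_n:
        return frozenset(significant), p, False
    order = sorted(p.index, key=lambda g: (p[g], g))
    return frozenset(order[:fallback_n]), p, True


def te_thresholds(series: ExpressionSeries, te_quantile: float = 0.90,
                  scope: str = "per_sample") -> pd.Series:
    """Abundance floor(s) from the TE rows.

    ``per_sample`` computes the quantile of TE abundances within each array
    (sample) separately; ``dataset`` pools all TE values into one floor.
    Linear-interpolation percentile convention.
    """
    if not series.te_rows:
        raise ConfigurationError(
            f"series {series.series_id!r}: te_rows is empty; "
            "the abundance filter needs TE rows")
    te = series.matrix.loc[sorted(series.te_rows)].to_numpy(dtype=float)
    if scope == "per_sample":
        thr = np.percentile(te, 100 * te_quantile, axis=0)
    elif scope == "dataset":
        thr = np.full(series.n_samples, np.percentile(te, 100 * te_quantile))
    else:
        raise ConfigurationError(f"te_percentile_scope: unknown scope {scope!r}")
    return pd.Series(thr, index=series.matrix.columns, name="te_threshold")


def abundance_filter(series: ExpressionSeries, te_quantile: float = 0.90,
                     scope: str = "per_sample") -> frozenset[str]:
    """Genes that are (a) called present in >= 1 sample and (b) exceed the
    TE abundance floor in >= 1 sample.  Both conditions required."""
    thr = te_thresholds(series, te_quantile, scope)
    gm = series.gene_matrix()
    present_any = series.present.loc[gm.index].any(axis=1)
    above_any = (gm > thr.to_numpy()[None, :]).any(axis=1)
    keep = gm.index[(present_any & above_any).to_numpy()]
    return frozenset(keep)


def select_relevant_genes(series: ExpressionSeries, alpha: float = 0.01,
                          fallback_n: int = 3000, te_quantile: float = 0.90,
                          te_scope: str = "per_sample",
                          min_samples: int = 20) -> FilterReport:
    """Full biologically-relevant-gene filter for one series.

    Final genes are the intersection of the ANOVA selection and the
    abundance-passing set, kept in the matrix row order (stable).  An empty
    final set is reported with a warning rather than raised.
    """
    if not check_min_samples(series, min_samples):
        raise DesignError(
            f"series {series.series_id!r} has {series.n_samples} samples, "
            f"fewer than the required {min_samples}")
    selected, p, fallback = anova_filter(series, alpha, fallback_n)
    passed = abundance_filter(series, te_quantile, te_scope)
    final = [g for g in series.gene_ids if g in selected and g in passed]
    warns: list[str] = []
    if not final:
        msg = f"series {series.series_id!r}: no genes pass the combined filter"
        warns.append(msg)
        warnings.warn(msg)
    return FilterReport(
        series_id=series.series_id,
        anova_p=p,
        selected_by_anova=selected,
        passed_abundance=passed,
        final_genes=final,
        fallback_used=fallback,
        warnings=warns,
    )
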