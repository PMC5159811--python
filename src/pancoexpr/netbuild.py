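"""Series-network construction: all-pairs Pearson correlation and a
top-fraction (default 0.1%) cutoff keeping positively correlated pairs.

The 0.1% is a rank cutoff on the post-filtering pair count P = G(G-1)/2;
the significance level it implies for a given sample size is reported
separately by :func:`correlation_pvalue`.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError
from .preprocess import select_relevant_genes, check_min_samples
from .types import CoexpressionNetwork, ExpressionSeries, FilterReport, ordered_pair


def pearson_all_pairs(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Condensed upper-triangle Pearson correlations for all gene pairs.

    Returns ``(pcc, genes)`` where ``pcc[k]`` is the correlation of the
    pair with condensed index ``k`` over ``genes`` (row order preserved).
    Rows with zero variance yield NaN for all their pairs, with a warning:
    complete matrices are assumed and such rows should have been filtered
    upstream.
    """
    if matrix.shape[1] < 3:
        raise DesignError("correlation requires at least 3 samples")
    if matrix.isna().to_numpy().any():
        raise DesignError("missing values are not supported in the PCC")
    genes = list(matrix.index)
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc ** 2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance row(s); their pairs are set to NaN")
    safe = np.where(zero, 1.0, norms)
    z = xc / safe[:, None]
    corr = z @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    if zero.any():
        corr[zero, :] = np.nan
        corr[:, zero] = np.nan
    iu = np.triu_indices(len(genes), k=1)
    return corr[iu], genes


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation ``r`` at sample size ``n``
    via the t-transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 df."""
    if n < 3:
        raise DesignError("correlation p-value requires n >= 3")
    if abs(r) > 1:
        raise ValueError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _condensed_to_pairs(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map condensed upper-triangle indices to (row, col) index pairs."""
    idx = np.asarray(idx, dtype=np.int64)
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * idx)) / 2.0).astype(np.int64)
    # guard against float rounding at block boundaries
    start = i * (b - i) // 2
    too_far = start > idx
    i[too_far] -= 1
    start = i * (b - i) // 2
    j = idx - start + i + 1
    return i, j


def threshold_top_fraction(pcc: np.ndarray, genes: list[str],
                           fraction: float = 0.001,
                           positive_only: bool = True,
                           drop_nonpositive_first: bool = False,
                           series_id: str = "", tissue: str = "",
                           condition: str = "") -> CoexpressionNetwork:
    """Keep the top ``fraction`` of all P = G(G-1)/2 pairs by correlation.

    k = floor(fraction * P) pairs are retained; ties at the boundary value
    are resolved by lexicographic gene-pair order.  With ``positive_only``
    (default) any retained pair with PCC <= 0 is then removed; the
    alternative ``drop_nonpositive_first`` excludes non-positive pairs from
    the ranking instead.  ``pcc_cutoff`` records the smallest retained PCC.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(genes)
    P = n * (n - 1) // 2
    if len(pcc) != P:
        raise ValueError(f"condensed length {len(pcc)} != G(G-1)/2 = {P}")
    vals = np.array(pcc, dtype=float)
    vals[np.isnan(vals)] = -np.inf
    if positive_only and drop_nonpositive_first:
        vals[vals <= 0] = -np.inf

    k = math.floor(fraction * P)
    if k == 0:
        warnings.warn("top-fraction cutoff keeps zero pairs; empty network")
        return CoexpressionNetwork(series_id=series_id, edges={},
                                   pcc_cutoff=None, tissue=tissue,
                                   condition=condition)

    n_finite = int(np.isfinite(vals).sum())
    k_eff = min(k, n_finite)
    selected: list[int] = []
    if k_eff > 0:
        vk = np.partition(vals, P - k_eff)[P - k_eff]
        gt = np.flatnonzero(vals > vk)
        selected = list(gt)
        m = k_eff - len(gt)
        if m > 0:
            ties = np.flatnonzero(vals == vk)
            ti, tj = _condensed_to_pairs(ties, n)
            named = sorted(
                (ordered_pair(genes[a], genes[b]), int(t))
                for a, b, t in zip(ti, tj, ties)
            )
            selected.extend(t for _, t in named[:m])

    sel = np.array(sorted(selected), dtype=np.int64)
    edges: dict[tuple[str, str], float] = {}
    if sel.size:
        ii, jj = _condensed_to_pairs(sel, n)
        for a, b, kdx in zip(ii, jj, sel):
            w = float(pcc[kdx])
            if positive_only and w <= 0:
                continue
            edges[ordered_pair(genes[a], genes[b])] = w
    cutoff = min(edges.values()) if edges else None
    return CoexpressionNetwork(series_id=series_id, edges=edges,
                               pcc_cutoff=cutoff, tissue=tissue,
                               condition=condition)


def build_series_network(series: ExpressionSeries,
                         min_samples: int = 20, alpha: float = 0.01,
                         fallback_n: int = 3000, te_quantile: float = 0.90,
                         te_scope: str = "per_sample",
                         fraction: float = 0.001, positive_only: bool = True,
                         drop_nonpositive_first: bool = False,
                         report: FilterReport | None = None
                         ) -> CoexpressionNetwork:
    """Filter a series and build its coexpression network.

    A precomputed :class:`FilterReport` may be passed to skip re-filtering.
    """
    if not check_min_samples(series, min_samples):
        raise DesignError(
            f"series {series.series_id!r} has {series.n_samples} samples, "
            f"fewer than the required {min_samples}")
    if report is None:
        report = select_relevant_genes(series, alpha, fallback_n,
                                       te_quantile, te_scope, min_samples)
    sub = series.matrix.loc[report.final_genes]
    if len(report.final_genes) < 2:
        warnings.warn(
            f"series {series.series_id!r}: fewer than 2 genes after filtering")
        return CoexpressionNetwork(series_id=series.series_id, edges={},
                                   pcc_cutoff=None, tissue=series.tissue,
                                   condition=series.condition)
    pcc, genes = pearson_all_pairs(sub)
    return threshold_top_fraction(
        pcc, genes, fraction=fraction, positive_only=positive_only,
        drop_nonpositive_first=drop_nonpositive_first,
        series_id=series.series_id, tissue=series.tissue,
        condition=series.condition)
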