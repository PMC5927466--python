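"""Per-feature time-course ANOVA, BH adjustment, effect-size decomposition
and post hoc day tests.

The omnibus test is the per-feature slice of a feature x time cell-means
model: a fixed-effects one-way ANOVA across day groups, optionally with a
per-feature observation weight and a residual variance pooled across
features (weighted least squares).  All routines are vectorised over
features.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# numerical tolerance for "no variation at all" degeneracy
_TOL = 1e-12


def _group_indices(design: pd.DataFrame, columns: Sequence[str]) -> dict[int, np.ndarray]:
    """Column indices of each day group, in matrix column order."""
    pos = {s: i for i, s in enumerate(columns)}
    out: dict[int, np.ndarray] = {}
    for day, sub in design.groupby("day", sort=True):
        out[int(day)] = np.array([pos[s] for s in sub["sample_id"]], dtype=int)
    return out


def group_sums_of_squares(
    values: np.ndarray, groups: Mapping[int, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Total, between and within sums of squares per feature (rows).

    Returns ``(sst, ssb, sse, n, t)`` where ``n`` is the total observation
    count and ``t`` the number of groups.
    """
    n = sum(len(ix) for ix in groups.values())
    t = len(groups)
    grand = values.mean(axis=1, keepdims=True)
    sst = ((values - grand) ** 2).sum(axis=1)
    sse = np.zeros(values.shape[0])
    for ix in groups.values():
        sub = values[:, ix]
        sse += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = sst - sse
    # guard against tiny negative round-off
    ssb = np.where(ssb < 0, 0.0, ssb)
    return sst, ssb, sse, n, t


def anova_pvalues(
    values: pd.DataFrame,
    design: pd.DataFrame,
    weights: pd.Series | None = None,
    error_pooling: str = "per_gene",
) -> pd.Series:
    """Omnibus p-value per feature for a time effect.

    ``error_pooling='per_gene'``: textbook per-feature one-way ANOVA,
    ``F = (SSB/(T-1)) / (SSE/(N-T))``.  A constant per-feature weight cancels
    in this ratio, so weights are ignored here.

    ``error_pooling='global'``: the residual variance is pooled across all
    features with per-feature observation weights (weighted least squares);
    each feature's weighted between-group mean square is tested against the
    pooled weighted mean squared error on ``G*(N-T)`` denominator df.

    Features with no variation at all get p = 1 by convention; features with
    zero within-group variance but real group differences get p = 0.
    """
    groups = _group_indices(design, values.columns)
    if len(groups) < 2:
        raise ValueError("need at least 2 time groups")
    for day, ix in groups.items():
        if error_pooling == "per_gene" and len(ix) < 2:
            raise ValueError(f"day {day} has fewer than 2 replicates")
    x = np.asarray(values, dtype=float)
    sst, ssb, sse, n, t = group_sums_of_squares(x, groups)
    dfn, dfd = t - 1, n - t
    if error_pooling == "per_gene":
        p = np.ones(x.shape[0])
        scale = np.maximum(sst, 1.0)
        degenerate = sst <= _TOL * scale
        zero_sse = (~degenerate) & (sse <= _TOL * scale)
        ok = (~degenerate) & (~zero_sse)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb[ok] / dfn) / (sse[ok] / dfd)
        p[ok] = stats.f.sf(f, dfn, dfd)
        p[zero_sse] = 0.0
    elif error_pooling == "global":
        if weights is None:
            w = np.ones(x.shape[0])
        else:
            w = np.asarray(weights.reindex(values.index), dtype=float)
        g = x.shape[0]
        pooled = float((w * sse).sum()) / (g * dfd)
        if pooled <= 0:
            raise ValueError("zero pooled residual variance")
        f = (w * ssb / dfn) / pooled
        p = stats.f.sf(f, dfn, g * dfd)
    else:
        raise ValueError(f"unknown error_pooling {error_pooling!r}")
    return pd.Series(p, index=values.index, name="p")


def bh_adjust(p: Sequence[float] | pd.Series) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving, <= 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return pd.Series(dtype=float) if isinstance(p, pd.Series) else arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(adj, index=p.index, name="p_adj")
    return adj


def effect_decomposition(
    values: pd.DataFrame, design: pd.DataFrame, mode: str = "as_written"
) -> pd.DataFrame:
    """Per-feature effect-size decomposition and filter decision.

    ``sst`` is the squared deviation of every observation from the feature's
    grand mean (the regression error about the grand mean); ``sse`` the
    within-day-group squared deviation.  With ``sigma_ssr = sqrt(sst/(N-1))``
    and ``sigma_within = sqrt(sse/(N-1))``, the feature passes when its
    minimum effect size ``delta = 0.3 * sigma_ssr`` strictly exceeds
    ``0.3 * sigma_within`` (mode ``as_written``, equivalent to SST > SSE),
    or when the between-group sum of squares exceeds the within-group one
    (mode ``between_vs_within``, SSB > SSE).
    """
    groups = _group_indices(design, values.columns)
    if len(groups) < 2:
        raise ValueError("need at least 2 time groups")
    x = np.asarray(values, dtype=float)
    sst, ssb, sse, n, _ = group_sums_of_squares(x, groups)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sigma_ssr = np.sqrt(sst / (n - 1))
    sigma_within = np.sqrt(sse / (n - 1))
    if mode == "as_written":
        passed = sst > sse
    elif mode == "between_vs_within":
        passed = ssb > sse
    else:
        raise ValueError(f"unknown effect mode {mode!r}")
    return pd.DataFrame(
        {
            "sst": sst,
            "ssb": ssb,
            "sse": sse,
            "n": n,
            "sigma_ssr": sigma_ssr,
            "sigma_within": sigma_within,
            "delta": 0.3 * sigma_ssr,
            "effect_pass": passed,
        },
        index=values.index,
    )


def posthoc_ttests(
    values: pd.DataFrame, design: pd.DataFrame, baseline_day: int = 0
) -> dict[int, pd.DataFrame]:
    """Equal-variance two-sample t tests of each non-baseline day vs baseline.

    Returns ``{day: DataFrame(p, mean_diff)}`` per feature.  Degenerate
    features (zero pooled variance) get p = 1 when the group means agree and
    p = 0 otherwise.
    """
    groups = _group_indices(design, values.columns)
    if baseline_day not in groups:
        raise ValueError(f"baseline day {baseline_day} missing from design")
    x = np.asarray(values, dtype=float)
    ix0 = groups[baseline_day]
    n0 = len(ix0)
    x0 = x[:, ix0]
    m0 = x0.mean(axis=1)
    ss0 = ((x0 - m0[:, None]) ** 2).sum(axis=1)
    out: dict[int, pd.DataFrame] = {}
    for day, ix in groups.items():
        if day == baseline_day:
            continue
        xd = x[:, ix]
        nd = len(ix)
        md = xd.mean(axis=1)
        ssd = ((xd - md[:, None]) ** 2).sum(axis=1)
        df = n0 + nd - 2
        if df <= 0:
            raise ValueError(f"day {day}: not enough replicates for a t test")
        sp2 = (ss0 + ssd) / df
        diff = md - m0
        scale = np.maximum(np.abs(m0) + np.abs(md), 1.0)
        degenerate = sp2 <= _TOL * scale**2
        p = np.empty(x.shape[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = diff / np.sqrt(sp2 * (1.0 / n0 + 1.0 / nd))
        p[~degenerate] = 2.0 * stats.t.sf(np.abs(tstat[~degenerate]), df)
        p[degenerate] = np.where(np.abs(diff[degenerate]) <= _TOL * scale[degenerate], 1.0, 0.0)
        out[int(day)] = pd.DataFrame(
            {"p": p, "mean_diff": diff}, index=values.index
        )
    return out
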