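"""Differential metabolite enrichment over a time course.

Log2 relative changes (log2RC) against the day-0 mean are tested per
metabolite with the same time-course ANOVA as the expression layer (unit
weights), BH-adjusted, and filtered against a metabolome-wide minimum
effect size: delta = 0.3 * sigma_log2RC, where sigma_log2RC^2 =
SSE_log2RC / (N - 1) pools the within metabolite-x-time measurement error
across the whole matrix, and the smallest sigma over the supplied cell
lines is used.  A threshold of 0.20 log2 units corresponds to about a
1.15-fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import (
    anova_pvalues,
    bh_adjust,
    group_sums_of_squares,
    _group_indices,
    posthoc_ttests,
)
from .foldchange import log2_ratio_matrix


def fold_change_equivalent(delta: float) -> float:
    """Fold-change equivalent of a log2 effect threshold (2**delta)."""
    return float(2.0**delta)


def metabolome_dispersion(l2rc: pd.DataFrame, design: pd.DataFrame) -> float:
    """Metabolome-wide sigma_log2RC = sqrt(SSE / (N - 1)).

    SSE sums squared deviations from the metabolite x time cell means over
    the entire matrix; N is the total number of observations in the matrix.
    """
    groups = _group_indices(design, l2rc.columns)
    for day, ix in groups.items():
        if len(ix) < 2:
            raise ValueError(f"day {day} has fewer than 2 replicates")
    x = np.asarray(l2rc, dtype=float)
    _, _, sse, n_per_feature, _ = group_sums_of_squares(x, groups)
    n_total = x.size
    if n_total < 2:
        raise ValueError("need at least 2 observations")
    return float(np.sqrt(sse.sum() / (n_total - 1)))


def metabolome_threshold(
    l2rc_per_line: list[tuple[pd.DataFrame, pd.DataFrame]],
    factor: float = 0.3,
    allow_zero: bool = False,
) -> float:
    """Minimum-effect threshold: ``factor`` x the smallest per-line sigma.

    ``l2rc_per_line`` is a list of (log2RC matrix, design) pairs, one per
    cell line; with two lines the smaller dispersion estimate wins.  A zero
    dispersion (noise-free input) is degenerate and raises unless
    ``allow_zero`` is set.
    """
    if not l2rc_per_line:
        raise ValueError("need at least one cell line")
    sigmas = [metabolome_dispersion(m, d) for m, d in l2rc_per_line]
    sigma = min(sigmas)
    if sigma <= 0 and not allow_zero:
        raise ValueError("zero metabolome-wide dispersion; pass allow_zero=True")
    return factor * sigma


class MetaboliteEnrichmentModel:
    """Time-course differential-enrichment model for metabolite abundances.

    Parameters
    ----------
    content
        metabolite x sample abundance matrix (positive, arbitrary units).
    design
        sample design table.
    other_lines
        optional list of (content, design) pairs for additional cell lines;
        the effect threshold takes the smallest metabolome-wide dispersion
        across all lines.
    """

    def __init__(
        self,
        content: pd.DataFrame,
        design: pd.DataFrame,
        *,
        other_lines: list[tuple[pd.DataFrame, pd.DataFrame]] | None = None,
        baseline_day: int = 0,
        floor: float = 0.01,
    ) -> None:
        self.content = content
        self.design = design.reset_index(drop=True)
        self.other_lines = other_lines or []
        self.baseline_day = baseline_day
        self.floor = floor

    @classmethod
    def from_study(cls, study, **kwargs) -> "MetaboliteEnrichmentModel":
        return cls(study.content, study.design, **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        alpha_posthoc: float = 0.05,
        threshold: float | None = None,
    ) -> "DEMResults":
        l2rc = log2_ratio_matrix(
            self.content, self.design, baseline_day=self.baseline_day, floor=self.floor
        )
        lines = [(l2rc, self.design)]
        for content2, design2 in self.other_lines:
            l2rc2 = log2_ratio_matrix(
                content2, design2, baseline_day=self.baseline_day, floor=self.floor
            )
            lines.append((l2rc2, design2))
        if threshold is None:
            threshold = metabolome_threshold(lines)
        p = anova_pvalues(l2rc, self.design, weights=None, error_pooling="per_gene")
        p_adj = bh_adjust(p)
        posthoc = posthoc_ttests(l2rc, self.design, baseline_day=self.baseline_day)
        days = sorted(posthoc)

        table = pd.DataFrame({"p": p, "p_adj": p_adj})
        group_means = np.column_stack(
            [posthoc[d]["mean_diff"].to_numpy() for d in days]
        )
        effect = np.abs(group_means).max(axis=1)
        table["effect"] = effect
        table["effect_pass"] = effect >= threshold
        for j, d in enumerate(days):
            sig = posthoc[d]["p"].to_numpy() < alpha_posthoc
            table[f"p_day{d}"] = posthoc[d]["p"]
            table[f"l2rc_day{d}"] = posthoc[d]["mean_diff"]
            table[f"dir_day{d}"] = np.where(
                sig, np.where(group_means[:, j] > 0, "up", "down"), "none"
            )
        table["is_dem"] = (table["p_adj"] <= alpha) & table["effect_pass"]
        return DEMResults(
            table=table,
            log2rc=l2rc,
            threshold=float(threshold),
            design=self.design,
            days=days,
            alpha=alpha,
            alpha_posthoc=alpha_posthoc,
            model=self,
        )


@dataclass
class DEMResults:
    """Fitted differential-enrichment results (one row per metabolite)."""

    table: pd.DataFrame
    log2rc: pd.DataFrame
    threshold: float
    design: pd.DataFrame
    days: list[int]
    alpha: float
    alpha_posthoc: float
    model: MetaboliteEnrichmentModel

    @property
    def n_dem(self) -> int:
        return int(self.table["is_dem"].sum())

    def dem_ids(self, day: int | None = None) -> pd.Index:
        t = self.table
        if day is None:
            return t.index[t["is_dem"]]
        return t.index[t["is_dem"] & (t[f"p_day{day}"] < self.alpha_posthoc)]

    def day_counts(self) -> pd.DataFrame:
        rows = []
        for d in self.days:
            ids = self.dem_ids(d)
            dirs = self.table.loc[ids, f"dir_day{d}"]
            rows.append(
                {
                    "day": d,
                    "n_dem": len(ids),
                    "up": int((dirs == "up").sum()),
                    "down": int((dirs == "down").sum()),
                }
            )
        return pd.DataFrame(rows).set_index("day")

    def intersection_all_days(self) -> pd.Index:
        ids = self.dem_ids(self.days[0])
        for d in self.days[1:]:
            ids = ids.intersection(self.dem_ids(d))
        return ids

    def evaluate(self, truth: pd.DataFrame) -> dict[str, float]:
        from .evaluate import confusion

        truth_any = (truth != 0).any(axis=1).reindex(self.table.index, fill_value=False)
        return confusion(self.table["is_dem"], truth_any)

    def summary(self) -> str:
        lines = [
            "Differential metabolite enrichment (time-course ANOVA)",
            "=" * 54,
            f"metabolites: {len(self.table)}",
            f"alpha (BH) <= {self.alpha}   post hoc p < {self.alpha_posthoc}",
            f"effect threshold delta_log2RC >= {self.threshold:.4f} "
            f"({fold_change_equivalent(self.threshold):.4f}-fold)",
            f"DEMs (any day): {self.n_dem}",
            "",
            self.day_counts().to_string(),
            "",
            f"common to all days: {len(self.intersection_all_days())}",
        ]
        return "\n".join(lines)
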