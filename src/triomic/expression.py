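"""Differential gene expression from an RPKM time course.

The model follows a weighted feature x time ANOVA design: per-gene log2
fold changes against the day-0 mean, an omnibus time-effect F test (with
optional cumulative-hazard gene weights and globally pooled error),
Benjamini-Hochberg adjustment across genes, a minimum gene-wise effect-size
filter (delta = 0.3 * sigma_SSR against 0.3 * sigma of the within-group
error), and post hoc Student t tests of each day against day 0.

A gene is called differentially expressed (DEG) when the adjusted omnibus
p <= alpha, the effect filter passes, and at least one day's post hoc test
is significant; its per-day direction is up/down only on significant days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import anova_pvalues, bh_adjust, effect_decomposition, posthoc_ttests
from .foldchange import log2_ratio_matrix
from .weights import gene_weights


class DifferentialExpressionModel:
    """Weighted-ANOVA differential expression model.

    Parameters
    ----------
    rpkm
        gene x sample RPKM matrix (nonnegative).
    design
        sample design with ``sample_id``, ``day``, ``replicate`` columns.
    baseline_day
        reference day for fold changes and post hoc tests.
    floor
        additive RPKM floor before log2 (keeps zero counts finite).
    weighting
        ``"hazard"`` for cumulative-hazard gene weights, ``"none"`` for unit
        weights (the textbook-ANOVA oracle path).
    error_pooling
        ``"per_gene"`` (per-gene residual variance; weights cancel) or
        ``"global"`` (residual variance pooled across genes under the gene
        weights, where the weighting is mathematically consequential).
    effect_mode
        ``"as_written"`` (delta > 0.3 * sigma_within, i.e. SST > SSE) or
        ``"between_vs_within"`` (SSB > SSE).
    """

    def __init__(
        self,
        rpkm: pd.DataFrame,
        design: pd.DataFrame,
        *,
        baseline_day: int = 0,
        floor: float = 0.01,
        weighting: str = "hazard",
        error_pooling: str = "per_gene",
        effect_mode: str = "as_written",
    ) -> None:
        if weighting not in ("hazard", "none"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.rpkm = rpkm
        self.design = design.reset_index(drop=True)
        self.baseline_day = baseline_day
        self.floor = floor
        self.weighting = weighting
        self.error_pooling = error_pooling
        self.effect_mode = effect_mode

    @classmethod
    def from_study(cls, study, **kwargs) -> "DifferentialExpressionModel":
        """Build from a simulated :class:`~triomic.simulate.ExpressionStudy`."""
        return cls(study.rpkm, study.design, **kwargs)

    def fit(self, alpha: float = 0.05, alpha_posthoc: float = 0.05) -> "DEGResults":
        l2fc = log2_ratio_matrix(
            self.rpkm, self.design, baseline_day=self.baseline_day, floor=self.floor
        )
        if self.weighting == "hazard":
            wtab = gene_weights(self.rpkm, floor=self.floor)
            w = wtab["weight"]
        else:
            wtab = None
            w = None
        p = anova_pvalues(l2fc, self.design, weights=w, error_pooling=self.error_pooling)
        p_adj = bh_adjust(p)
        eff = effect_decomposition(l2fc, self.design, mode=self.effect_mode)
        posthoc = posthoc_ttests(l2fc, self.design, baseline_day=self.baseline_day)

        table = pd.DataFrame({"p": p, "p_adj": p_adj})
        table = table.join(eff)
        days = sorted(posthoc)
        any_day = np.zeros(len(table), dtype=bool)
        for d in days:
            pd_day = posthoc[d]
            sig = pd_day["p"].to_numpy() < alpha_posthoc
            direction = np.where(
                sig, np.where(pd_day["mean_diff"].to_numpy() > 0, "up", "down"), "none"
            )
            # a zero mean difference cannot carry a direction
            direction = np.where(
                sig & (pd_day["mean_diff"].to_numpy() == 0), "none", direction
            )
            table[f"p_day{d}"] = pd_day["p"]
            table[f"l2fc_day{d}"] = pd_day["mean_diff"]
            table[f"dir_day{d}"] = direction
            any_day |= sig
        is_deg = (
            (table["p_adj"].to_numpy() <= alpha)
            & table["effect_pass"].to_numpy()
            & any_day
        )
        table["is_deg"] = is_deg
        sig_mat = np.column_stack(
            [(posthoc[d]["p"].to_numpy() < alpha_posthoc) for d in days]
        )
        table["deg_days"] = [
            ",".join(str(d) for j, d in enumerate(days) if sig_mat[i, j])
            if is_deg[i]
            else ""
            for i in range(len(table))
        ]
        return DEGResults(
            table=table,
            log2fc=l2fc,
            weights=wtab,
            design=self.design,
            days=days,
            alpha=alpha,
            alpha_posthoc=alpha_posthoc,
            model=self,
        )


@dataclass
class DEGResults:
    """Fitted differential-expression results.

    ``table`` has one row per gene: omnibus ``p``/``p_adj``, the effect-size
    decomposition (``sst``, ``ssb``, ``sse``, ``delta``, ``effect_pass``),
    per-day post hoc ``p_day{d}``, mean log2FC ``l2fc_day{d}`` and direction
    ``dir_day{d}``, plus ``is_deg`` and the comma-joined ``deg_days``.
    """

    table: pd.DataFrame
    log2fc: pd.DataFrame
    weights: pd.DataFrame | None
    design: pd.DataFrame
    days: list[int]
    alpha: float
    alpha_posthoc: float
    model: DifferentialExpressionModel

    @property
    def n_deg(self) -> int:
        return int(self.table["is_deg"].sum())

    def deg_ids(self, day: int | None = None) -> pd.Index:
        """Genes called at a given day (post hoc significant) or overall."""
        t = self.table
        if day is None:
            return t.index[t["is_deg"]]
        return t.index[t["is_deg"] & (t[f"p_day{day}"] < self.alpha_posthoc)]

    def day_counts(self) -> pd.DataFrame:
        """Per-day DEG counts split by direction."""
        rows = []
        for d in self.days:
            ids = self.deg_ids(d)
            dirs = self.table.loc[ids, f"dir_day{d}"]
            rows.append(
                {
                    "day": d,
                    "n_deg": len(ids),
                    "up": int((dirs == "up").sum()),
                    "down": int((dirs == "down").sum()),
                }
            )
        return pd.DataFrame(rows).set_index("day")

    def intersection_all_days(self) -> pd.Index:
        ids = self.deg_ids(self.days[0])
        for d in self.days[1:]:
            ids = ids.intersection(self.deg_ids(d))
        return ids

    def evaluate(self, truth: pd.DataFrame) -> dict[str, float]:
        """Sensitivity / observed FDR of the overall DEG calls vs truth."""
        from .evaluate import confusion

        truth_any = (truth != 0).any(axis=1).reindex(self.table.index, fill_value=False)
        return confusion(self.table["is_deg"], truth_any)

    def summary(self) -> str:
        counts = self.day_counts()
        lines = [
            "Differential expression (weighted time-course ANOVA)",
            "=" * 54,
            f"genes: {len(self.table)}   weighting: {self.model.weighting}"
            f"   pooling: {self.model.error_pooling}",
            f"alpha (BH) <= {self.alpha}   post hoc p < {self.alpha_posthoc}"
            f"   effect mode: {self.model.effect_mode}",
            f"DEGs (any day): {self.n_deg}",
            "",
            counts.to_string(),
            "",
            f"common to all days: {len(self.intersection_all_days())}",
        ]
        return "\n".join(lines)

    def plot_volcano(self, day: int, ax=None):
        """Volcano plot of a day's mean log2FC vs -log10 adjusted p."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.table[f"l2fc_day{day}"]
        y = -np.log10(self.table["p_adj"].clip(lower=1e-300))
        called = self.table["is_deg"] & (self.table[f"p_day{day}"] < self.alpha_posthoc)
        ax.scatter(x[~called], y[~called], s=4, c="grey", alpha=0.5, label="not called")
        ax.scatter(x[called], y[called], s=6, c="crimson", label="DEG")
        ax.set_xlabel(f"mean log2FC day {day} vs 0")
        ax.set_ylabel("-log10 BH-adjusted p")
        ax.legend(frameon=False)
        return ax
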