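"""Cross-referencing differential methylation with differential expression.

Gene-level summaries aggregate significant probes by array location class
(promoter = TSS1500 + TSS200 by default, body = gene body + 1st exon,
overall = all probes inside the gene, its UTRs and promoter), and feed
three statistics:

* DMEG counts — how many of a day's DEGs carry a significant promoter
  methylation change (reported also as an integer percentage);
* the 2x2 association between being a DEG and bearing a promoter
  methylation change, as an odds ratio with a Pearson chi-squared test
  (Haldane-Anscombe +0.5 correction when a cell is empty);
* concordance — the fraction of DEGs whose methylation change sign agrees
  with their expression direction under a stated sign convention
  (``promoter_inverse`` counts hypomethylation-with-upregulation and
  hypermethylation-with-downregulation as concordant; ``same_sign``
  counts matching signs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PROMOTER_CLASSES = ("TSS1500", "TSS200")
BODY_CLASSES = ("Body", "1stExon")
UTR_CLASSES = ("5UTR", "3UTR")


def round_percentage(numerator: float, denominator: float) -> int:
    """Integer percentage, rounded half away from zero (published style)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    pct = 100.0 * numerator / denominator
    return int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))


def summarize_gene_methylation(
    dml_table: pd.DataFrame,
    day: int,
    promoter_classes: tuple[str, ...] = PROMOTER_CLASSES,
    alpha_posthoc: float = 0.05,
) -> pd.DataFrame:
    """Per-gene methylation-change summary at one day.

    ``dml_table`` is a :class:`~triomic.methylation.DMLResults` table with
    ``gene_id``, ``location_class``, ``is_dml`` and per-day ``p_day{d}`` /
    ``delta_day{d}`` columns.  Only significant probes (DML overall and
    post hoc significant at the day) contribute.  Genes with no
    contributing probe in a scope get NaN for that scope's mean delta;
    genes with no probes at all are absent.
    """
    t = dml_table
    required = {f"p_day{day}", f"delta_day{day}", "gene_id", "location_class"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"dml table lacks columns {sorted(missing)}")
    sig = t["is_dml"] & (t[f"p_day{day}"] < alpha_posthoc).fillna(False)
    sub = t.loc[sig & t["gene_id"].notna()].copy()
    body_classes = tuple(c for c in BODY_CLASSES if c not in promoter_classes)
    overall_classes = set(promoter_classes) | set(body_classes) | set(UTR_CLASSES)

    def scope_mean(scope_classes):
        s = sub.loc[sub["location_class"].isin(scope_classes)]
        return s.groupby("gene_id")[f"delta_day{day}"].mean()

    promoter = scope_mean(promoter_classes)
    body = scope_mean(body_classes)
    overall = scope_mean(overall_classes)
    genes = overall.index.union(promoter.index).union(body.index)
    out = pd.DataFrame(index=genes)
    out.index.name = "gene_id"
    out["promoter_delta"] = promoter.reindex(genes)
    out["body_delta"] = body.reindex(genes)
    out["overall_delta"] = overall.reindex(genes)
    out["has_promoter_dml"] = out["promoter_delta"].notna()
    return out


def count_dmegs(
    deg_table: pd.DataFrame,
    summary: pd.DataFrame,
    day: int,
    alpha_posthoc: float = 0.05,
) -> tuple[int, int | None]:
    """Differentially methylated DEG count at a day and its percentage.

    A DMEG is a day-``day`` DEG (post hoc significant that day) whose gene
    has at least one significant promoter probe the same day.  The
    percentage is of that day's DEGs, rounded to the nearest integer; with
    zero DEGs it is undefined (None).
    """
    degs = deg_table.index[
        deg_table["is_deg"] & (deg_table[f"p_day{day}"] < alpha_posthoc)
    ]
    if len(degs) == 0:
        return 0, None
    with_dml = summary.index[summary["has_promoter_dml"]]
    n_dmeg = len(degs.intersection(with_dml))
    return n_dmeg, round_percentage(n_dmeg, len(degs))


@dataclass
class ContingencyResult:
    """2x2 DEG x promoter-DML association over a gene universe."""

    a: int  # DEG and DML
    b: int  # DEG, no DML
    c: int  # not DEG, DML
    d: int  # neither
    odds_ratio: float
    corrected: bool  # Haldane-Anscombe +0.5 applied for the OR
    chi2: float
    p: float

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """(a*d)/(b*c), with +0.5 on every cell when any cell is zero."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def deg_dml_association(
    deg_table: pd.DataFrame,
    summaries: dict[int, pd.DataFrame] | pd.DataFrame,
    universe_size: int,
) -> ContingencyResult:
    """DEG x promoter-methylation 2x2 table over the annotated gene universe.

    A gene counts as methylation-changed when it has a significant promoter
    probe at any day (``summaries`` maps day -> gene summary, or is a single
    summary).  The chi-squared statistic is Pearson's without continuity
    correction on 1 df.
    """
    if isinstance(summaries, pd.DataFrame):
        summaries = {0: summaries}
    dml_genes: set = set()
    for s in summaries.values():
        dml_genes |= set(s.index[s["has_promoter_dml"]])
    deg_genes = set(deg_table.index[deg_table["is_deg"]])
    observed = deg_genes | dml_genes
    if universe_size < len(observed):
        raise ValueError(
            f"universe_size {universe_size} smaller than observed gene set "
            f"({len(observed)})"
        )
    a = len(deg_genes & dml_genes)
    b = len(deg_genes - dml_genes)
    c = len(dml_genes - deg_genes)
    d = universe_size - a - b - c
    oratio, corrected = odds_ratio_2x2(a, b, c, d)
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ContingencyResult(a, b, c, d, oratio, corrected, float(chi2), float(p))


@dataclass
class ConcordanceResult:
    """Sign-quadrant breakdown of methylation change vs expression direction."""

    day: int
    scope: str  # promoter | body | overall
    convention: str  # promoter_inverse | same_sign
    quadrants: dict[str, int]  # e.g. {"hyper_up": 3, ...}
    n_eligible: int
    fraction: float | None  # None when no gene is eligible


def concordance(
    deg_table: pd.DataFrame,
    summary: pd.DataFrame,
    day: int,
    scope: str = "promoter",
    convention: str = "promoter_inverse",
    alpha_posthoc: float = 0.05,
) -> ConcordanceResult:
    """Concordance between methylation change sign and expression direction.

    Eligible genes are the day's DEGs with a direction and a nonzero
    ``{scope}_delta`` in ``summary``.  ``promoter_inverse`` counts
    hypo+up and hyper+down as concordant (the repressive-promoter
    expectation); ``same_sign`` counts hyper+up and hypo+down.
    """
    col = f"{scope}_delta"
    if col not in summary.columns:
        raise ValueError(f"scope {scope!r} not present in summary")
    if convention not in ("promoter_inverse", "same_sign"):
        raise ValueError(f"unknown convention {convention!r}")
    degs = deg_table.loc[
        deg_table["is_deg"] & (deg_table[f"p_day{day}"] < alpha_posthoc)
    ]
    quad = {"hyper_up": 0, "hyper_down": 0, "hypo_up": 0, "hypo_down": 0}
    for gene, row in degs.iterrows():
        direction = row[f"dir_day{day}"]
        if direction not in ("up", "down") or gene not in summary.index:
            continue
        delta = summary.loc[gene, col]
        if pd.isna(delta) or delta == 0:
            continue
        meth = "hyper" if delta > 0 else "hypo"
        quad[f"{meth}_{direction}"] += 1
    n = sum(quad.values())
    if convention == "promoter_inverse":
        conc = quad["hypo_up"] + quad["hyper_down"]
    else:
        conc = quad["hyper_up"] + quad["hypo_down"]
    return ConcordanceResult(
        day=day,
        scope=scope,
        convention=convention,
        quadrants=quad,
        n_eligible=n,
        fraction=(conc / n) if n else None,
    )
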