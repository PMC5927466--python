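"""450K-style methylation processing: beta values, block QC, imputation
and differentially methylated locus (DML) calling.

Probe methylation is quantified as ``beta = mCG/(mCG+CG) * 100`` from the
paired fluorometric intensities (no background subtraction, no
normalisation).  QC operates on probe x cell x time replicate blocks:

* a block with more than one failed read or more than one outlier is
  discarded;
* outliers are replicates whose residual around the block sample mean
  falls outside a 1.5-IQR fence.  The fence is estimated array-wise: the
  residuals of all blocks are pooled and the Tukey fence
  ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` of that pooled distribution (linear
  interpolation quartiles) is applied to every replicate.  Per-block
  quartile fences are degenerate on 3 replicates (they can never flag, or
  flag almost half of clean blocks, depending on convention); pooling the
  residual distribution restores a calibrated rule.  When a lone block is
  QC'd without array context, a median-centred block fence
  (median +/- 1.5*IQR of the block residuals) is used instead;
* a single failed/outlier replicate is dropped and the block (now N = 2)
  is brought back to N = 3 by imputation: the trimmed mean of the two
  survivors plus a residual estimate borrowed from the probe's other
  cell x time groups, weighted by the pairwise correlation of group beta
  profiles.

DML calling is a per-probe one-way ANOVA across days on post-QC beta, BH
adjustment over probes, and post hoc t tests per day against day 0 with
per-day delta %mCG (mean beta difference vs day 0, percentage points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import bh_adjust

_TOL = 1e-12

KEEP, IMPUTE, DISCARD = "keep", "impute_needed", "discard"


def compute_beta(mcg, cg):
    """Percent methylation beta = mCG/(mCG+CG) * 100.

    Accepts scalars or arrays; cells with mcg + cg == 0 are undefined and
    returned as NaN (callers treat them as failed reads).
    """
    mcg = np.asarray(mcg, dtype=float)
    cg = np.asarray(cg, dtype=float)
    if (mcg < 0).any() or (cg < 0).any():
        raise ValueError("intensities must be nonnegative")
    total = mcg + cg
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(total > 0, mcg / np.where(total > 0, total, 1.0) * 100.0, np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def block_fence(values: np.ndarray) -> tuple[float, float]:
    """Median-centred 1.5-IQR fence of a lone block's residuals.

    Used only when no array-wide residual distribution is available; with
    three replicates this fence flags at most one of them.
    """
    res = np.asarray(values, dtype=float)
    res = res - res.mean()
    q1, med, q3 = np.percentile(res, [25, 50, 75])
    iqr = q3 - q1
    return med - 1.5 * iqr, med + 1.5 * iqr


def pooled_residual_fence(residuals: np.ndarray) -> tuple[float, float]:
    """Tukey fence [Q1 - 1.5*IQR, Q3 + 1.5*IQR] of pooled block residuals."""
    res = np.asarray(residuals, dtype=float)
    res = res[np.isfinite(res)]
    if res.size < 4:
        raise ValueError("need at least 4 pooled residuals for a fence")
    q1, q3 = np.percentile(res, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


@dataclass
class BlockQC:
    """QC verdict for one probe x cell x time replicate block."""

    status: str  # keep | impute_needed | discard
    surviving: np.ndarray  # boolean mask over the block's replicates
    outlier: np.ndarray  # boolean mask of flagged outliers
    n_failed: int


def qc_filter(
    beta_block: np.ndarray,
    failed: np.ndarray | None = None,
    fence: tuple[float, float] | None = None,
) -> BlockQC:
    """Apply the failed-read / 1.5-IQR outlier rule to one replicate block.

    A block loses at most one replicate: more than one failed read or more
    than one outlier discards it outright; a single failed or outlying
    replicate is dropped (status ``impute_needed`` when 2 of 3 survive).
    Undefined beta values (NaN) count as failed reads.  ``fence`` is the
    array-wide residual fence; without it the block's own median-centred
    fence is used.
    """
    beta_block = np.asarray(beta_block, dtype=float)
    if beta_block.size == 0:
        raise ValueError("empty block")
    if failed is None:
        failed = np.zeros(beta_block.shape, dtype=bool)
    failed = np.asarray(failed, dtype=bool) | ~np.isfinite(beta_block)
    n = beta_block.size
    n_failed = int(failed.sum())
    outlier = np.zeros(n, dtype=bool)
    if n_failed > 1:
        return BlockQC(DISCARD, np.zeros(n, dtype=bool), outlier, n_failed)
    ok = ~failed
    vals = beta_block[ok]
    if vals.size >= 3:
        res = vals - vals.mean()
        lo, hi = fence if fence is not None else block_fence(vals)
        flags = (res < lo) | (res > hi)
        if int(flags.sum()) > 1:
            # several crossings: a lone aberrant replicate drags the block
            # mean and can push the honest replicates over the fence too.
            # Drop the most aberrant value and re-test the survivors; only
            # a still-aberrant remainder counts as a second outlier.
            worst = int(np.argmax(np.abs(res)))
            rest = np.delete(vals, worst)
            res_rest = rest - rest.mean()
            if ((res_rest < lo) | (res_rest > hi)).any():
                outlier[np.flatnonzero(ok)[flags]] = True
            else:
                keep_flags = np.zeros(vals.size, dtype=bool)
                keep_flags[worst] = True
                outlier[np.flatnonzero(ok)[keep_flags]] = True
        else:
            outlier[np.flatnonzero(ok)[flags]] = True
    if int(outlier.sum()) > 1:
        return BlockQC(DISCARD, np.zeros(n, dtype=bool), outlier, n_failed)
    surviving = ok & ~outlier
    n_surv = int(surviving.sum())
    if n_surv == n:
        status = KEEP
    elif n_surv == n - 1 and n_surv >= 2:
        status = IMPUTE
    else:
        status = DISCARD
        surviving = np.zeros(n, dtype=bool)
    return BlockQC(status, surviving, outlier, n_failed)


def impute_third(
    survivors: np.ndarray,
    context: list[tuple[float, float]] | None = None,
) -> float:
    """Impute the missing third replicate of a 2-survivor block.

    The base is the trimmed mean of the survivors (with two values, their
    midpoint); it is adjusted by a residual estimate borrowed from the
    probe's other groups, ``sum(rho_k * resid_k) / sum(|rho_k|)`` over
    ``context`` pairs ``(rho, resid)``.  With no context the unadjusted
    mean is returned.  The result is clipped to [0, 100].
    """
    survivors = np.asarray(survivors, dtype=float)
    if survivors.size != 2:
        raise ValueError("imputation requires exactly 2 surviving replicates")
    base = float(survivors.mean())
    adj = 0.0
    if context:
        denom = sum(abs(rho) for rho, _ in context)
        if denom > 0:
            adj = sum(rho * resid for rho, resid in context) / denom
    return float(np.clip(base + adj, 0.0, 100.0))


@dataclass
class QCSummary:
    n_blocks: int
    n_keep: int
    n_imputed: int
    n_discarded: int
    fence: tuple[float, float] | None = None
    excluded_probes: list[str] = field(default_factory=list)


@dataclass
class BetaMatrix:
    """Post-QC beta matrix with per-cell provenance.

    ``beta`` holds observed and imputed percent-methylation values (NaN for
    discarded cells); ``provenance`` labels each cell observed / imputed /
    discarded; ``status`` is the per probe x day block verdict.
    """

    beta: pd.DataFrame
    provenance: pd.DataFrame
    status: pd.DataFrame
    correlation: pd.DataFrame
    qc_summary: QCSummary
    design: pd.DataFrame


class MethylationModel:
    """Methylation array model: intensities -> QC'd beta -> DML calls.

    Parameters
    ----------
    mcg, cg
        probe x sample methylated/unmethylated intensity matrices.
    failed
        probe x sample boolean failed-read mask; cells with zero total
        intensity are treated as failed too.
    design
        sample design table (one cell line per model).
    probe_annot
        probe annotation indexed by probe_id with ``gene_id`` (nullable)
        and ``location_class`` columns.
    """

    def __init__(
        self,
        mcg: pd.DataFrame,
        cg: pd.DataFrame,
        failed: pd.DataFrame | None,
        design: pd.DataFrame,
        probe_annot: pd.DataFrame | None = None,
        *,
        baseline_day: int = 0,
    ) -> None:
        if not mcg.index.equals(cg.index) or not mcg.columns.equals(cg.columns):
            raise ValueError("mcg and cg matrices must be aligned")
        self.mcg = mcg
        self.cg = cg
        if failed is None:
            failed = pd.DataFrame(False, index=mcg.index, columns=mcg.columns)
        self.failed = failed.astype(bool)
        self.design = design.reset_index(drop=True)
        self.probe_annot = probe_annot
        self.baseline_day = baseline_day

    @classmethod
    def from_study(cls, study, **kwargs) -> "MethylationModel":
        return cls(
            study.mcg, study.cg, study.failed, study.design, study.probe_annot, **kwargs
        )

    def _groups(self) -> dict[int, list[str]]:
        return {
            int(day): sub["sample_id"].tolist()
            for day, sub in self.design.groupby("day", sort=True)
        }

    # -- QC / imputation ---------------------------------------------------

    def preprocess(self) -> BetaMatrix:
        """Compute beta, run block QC and imputation; returns the QC'd matrix."""
        beta_raw = pd.DataFrame(
            compute_beta(self.mcg.to_numpy(), self.cg.to_numpy()),
            index=self.mcg.index,
            columns=self.mcg.columns,
        )
        probes = beta_raw.index
        columns = beta_raw.columns
        col_idx = {c: j for j, c in enumerate(columns)}
        groups = self._groups()
        days_sorted = sorted(groups)
        n_probes, n_cols = beta_raw.shape
        b = beta_raw.to_numpy()
        failed = self.failed.to_numpy() | ~np.isfinite(b)

        # array-wide residual fence: residuals around block means, pooled
        # over all blocks with >= 2 readable replicates
        pooled: list[np.ndarray] = []
        for day in days_sorted:
            ix = [col_idx[c] for c in groups[day]]
            vals = np.where(failed[:, ix], np.nan, b[:, ix])
            nvalid = np.isfinite(vals).sum(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                bmean = np.nanmean(vals, axis=1)
            res = vals - bmean[:, None]
            res[nvalid < 2, :] = np.nan
            pooled.append(res.ravel())
        try:
            fence = pooled_residual_fence(np.concatenate(pooled))
        except ValueError:
            fence = None

        status_arr = np.empty((n_probes, len(days_sorted)), dtype=object)
        surv_arr = np.zeros((n_probes, n_cols), dtype=bool)
        qc: dict[tuple[int, int], BlockQC] = {}
        for gi, day in enumerate(days_sorted):
            ix = np.array([col_idx[c] for c in groups[day]])
            for i in range(n_probes):
                verdict = qc_filter(b[i, ix], failed[i, ix], fence=fence)
                qc[(i, day)] = verdict
                status_arr[i, gi] = verdict.status
                surv_arr[i, ix] = verdict.surviving
        status = pd.DataFrame(status_arr, index=probes, columns=days_sorted)

        # correlation of cell x time group mean profiles over clean probes
        clean = (status == KEEP).all(axis=1).to_numpy()
        corr = np.eye(len(days_sorted))
        if clean.sum() >= 2:
            profiles = np.column_stack(
                [
                    b[np.ix_(clean, [col_idx[c] for c in groups[d]])].mean(axis=1)
                    for d in days_sorted
                ]
            )
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(profiles, rowvar=False)
            corr = np.where(np.isfinite(c), c, 0.0)
        corr_df = pd.DataFrame(corr, index=days_sorted, columns=days_sorted)

        rep_col = {
            (int(r["day"]), int(r["replicate"])): col_idx[r["sample_id"]]
            for _, r in self.design.iterrows()
        }
        reps_by_day = {
            d: sorted(
                int(r) for r in self.design.loc[self.design["day"] == d, "replicate"]
            )
            for d in days_sorted
        }

        beta_post = np.where(surv_arr, b, np.nan)
        prov = np.where(surv_arr, "observed", "discarded").astype(object)

        n_imputed = 0
        day_pos = {d: gi for gi, d in enumerate(days_sorted)}
        for gi, day in enumerate(days_sorted):
            ix = np.array([col_idx[c] for c in groups[day]])
            for i in np.flatnonzero(status_arr[:, gi] == IMPUTE):
                verdict = qc[(i, day)]
                missing_pos = int(np.flatnonzero(~verdict.surviving)[0])
                missing_rep = reps_by_day[day][missing_pos]
                survivors = b[i, ix][verdict.surviving]
                if survivors.size != 2:  # only 3-replicate blocks are imputed
                    continue
                context: list[tuple[float, float]] = []
                for other in days_sorted:
                    if other == day or status_arr[i, day_pos[other]] == DISCARD:
                        continue
                    rho = float(corr_df.loc[day, other])
                    j = rep_col.get((other, missing_rep))
                    if j is not None and surv_arr[i, j]:
                        other_ix = np.array([col_idx[c] for c in groups[other]])
                        other_surv = b[i, other_ix][qc[(i, other)].surviving]
                        resid = float(b[i, j] - other_surv.mean())
                    else:
                        resid = 0.0  # survivors' mean residual is zero
                    context.append((rho, resid))
                value = impute_third(survivors, context)
                j = rep_col[(day, missing_rep)]
                beta_post[i, j] = value
                prov[i, j] = "imputed"
                n_imputed += 1

        summary = QCSummary(
            n_blocks=n_probes * len(days_sorted),
            n_keep=int((status_arr == KEEP).sum()),
            n_imputed=n_imputed,
            n_discarded=int((status_arr == DISCARD).sum()),
            fence=fence,
        )
        return BetaMatrix(
            beta=pd.DataFrame(beta_post, index=probes, columns=columns),
            provenance=pd.DataFrame(prov, index=probes, columns=columns),
            status=status,
            correlation=corr_df,
            qc_summary=summary,
            design=self.design,
        )

    # -- DML calling -------------------------------------------------------

    def fit(self, alpha: float = 0.05, alpha_posthoc: float = 0.05) -> "DMLResults":
        bm = self.preprocess()
        groups = self._groups()
        days_sorted = sorted(groups)
        baseline = self.baseline_day
        if baseline not in groups:
            raise ValueError(f"baseline day {baseline} missing")
        other_days = [d for d in days_sorted if d != baseline]

        status = bm.status
        beta = bm.beta
        group_ok = status != DISCARD
        usable = group_ok[baseline] & (group_ok.sum(axis=1) >= 2)
        bm.qc_summary.excluded_probes = beta.index[~usable].tolist()

        x = beta.loc[usable]
        imputed_mask = (bm.provenance == "imputed").loc[usable]
        p_series, deltas, posthoc_p = self._anova_posthoc(
            x, groups, group_ok.loc[usable], baseline, other_days, imputed_mask
        )
        p_adj = bh_adjust(p_series)

        table = pd.DataFrame({"p": p_series, "p_adj": p_adj})
        any_day = np.zeros(len(table), dtype=bool)
        for d in other_days:
            pday = posthoc_p[d]
            delta = deltas[d]
            sig = (pday < alpha_posthoc).fillna(False).to_numpy()
            direction = np.where(
                sig & (delta.to_numpy() > 0),
                "hyper",
                np.where(sig & (delta.to_numpy() < 0), "hypo", "none"),
            )
            table[f"p_day{d}"] = pday
            table[f"delta_day{d}"] = delta
            table[f"dir_day{d}"] = direction
            any_day |= sig
        table["is_dml"] = (table["p_adj"] <= alpha) & any_day
        if self.probe_annot is not None:
            annot = self.probe_annot.reindex(table.index)
            table["gene_id"] = annot["gene_id"]
            table["location_class"] = annot["location_class"]
        return DMLResults(
            table=table,
            beta=bm,
            days=other_days,
            alpha=alpha,
            alpha_posthoc=alpha_posthoc,
            model=self,
        )

    @staticmethod
    def _anova_posthoc(beta, groups, group_ok, baseline, other_days, imputed=None):
        """Vectorised NaN-aware one-way ANOVA + per-day t tests vs baseline.

        Imputed cells contribute to group means (and delta %mCG) but carry
        no information about the residual error, so each one removes a
        denominator degree of freedom (the classic missing-plot df
        correction); without this the substituted values shrink the error
        estimate and inflate F.
        """
        probes = beta.index
        day_vals = {}
        day_imp = {}
        for d, cols in groups.items():
            v = beta[cols].to_numpy(dtype=float).copy()
            v[~group_ok[d].to_numpy(), :] = np.nan
            day_vals[d] = v
            if imputed is not None:
                day_imp[d] = (
                    imputed[cols].to_numpy(dtype=bool) & np.isfinite(v)
                ).sum(axis=1).astype(float)
            else:
                day_imp[d] = np.zeros(len(probes))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = {d: np.nanmean(v, axis=1) for d, v in day_vals.items()}
        counts = {
            d: np.isfinite(v).sum(axis=1).astype(float) for d, v in day_vals.items()
        }
        n_tot = sum(counts.values())
        all_vals = np.concatenate([day_vals[d] for d in sorted(groups)], axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            grand = np.nanmean(all_vals, axis=1)
        sst = np.nansum((all_vals - grand[:, None]) ** 2, axis=1)
        sse = np.zeros(len(probes))
        ssb = np.zeros(len(probes))
        t_groups = np.zeros(len(probes))
        for d, v in day_vals.items():
            present = counts[d] > 0
            mean_d = np.where(present, means[d], 0.0)
            dev = v - mean_d[:, None]
            sse += np.where(present, np.nansum(dev**2, axis=1), 0.0)
            ssb += np.where(present, counts[d] * (mean_d - grand) ** 2, 0.0)
            t_groups += present
        n_imp_tot = sum(day_imp.values())
        dfn = t_groups - 1
        dfd = np.maximum(n_tot - t_groups - n_imp_tot, 1.0)
        p = np.ones(len(probes))
        scale = np.maximum(sst, 1.0)
        degenerate = sst <= _TOL * scale
        zero_sse = (~degenerate) & (sse <= _TOL * scale)
        ok = (~degenerate) & (~zero_sse) & (dfd > 0) & (dfn > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb[ok] / dfn[ok]) / (sse[ok] / dfd[ok])
        p[ok] = stats.f.sf(f, dfn[ok], dfd[ok])
        p[zero_sse] = 0.0
        p_series = pd.Series(p, index=probes, name="p")

        deltas: dict[int, pd.Series] = {}
        posthoc_p: dict[int, pd.Series] = {}
        v0 = day_vals[baseline]
        m0, n0 = means[baseline], counts[baseline]
        ss0 = np.nansum((v0 - m0[:, None]) ** 2, axis=1)
        for d in other_days:
            vd = day_vals[d]
            md, nd = means[d], counts[d]
            ssd = np.nansum((vd - md[:, None]) ** 2, axis=1)
            present = nd > 0
            df = np.maximum(n0 + nd - 2 - day_imp[baseline] - day_imp[d], 1.0)
            diff = md - m0
            with np.errstate(divide="ignore", invalid="ignore"):
                sp2 = (ss0 + ssd) / df
                tstat = diff / np.sqrt(sp2 * (1.0 / n0 + 1.0 / nd))
            pt = np.full(len(probes), np.nan)
            msc = np.maximum(np.abs(m0) + np.abs(md), 1.0) ** 2
            ok = present & (df > 0) & (sp2 > _TOL * msc)
            pt[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df[ok])
            degen = present & (df > 0) & ~ok
            pt[degen] = np.where(np.abs(diff[degen]) <= _TOL, 1.0, 0.0)
            deltas[d] = pd.Series(np.where(present, diff, np.nan), index=probes)
            posthoc_p[d] = pd.Series(pt, index=probes)
        return p_series, deltas, posthoc_p


@dataclass
class DMLResults:
    """Fitted DML results: one row per analysable probe."""

    table: pd.DataFrame
    beta: BetaMatrix
    days: list[int]
    alpha: float
    alpha_posthoc: float
    model: MethylationModel

    @property
    def n_dml(self) -> int:
        return int(self.table["is_dml"].sum())

    def dml_ids(self, day: int | None = None) -> pd.Index:
        t = self.table
        if day is None:
            return t.index[t["is_dml"]]
        sig = t[f"p_day{day}"] < self.alpha_posthoc
        return t.index[t["is_dml"] & sig.fillna(False)]

    def day_counts(self) -> pd.DataFrame:
        rows = []
        for d in self.days:
            ids = self.dml_ids(d)
            dirs = self.table.loc[ids, f"dir_day{d}"]
            rows.append(
                {
                    "day": d,
                    "n_dml": len(ids),
                    "hyper": int((dirs == "hyper").sum()),
                    "hypo": int((dirs == "hypo").sum()),
                }
            )
        return pd.DataFrame(rows).set_index("day")

    def location_class_counts(self) -> pd.DataFrame:
        """Per-day DML counts stratified by probe location class."""
        if "location_class" not in self.table.columns:
            raise ValueError("model was built without probe annotation")
        rows = {}
        for d in self.days:
            ids = self.dml_ids(d)
            rows[d] = self.table.loc[ids, "location_class"].value_counts()
        return pd.DataFrame(rows).fillna(0).astype(int)

    def evaluate(self, truth: pd.DataFrame) -> dict[str, float]:
        from .evaluate import confusion

        truth_any = (truth != 0).any(axis=1).reindex(self.table.index, fill_value=False)
        return confusion(self.table["is_dml"], truth_any)

    def summary(self) -> str:
        qc = self.beta.qc_summary
        lines = [
            "Differential methylation (post-QC time-course ANOVA)",
            "=" * 54,
            f"probes analysed: {len(self.table)} "
            f"(excluded by QC: {len(qc.excluded_probes)})",
            f"blocks: {qc.n_blocks}  kept: {qc.n_keep}  imputed: {qc.n_imputed}"
            f"  discarded: {qc.n_discarded}",
            f"alpha (BH) <= {self.alpha}   post hoc p < {self.alpha_posthoc}",
            f"DMLs (any day): {self.n_dml}",
            "",
            self.day_counts().to_string(),
        ]
        return "\n".join(lines)
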