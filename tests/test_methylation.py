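"""Beta computation, block QC, imputation and DML calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triomic import (
    MethylationModel,
    compute_beta,
    generate_methylation,
    impute_third,
    qc_filter,
)
from triomic.methylation import DISCARD, IMPUTE, KEEP, block_fence


class TestBeta:
    @pytest.mark.parametrize(
        "mcg,cg,expected",
        [(75, 25, 75.0), (0, 10, 0.0), (10, 0, 100.0), (1, 3, 25.0)],
    )
    def test_exact_fractions(self, mcg, cg, expected):
        assert compute_beta(mcg, cg) == expected

    def test_zero_total_is_undefined(self):
        assert np.isnan(compute_beta(0.0, 0.0))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(-1.0, 5.0)

    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_bounds(self, mcg, cg):
        b = compute_beta(mcg, cg)
        assert 0.0 <= b <= 100.0


class TestQCFilter:
    def test_clean_block_keeps_all(self):
        verdict = qc_filter(np.array([50.0, 51.0, 49.0]))
        assert verdict.status == KEEP
        assert verdict.surviving.all()

    def test_two_failed_reads_discard(self):
        verdict = qc_filter(
            np.array([50.0, 51.0, 49.0]), np.array([True, True, False])
        )
        assert verdict.status == DISCARD
        assert not verdict.surviving.any()

    def test_lone_block_outlier_flagged(self):
        # residuals around the block mean 63.67: {-13.67, -12.67, +26.33};
        # the lone-block fence is median(res) +/- 1.5*IQR with interpolated
        # quartiles: IQR = 20, fence [-42.67, 17.33], so +26.33 is out
        block = np.array([50.0, 51.0, 90.0])
        res = block - block.mean()
        assert res == pytest.approx([-13.667, -12.667, 26.333], abs=1e-3)
        lo, hi = block_fence(block)
        assert (lo, hi) == (pytest.approx(-42.667, abs=1e-3), pytest.approx(17.333, abs=1e-3))
        verdict = qc_filter(block)
        assert verdict.status == IMPUTE
        assert verdict.outlier.tolist() == [False, False, True]

    def test_single_failed_read_needs_imputation(self):
        verdict = qc_filter(
            np.array([50.0, 51.0, 49.0]), np.array([False, True, False])
        )
        assert verdict.status == IMPUTE
        assert verdict.surviving.sum() == 2

    def test_nan_beta_counts_as_failed(self):
        verdict = qc_filter(np.array([50.0, np.nan, np.nan]))
        assert verdict.status == DISCARD

    def test_idempotent_on_kept_blocks(self):
        block = np.array([40.0, 42.0, 44.0])
        first = qc_filter(block)
        assert first.status == KEEP
        second = qc_filter(block[first.surviving])
        assert second.surviving.all()

    def test_array_fence_overrides_block_fence(self):
        # with a wide array-wide fence the 90 replicate is tolerated
        verdict = qc_filter(np.array([50.0, 51.0, 90.0]), fence=(-50.0, 50.0))
        assert verdict.status == KEEP

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            qc_filter(np.array([]))


class TestImputation:
    def test_zero_context_residuals_give_survivor_mean(self):
        assert impute_third([40.0, 44.0], [(0.9, 0.0), (0.8, 0.0)]) == 42.0
        assert impute_third([40.0, 44.0], None) == 42.0

    def test_single_perfectly_correlated_group(self):
        assert impute_third([40.0, 44.0], [(1.0, 4.0)]) == 46.0

    def test_result_clipped_to_beta_range(self):
        assert impute_third([99.0, 99.5], [(1.0, 50.0)]) == 100.0
        assert impute_third([0.5, 1.0], [(1.0, -50.0)]) == 0.0

    def test_requires_exactly_two_survivors(self):
        with pytest.raises(ValueError):
            impute_third([40.0, 42.0, 44.0])

    def test_noop_on_complete_tight_data(self):
        # one probe, tight replicate blocks: QC keeps everything and the
        # post-QC matrix equals the raw beta matrix cell for cell
        from triomic import make_design

        design = make_design(days=(0, 3, 6, 9), n_reps=3)
        beta = np.array([[40.0, 42.0, 44.0, 41.0, 42.0, 43.0,
                          50.0, 51.0, 52.0, 45.0, 46.0, 47.0]])
        total = 2000.0
        mcg = pd.DataFrame(
            total * beta / 100.0, index=["cg1"],
            columns=design["sample_id"].tolist(),
        )
        cg = total - mcg
        bm = MethylationModel(mcg, cg, None, design).preprocess()
        assert (bm.provenance == "observed").all().all()
        assert np.allclose(bm.beta.to_numpy(), beta)

    def test_observed_cells_unchanged_on_clean_array(self):
        study = generate_methylation(
            n_probes=80, frac_dml=0.0, fail_rate=0.0, outlier_rate=0.0,
            noise_sd=0.5, seed=12,
        )
        bm = MethylationModel.from_study(study).preprocess()
        assert bm.qc_summary.n_discarded == 0
        raw = compute_beta(study.mcg.to_numpy(), study.cg.to_numpy())
        observed = (bm.provenance == "observed").to_numpy()
        assert np.allclose(bm.beta.to_numpy()[observed], raw[observed])

    def test_masked_at_random_imputation_unbiased(self):
        # mask one replicate in ~300 random blocks; imputed values should be
        # mean-unbiased for the masked truth within Monte-Carlo error
        study = generate_methylation(
            n_probes=400, frac_dml=0.0, fail_rate=0.0, outlier_rate=0.0,
            noise_sd=2.0, seed=13,
        )
        rng = np.random.default_rng(99)
        failed = study.failed.copy()
        true_beta = pd.DataFrame(
            compute_beta(study.mcg.to_numpy(), study.cg.to_numpy()),
            index=study.mcg.index, columns=study.mcg.columns,
        )
        days = sorted(study.design["day"].unique())
        masked = []
        probe_rows = rng.choice(len(failed), size=300, replace=False)
        for i in probe_rows:
            day = days[rng.integers(len(days))]
            cols = study.design.loc[study.design.day == day, "sample_id"].tolist()
            col = cols[rng.integers(len(cols))]
            failed.iloc[i, failed.columns.get_loc(col)] = True
            masked.append((failed.index[i], col))
        model = MethylationModel(
            study.mcg, study.cg, failed, study.design, study.probe_annot
        )
        bm = model.preprocess()
        errors = []
        for probe, col in masked:
            if bm.provenance.loc[probe, col] == "imputed":
                errors.append(bm.beta.loc[probe, col] - true_beta.loc[probe, col])
        errors = np.array(errors)
        assert len(errors) > 200
        se = errors.std(ddof=1) / np.sqrt(len(errors))
        assert abs(errors.mean()) < 4 * se + 0.05

    def test_beta_bounds_preserved_through_qc(self, meth_results):
        vals = meth_results.beta.beta.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= 0.0 and finite.max() <= 100.0


class TestDMLCalling:
    def test_planted_recovery(self, meth_study, meth_results):
        ev = meth_results.evaluate(meth_study.truth)
        assert ev["sensitivity"] >= 0.9
        assert ev["fdr"] <= 0.10

    def test_signed_delta_recovered_on_average(self, meth_study, meth_results):
        truth_any = meth_study.truth_any().reindex(
            meth_results.table.index, fill_value=False
        )
        tp = meth_results.table.index[meth_results.table["is_dml"] & truth_any]
        err = (
            meth_results.table.loc[tp, "delta_day6"]
            - meth_study.truth.loc[tp, 6]
        ).abs()
        assert err.mean() <= 2.0

    def test_null_simulation_controls_discoveries(self):
        study = generate_methylation(frac_dml=0.0, seed=2)
        res = MethylationModel.from_study(study).fit()
        se = np.sqrt(0.05 * 0.95 / len(res.table))
        assert res.table["is_dml"].mean() <= 0.05 + 3 * se

    def test_constant_probe_not_called(self):
        study = generate_methylation(
            n_probes=30, frac_dml=0.0, fail_rate=0.0, outlier_rate=0.0,
            noise_sd=1.0, seed=3,
        )
        # overwrite one probe to a constant beta of 50 at total intensity 2000
        study.mcg.iloc[0, :] = 1000.0
        study.cg.iloc[0, :] = 1000.0
        res = MethylationModel.from_study(study).fit()
        probe = study.mcg.index[0]
        row = res.table.loc[probe]
        assert row["p"] == 1.0
        assert not row["is_dml"]
        assert row["delta_day6"] == 0.0
        assert row["dir_day6"] == "none"

    def test_direction_partition(self, meth_results):
        t = meth_results.table
        for d in meth_results.days:
            sig = t["is_dml"] & (t[f"p_day{d}"] < 0.05).fillna(False)
            dirs = t.loc[sig, f"dir_day{d}"]
            assert set(dirs.unique()) <= {"hyper", "hypo"}

    def test_baseline_discard_excludes_probe(self):
        study = generate_methylation(
            n_probes=30, frac_dml=0.0, fail_rate=0.0, outlier_rate=0.0,
            noise_sd=1.0, seed=7,
        )
        failed = study.failed.copy()
        day0 = study.design.loc[study.design.day == 0, "sample_id"].tolist()
        failed.loc[failed.index[0], day0[:2]] = True  # >1 failed at baseline
        res = MethylationModel(
            study.mcg, study.cg, failed, study.design, study.probe_annot
        ).fit()
        assert failed.index[0] not in res.table.index
        assert failed.index[0] in res.beta.qc_summary.excluded_probes
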