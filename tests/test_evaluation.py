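"""Metrics, splits, protocols, noise ceiling and outlier enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probass import (
    MutationRecord,
    MutationSpec,
    SplitSpec,
    cross_pdb_split,
    learning_curve,
    leave_one_pdb_out_split,
    noise_ceiling,
    outlier_enrichment,
    pearson,
    random_within_split,
    rmse,
    run_protocol,
    spearman,
)
from probass.evaluation import binomial_tail, write_scatter_csv


def _pearson_oracle(a, b):
    # direct product-moment formula, independent of the implementation path
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


def _rank_oracle(x):
    # average ranks for ties via double argsort bookkeeping
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def simple_records(pdb_counts):
    records = []
    muts = iter(
        MutationSpec("A", str(pos), wt, mut)
        for pos in range(1, 10_000)
        for wt, mut in [("K", "A")]
    )
    for pdb, count in pdb_counts.items():
        for _ in range(count):
            records.append(MutationRecord(pdb, (next(muts),), 1.0))
    return records


class TestMetrics:
    def test_rmse_examples(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))
        assert rmse([2.0], [5.0]) == 3.0

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0])

    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(2 * x + 1, x) == pytest.approx(1.0)
        assert pearson(-2 * x, x) == pytest.approx(-1.0)
        assert spearman(np.exp(x), x) == pytest.approx(1.0)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=37)
            b = rng.normal(size=37) + 0.5 * a
            assert abs(pearson(a, b) - _pearson_oracle(a, b)) < 1e-12
            assert abs(
                spearman(a, b) - _pearson_oracle(_rank_oracle(a), _rank_oracle(b))
            ) < 1e-12

    @settings(deadline=None, max_examples=30)
    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 10),
    )
    def test_invariance_under_increasing_affine_maps(self, shift, scale):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=25), rng.normal(size=25)
        assert pearson(scale * a + shift, b) == pytest.approx(pearson(a, b), abs=1e-9)
        assert spearman(np.exp(scale * a + shift), b) == pytest.approx(
            spearman(a, b), abs=1e-12
        )


class TestSplits:
    def test_random_within_sizes(self):
        records = simple_records({"3OTJ": 100})
        split = random_within_split(records, 0.8, seed=0)
        assert len(split.train_ids) == 80 and len(split.test_ids) == 20
        small = random_within_split(simple_records({"3OTJ": 10}), 0.8, seed=0)
        assert len(small.train_ids) == 8 and len(small.test_ids) == 2

    def test_random_within_deterministic(self):
        records = simple_records({"3OTJ": 50})
        a = random_within_split(records, seed=3)
        b = random_within_split(records, seed=3)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_random_within_too_few(self):
        with pytest.raises(ValueError, match="at least 5"):
            random_within_split(simple_records({"X": 4}))

    def test_leave_one_pdb_out_counts_and_leakage(self):
        records = simple_records({"1AAA": 5, "2BBB": 6, "3CCC": 7})
        split = leave_one_pdb_out_split(records, "3CCC")
        assert len(split.train_ids) == 11 and len(split.test_ids) == 7
        train_pdbs = {records[i].pdb_id for i in split.train_ids}
        assert "3CCC" not in train_pdbs

    def test_leave_one_pdb_out_unknown(self):
        with pytest.raises(ValueError, match="9ZZZ"):
            leave_one_pdb_out_split(simple_records({"1AAA": 5}), "9ZZZ")

    def test_cross_pdb(self):
        records = simple_records({"1AAA": 5, "2BBB": 6})
        split = cross_pdb_split(records, "1AAA", "2BBB")
        assert len(split.train_ids) == 5 and len(split.test_ids) == 6
        with pytest.raises(ValueError):
            cross_pdb_split(records, "1AAA", "1AAA")

    def test_split_spec_invariants(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitSpec("random_within", (0, 1), (1, 2))
        with pytest.raises(ValueError, match="empty"):
            SplitSpec("random_within", (0, 1), ())


class TestRunProtocol:
    def test_repeat_count_and_determinism(self, small_fixture, fast_params):
        fx = small_fixture
        args = dict(mode="random_within", repeats=3, seeds=[101, 102, 103],
                    params=fast_params)
        a = run_protocol(fx.records, fx.dataset.X, fx.dataset.y, **args)
        b = run_protocol(fx.records, fx.dataset.X, fx.dataset.y, **args)
        assert len(a.per_repeat) == 3
        assert a.to_dict() == b.to_dict()
        assert a.sd_r >= 0 and -1 <= a.mean_r <= 1

    def test_failing_repeat_names_its_index(self, small_fixture, fast_params):
        fx = small_fixture
        with pytest.raises(RuntimeError, match="repeat 0"):
            run_protocol(fx.records, fx.dataset.X, fx.dataset.y,
                         mode="cross_pdb", repeats=1, params=fast_params)

    def test_misaligned_inputs_rejected(self, small_fixture):
        fx = small_fixture
        with pytest.raises(ValueError, match="aligned"):
            run_protocol(fx.records[:-1], fx.dataset.X, fx.dataset.y)

    def test_scatter_csv(self, small_fixture, fast_params, tmp_path):
        fx = small_fixture
        report = run_protocol(fx.records, fx.dataset.X, fx.dataset.y,
                              repeats=1, params=fast_params)
        out = tmp_path / "scatter.csv"
        write_scatter_csv(report, out)
        import pandas as pd
        df = pd.read_csv(out)
        assert set(df.columns) >= {"exp", "pred", "residual", "outlier"}
        assert len(df) == report.n_test


class TestLearningCurve:
    def test_shape_fixed_test_half_and_nesting(self, small_fixture, fast_params):
        fx = small_fixture
        points = learning_curve(fx.records, fx.dataset.X, fx.dataset.y,
                                seed=5, params=fast_params)
        fractions = [f for f, _ in points]
        assert len(points) == 10
        assert fractions == pytest.approx([0.05 * (i + 1) for i in range(10)])
        test_sets = [tuple(rep.params["test_ids"]) for _, rep in points]
        assert len(set(test_sets)) == 1  # frozen test half
        train_sets = [rep.params["train_ids"] for _, rep in points]
        for smaller, larger in zip(train_sets, train_sets[1:]):
            assert set(smaller) <= set(larger)  # nested
            assert len(smaller) < len(larger)

    def test_too_few_records(self, fast_params):
        records = simple_records({"1AAA": 30})
        X = np.random.default_rng(0).normal(size=(30, 4))
        y = X[:, 0]
        with pytest.raises(ValueError, match="fraction"):
            learning_curve(records, X, y, fraction_step=0.05, max_fraction=0.5,
                           params=fast_params)


class TestNoiseCeiling:
    def test_zero_errors_give_r_of_one(self, rng):
        values = rng.normal(size=100)
        result = noise_ceiling(values, 0.0, n_sim=20, seed=0)
        np.testing.assert_allclose(result.r_values, 1.0, atol=1e-12)

    def test_homoscedastic_attenuation_closed_form(self, rng):
        # r ≈ σ_s / sqrt(σ_s² + σ_n²) for homoscedastic noise
        values = rng.normal(scale=2.0, size=2000)
        sigma_n = 1.0
        expected = values.std() / np.sqrt(values.std() ** 2 + sigma_n**2)
        result = noise_ceiling(values, sigma_n, n_sim=500, seed=1)
        assert result.mean_r == pytest.approx(expected, abs=0.01)

    def test_mean_r_non_increasing_in_error_scale(self, rng):
        values = rng.normal(size=300)
        errors = np.abs(rng.normal(scale=0.5, size=300))
        base = noise_ceiling(values, errors, n_sim=500, seed=2).mean_r
        scaled = noise_ceiling(values, 1.5 * errors, n_sim=500, seed=2).mean_r
        assert scaled <= base

    def test_reproducible(self, rng):
        values = rng.normal(size=50)
        a = noise_ceiling(values, 0.3, n_sim=100, seed=7)
        b = noise_ceiling(values, 0.3, n_sim=100, seed=7)
        assert a.mean_r == b.mean_r

    def test_negative_error_rejected(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            noise_ceiling(rng.normal(size=10), -0.1)


def enrichment_records(letters):
    return [
        MutationRecord("1AAA", (MutationSpec("A", str(i + 1), "G" if l != "G" else "A", l),), 1.0)
        for i, l in enumerate(letters)
    ]


class TestOutlierEnrichment:
    def test_single_far_point_flagged(self, rng):
        n = 50
        exp = rng.normal(size=n)
        resid = rng.normal(scale=0.1, size=n)
        resid[17] = 1.5  # many residual SDs off the line
        pred = 1.3 * exp + 0.2 + resid
        records = enrichment_records(["L"] * n)
        report = outlier_enrichment(pred, exp, records, threshold_sd=3.0)
        assert report.outlier_indices.tolist() == [17]
        assert report.directions == ["over_destabilizing"]

    def test_below_line_is_over_stabilizing(self, rng):
        n = 50
        exp = rng.normal(size=n)
        resid = rng.normal(scale=0.1, size=n)
        resid[5] = -1.5
        pred = exp + resid
        report = outlier_enrichment(pred, exp, enrichment_records(["L"] * n),
                                    threshold_sd=3.0)
        assert report.directions == ["over_stabilizing"]

    def test_exact_binomial_tail(self):
        # k=8 of n=10 outliers in a class with background frequency 0.3:
        # sum_{k=8}^{10} C(10,k) 0.3^k 0.7^(10-k), frozen from direct enumeration
        from math import comb
        exact = sum(comb(10, k) * 0.3**k * 0.7 ** (10 - k) for k in range(8, 11))
        assert binomial_tail(8, 10, 0.3, "enriched") == pytest.approx(exact, abs=1e-12)
        assert exact == pytest.approx(1.5903864e-3, abs=1e-9)

    def test_huge_threshold_gives_empty_report(self, rng):
        exp = rng.normal(size=30)
        pred = exp + rng.normal(scale=0.1, size=30)
        report = outlier_enrichment(pred, exp, enrichment_records(["L"] * 30),
                                    threshold_sd=100.0)
        assert len(report.outlier_indices) == 0
        assert report.class_tests == []

    def test_enrichment_direction_and_background(self, rng):
        # hydrophobic mutations made deliberately over-destabilizing
        n = 60
        letters = ["L"] * 20 + ["D"] * 40
        exp = rng.normal(size=n)
        resid = rng.normal(scale=0.05, size=n)
        resid[:8] = 1.0  # eight hydrophobic records far above the line
        pred = exp + resid
        report = outlier_enrichment(pred, exp, enrichment_records(letters),
                                    threshold_sd=2.0)
        tests = {(t.direction, t.residue_class): t for t in report.class_tests}
        t = tests[("over_destabilizing", "hydrophobic")]
        assert t.status == "enriched"
        assert t.background_p == pytest.approx(20 / 60)
        assert t.p_value < 0.01

    def test_degenerate_regression_rejected(self):
        records = enrichment_records(["L"] * 10)
        with pytest.raises(ValueError, match="degenerate"):
            outlier_enrichment(np.arange(10.0), np.ones(10), records)

    def test_holm_adjustment_is_conservative(self, rng):
        n = 60
        letters = (["L"] * 20 + ["D"] * 20 + ["P"] * 20)
        exp = rng.normal(size=n)
        resid = rng.normal(scale=0.05, size=n)
        resid[:6] = 1.0
        pred = exp + resid
        report = outlier_enrichment(pred, exp, enrichment_records(letters),
                                    threshold_sd=2.0, holm=True)
        for t in report.class_tests:
            assert t.p_adjusted is not None and t.p_adjusted >= t.p_value
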