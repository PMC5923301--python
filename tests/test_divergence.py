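"""Pairwise divergence: empirical null, outlier flagging, correlations, OLS band."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import venomcomp as vc
from venomcomp.datatypes import ClrMatrix


def _rows(*arrays, cols=None):
    arrs = [np.asarray(a, float) for a in arrays]
    cols = cols or [f"T-{j}" for j in range(len(arrs[0]))]
    return [pd.Series(a, index=cols) for a in arrs]


def _percentile_oracle(values, q):
    """Linear-interpolation percentile between order statistics, by hand."""
    d = np.sort(np.asarray(values, float))
    h = (len(d) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return d[lo] + (h - lo) * (d[hi] - d[lo])


def _spearman_oracle(x, y):
    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    return _pearson_oracle(avg_ranks(x), avg_ranks(y))


def _pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestNullThreshold:
    def test_identical_rows_give_zero(self):
        r1, r2 = _rows([1.0, -1.0, 0.0], [1.0, -1.0, 0.0])
        assert vc.null_threshold(r1, r2, ["T-0", "T-1", "T-2"]) == 0.0

    def test_hundred_point_grid_interpolates(self):
        diffs = np.arange(0, 10, 0.1)  # |delta| values 0.0 .. 9.9
        r1, r2 = _rows(diffs, np.zeros(100))
        thr = vc.null_threshold(r1, r2, list(r1.index), percentile=99)
        assert thr == pytest.approx(9.801, abs=1e-12)
        assert thr == pytest.approx(_percentile_oracle(diffs, 99))

    def test_symmetric_in_pair_order(self, rng):
        r1, r2 = _rows(rng.normal(size=50), rng.normal(size=50))
        ids = list(r1.index)
        assert vc.null_threshold(r1, r2, ids) == vc.null_threshold(r2, r1, ids)

    def test_matches_interpolation_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(5, 200)
            a, b = rng.normal(size=n), rng.normal(size=n)
            q = float(rng.uniform(50, 99.9))
            r1, r2 = _rows(a, b)
            ours = vc.null_threshold(r1, r2, list(r1.index), percentile=q)
            assert ours == pytest.approx(_percentile_oracle(np.abs(a - b), q), rel=1e-12)

    def test_too_few_nontoxins_rejected(self):
        r1, r2 = _rows([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="at least 2"):
            vc.null_threshold(r1, r2, ["T-0"])

    def test_mismatched_universes_rejected(self):
        r1 = pd.Series([1.0, 2.0], index=["a", "b"])
        r2 = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValueError, match="universe"):
            vc.null_threshold(r1, r2, ["a"])


class TestFlagOutliers:
    def test_no_divergence_flags_nothing(self):
        r1, r2 = _rows([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = vc.flag_outliers(r1, r2, list(r1.index), threshold=0.5)
        assert out.empty

    def test_tie_at_threshold_not_flagged(self):
        r1, r2 = _rows([2.0, 0.0], [0.0, 0.0])
        out = vc.flag_outliers(r1, r2, ["T-0"], threshold=2.0)
        assert out.empty
        out = vc.flag_outliers(r1, r2, ["T-0"], threshold=1.999)
        assert list(out.index) == ["T-0"]
        assert out.at["T-0", "direction"] == "up_in_i"

    def test_spiked_toxin_is_the_only_flag(self, rng):
        noise = rng.normal(0, 0.1, size=200)
        base = rng.normal(0, 1, size=200)
        a = np.r_[base + noise, 0.0]
        b = np.r_[base, -8.0]
        cols = [f"NT-{i}" for i in range(200)] + ["TOX-1"]
        r1, r2 = _rows(a, b, cols=cols)
        thr = vc.null_threshold(r1, r2, cols[:-1])
        out = vc.flag_outliers(r1, r2, ["TOX-1"], thr)
        assert list(out.index) == ["TOX-1"]
        assert out.at["TOX-1", "direction"] == "up_in_i"

    def test_swapping_pair_negates_deltas_and_directions(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        r1, r2 = _rows(a, b)
        ids = list(r1.index)
        f12 = vc.flag_outliers(r1, r2, ids, 0.8)
        f21 = vc.flag_outliers(r2, r1, ids, 0.8)
        assert set(f12.index) == set(f21.index)
        for t in f12.index:
            assert f12.at[t, "delta_clr"] == pytest.approx(-f21.at[t, "delta_clr"])
            assert f12.at[t, "direction"] != f21.at[t, "direction"]

    def test_larger_threshold_only_shrinks_outlier_set(self, rng):
        a, b = rng.normal(size=60), rng.normal(size=60)
        r1, r2 = _rows(a, b)
        ids = list(r1.index)
        small = set(vc.flag_outliers(r1, r2, ids, 0.5).index)
        large = set(vc.flag_outliers(r1, r2, ids, 1.5).index)
        assert large <= small


class TestPairCorrelations:
    def test_identical_rows(self, rng):
        a = rng.normal(size=20)
        r1, r2 = _rows(a, a)
        triple = vc.pair_correlations(r1, r2, list(r1.index))
        assert triple == pytest.approx((1.0, 1.0, 1.0))

    def test_negated_rows(self, rng):
        a = rng.normal(size=20)
        r1, r2 = _rows(a, -a)
        triple = vc.pair_correlations(r1, r2, list(r1.index))
        assert triple == pytest.approx((-1.0, -1.0, 1.0))

    def test_zero_variance_is_undefined_not_zero(self):
        r1, r2 = _rows([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        triple = vc.pair_correlations(r1, r2, list(r1.index))
        assert np.isnan(triple.spearman_rho) and np.isnan(triple.pearson_r)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            a = rng.normal(size=n)
            b = 0.5 * a + rng.normal(size=n)
            if rng.random() < 0.3:  # inject ties to exercise average ranks
                a = np.round(a)
            r1, r2 = _rows(a, b)
            got = vc.pair_correlations(r1, r2, list(r1.index))
            assert got.pearson_r == pytest.approx(_pearson_oracle(a, b), abs=1e-12)
            assert got.spearman_rho == pytest.approx(_spearman_oracle(a, b), abs=1e-12)
            assert got.r_squared == pytest.approx(_pearson_oracle(a, b) ** 2, abs=1e-12)


class TestAggregatePairs:
    @staticmethod
    def _clr_from(values: pd.DataFrame) -> ClrMatrix:
        logs = np.log(values.to_numpy())
        clr = logs - logs.mean(axis=1, keepdims=True)
        return ClrMatrix(pd.DataFrame(clr, index=values.index, columns=values.columns))

    def test_b_exclusive_block_hits_all_pairs(self, rng):
        cols = [f"NT-{i}" for i in range(300)] + ["SVMP-1"]
        samples = [f"A{i}" for i in range(1, 6)] + [f"B{i}" for i in range(1, 5)]
        types = {s: s[0] for s in samples}
        base = rng.lognormal(3, 1, size=300)
        rows = {}
        for s in samples:
            nt = base * rng.lognormal(0, 0.2, size=300)
            tox = 5000.0 if types[s] == "B" else 1e-3  # delta-replaced absence
            rows[s] = np.r_[nt, tox]
        clr = self._clr_from(pd.DataFrame(rows, index=cols).T)
        agg, pairs = vc.aggregate_pairs(clr, types, cols[:-1], ["SVMP-1"])
        assert len(pairs) == 20
        assert agg.at["SVMP-1", "UpB"] == 20
        assert agg.at["SVMP-1", "UpA"] == 0
        assert agg.at["SVMP-1", "delta"] == 20

    def test_identical_cohorts_flag_nothing(self, rng):
        cols = [f"NT-{i}" for i in range(100)] + ["TOX-1"]
        row = rng.lognormal(3, 1, size=101)
        values = pd.DataFrame([row, row], index=["a1", "b1"], columns=cols)
        clr = self._clr_from(values)
        agg, _ = vc.aggregate_pairs(clr, {"a1": "A", "b1": "B"}, cols[:-1], ["TOX-1"])
        assert (agg[["UpB", "UpA", "delta"]] == 0).all().all()

    def test_average_direction_classification(self, rng):
        cols = [f"NT-{i}" for i in range(200)] + ["TOX-1"]
        base = rng.lognormal(3, 1, size=200)
        rows = {}
        for s, typ in [("a1", "A"), ("b1", "B"), ("AveA", "A"), ("AveB", "B")]:
            nt = base * rng.lognormal(0, 0.1, size=200)
            rows[s] = np.r_[nt, 1e4 if typ == "B" else 1e-2]
        clr = self._clr_from(pd.DataFrame(rows, index=cols).T)
        agg, _ = vc.aggregate_pairs(
            clr, {"a1": "A", "b1": "B"}, cols[:-1], ["TOX-1"],
            average_names=("AveA", "AveB"),
        )
        assert agg.at["TOX-1", "ave_direction"] == "Up"

    def test_missing_type_rejected(self, rng):
        clr = self._clr_from(pd.DataFrame({"T-0": [1.0], "T-1": [2.0]}, index=["a1"]))
        with pytest.raises(ValueError, match="each venom type"):
            vc.aggregate_pairs(clr, {"a1": "A"}, ["T-0"], ["T-1"])


class TestOlsBand:
    def test_toxins_on_the_line_not_flagged(self, rng):
        x = rng.normal(size=100)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.3, size=100)
        cols = [f"NT-{i}" for i in range(100)] + ["TOX-1"]
        xt = np.r_[x, 0.5]
        yt = np.r_[y, 2.0 * 0.5 + 1.0]
        r1, r2 = _rows(xt, yt, cols=cols)
        out = vc.ols_band_outliers(r1, r2, cols[:-1], ["TOX-1"])
        assert out.empty

    def test_far_point_flagged_above(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.05, size=50)
        cols = [f"NT-{i}" for i in range(50)] + ["TOX-1"]
        r1, r2 = _rows(np.r_[x, 0.0], np.r_[y, 10.0], cols=cols)
        out = vc.ols_band_outliers(r1, r2, cols[:-1], ["TOX-1"])
        assert list(out.index) == ["TOX-1"]
        assert out.at["TOX-1", "direction"] == "up_in_j"

    def test_band_matches_statsmodels_prediction_interval(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(0, 0.5, size=40)
        x0 = np.linspace(-2, 2, 9)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        frame = fit.get_prediction(sm.add_constant(x0)).summary_frame(alpha=0.01)
        upper = frame["obs_ci_upper"].to_numpy()
        cols = [f"NT-{i}" for i in range(40)] + [f"TOX-{k}" for k in range(9)]
        # toxins just outside / just inside the statsmodels band
        for shift, expect_flag in [(1e-6, True), (-1e-6, False)]:
            r1, r2 = _rows(np.r_[x, x0], np.r_[y, upper + shift], cols=cols)
            out = vc.ols_band_outliers(r1, r2, cols[:40], cols[40:], level=0.99)
            assert len(out) == (9 if expect_flag else 0)

    def test_null_points_outside_band_near_one_percent(self, rng):
        hits = 0
        total = 0
        for _ in range(40):
            x = rng.normal(size=400)
            y = x + rng.normal(0, 0.5, size=400)
            cols = [f"P-{i}" for i in range(400)]
            r1, r2 = _rows(x, y, cols=cols)
            out = vc.ols_band_outliers(r1, r2, cols[:300], cols[300:], level=0.99)
            hits += len(out)
            total += 100
        assert hits / total == pytest.approx(0.01, abs=0.006)

    def test_degenerate_fit_rejected(self):
        r1, r2 = _rows([1.0, 1.0, 1.0, 2.0], [0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            vc.ols_band_outliers(r1, r2, ["T-0", "T-1", "T-2"], ["T-3"])


class TestModelResults:
    def test_toxins_only_matrix_cannot_form_a_null(self, toxin_expression, venom_types):
        """The printed table carries no nontoxins, so no empirical null exists."""
        expr, catalog = toxin_expression
        with pytest.raises(ValueError, match="nontoxin"):
            vc.ExpressionDivergence(expr, catalog, venom_types)

    def test_fit_runs_full_pipeline_and_summarizes(self):
        cfg = vc.SimulationConfig(
            n_nontoxins=300,
            toxin_family_spec=(("SVMP", 5), ("CTL", 5)),
            exclusive_blocks={"SVMP": "B_only"},
            coverage_transcripts="none",
            seed=77,
        )
        ds = vc.generate(cfg)
        results = vc.ExpressionDivergence(
            ds.expression, ds.catalog, ds.venom_types
        ).fit()
        assert len(results.pairs) == 20
        assert set(results.aggregate.columns) >= {"UpB", "UpA", "delta", "ave_direction"}
        assert (results.aggregate["UpB"] + results.aggregate["UpA"] <= 20).all()
        assert (results.aggregate.loc[[f"SVMP-{i}" for i in range(1, 6)], "UpB"] == 20).all()
        assert (results.aggregate.loc[[f"SVMP-{i}" for i in range(1, 6)], "ave_direction"] == "Up").all()
        text = results.summary()
        assert "pairs tested: 20" in text
        corr = results.correlation_table()
        assert set(corr["subset"]) == {"toxins", "nontoxins"}
        assert results.thresholds["threshold"].ge(0).all()

    def test_methods_and_band_agree_on_direction(self, rng):
        """Toxins flagged by both the |delta| rule and the OLS band agree in direction."""
        cols = [f"NT-{i}" for i in range(500)] + [f"TOX-{k}" for k in range(20)]
        x = np.r_[rng.normal(0, 2, 500), rng.normal(0, 2, 20)]
        y = x + np.r_[rng.normal(0, 0.3, 500), rng.normal(0, 4, 20)]
        r1, r2 = _rows(x, y, cols=cols)
        thr = vc.null_threshold(r1, r2, cols[:500])
        flat = vc.flag_outliers(r1, r2, cols[500:], thr)
        band = vc.ols_band_outliers(r1, r2, cols[:500], cols[500:])
        both = set(flat.index) & set(band.index)
        assert both  # construction guarantees some shared flags
        for t in both:
            assert flat.at[t, "direction"] == band.at[t, "direction"]
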