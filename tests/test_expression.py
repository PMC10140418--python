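import numpy as np
import pandas as pd
import pytest

from era3 import (
    EraModelSpec,
    ExpressionMatrix,
    bin_human_ages,
    cluster_patterns,
    de_by_abundance,
    de_trend,
    normalize_counts,
    spikein_ratio_trend,
)


def expr_matrix(counts: dict, classes: dict | str = "mRNA") -> ExpressionMatrix:
    df = pd.DataFrame(counts).T
    if isinstance(classes, str):
        cls = pd.Series(classes, index=df.index)
    else:
        cls = pd.Series(classes)
    return ExpressionMatrix(counts=df, feature_class=cls)


def meta(n, ages=None, **extra):
    md = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "age_days": ages if ages is not None else np.linspace(20, 120, n),
        }
    )
    for k, v in extra.items():
        md[k] = v
    return md


class TestSpikeinRatioTrend:
    def test_simple_ratio(self):
        m = expr_matrix(
            {"mir": [1_000_000, 500_000, 800_000], "sp": [10_000, 5_000, 8_000]},
            {"mir": "endogenous_miRNA", "sp": "spikein_small"},
        )
        m.counts.columns = ["s0", "s1", "s2"]
        trend = spikein_ratio_trend(m, meta(3, ages=[20.0, 40.0, 60.0]))
        assert (trend.ratios == 100.0).all()

    def test_exact_linear_ratio_trend(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0])
        ratios = 2 + 0.05 * ages
        spike = np.full(4, 10_000.0)
        endo = ratios * spike
        m = expr_matrix(
            {"mir": endo, "sp": spike},
            {"mir": "endogenous_miRNA", "sp": "spikein_small"},
        )
        m.counts.columns = [f"s{i}" for i in range(4)]
        trend = spikein_ratio_trend(m, meta(4, ages=ages))
        assert trend.estimate_age == pytest.approx(0.05, abs=1e-12)
        assert trend.adj_r2 == pytest.approx(1.0)

    def test_zero_spikein_total_raises(self):
        m = expr_matrix(
            {"mir": [10, 10], "sp": [0, 5]},
            {"mir": "endogenous_miRNA", "sp": "spikein_small"},
        )
        m.counts.columns = ["s0", "s1"]
        with pytest.raises(ValueError, match="s0"):
            spikein_ratio_trend(m, meta(2, ages=[10.0, 20.0]))

    def test_injected_gain_recovered_on_synthetic_data(self):
        from era3 import SimulationConfig, simulate_expression, simulate_isomir_table

        cfg = SimulationConfig(
            seed=21, n_mirnas=30, endogenous_gain_per_day=0.01,
            shortened_up_bias=0.0, expr_noise_sigma=0.05,
        )
        _, md, truth = simulate_isomir_table(cfg)
        matrix, _, truth = simulate_expression(cfg, truth, md)
        trend = spikein_ratio_trend(matrix, md, EraModelSpec(covariates=["batch", "sex"]))
        se = abs(trend.estimate_age) / 10  # loose scale reference
        assert trend.estimate_age == pytest.approx(
            truth.expected_ratio_slope, rel=0.25
        )
        assert trend.p_age < 0.01


class TestNormalization:
    def test_doubled_sample_size_factors(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=10).astype(float)
        m = ExpressionMatrix(
            counts=pd.DataFrame({"s0": base, "s1": 2 * base},
                                index=[f"f{i}" for i in range(10)]),
            feature_class=pd.Series("mRNA", index=[f"f{i}" for i in range(10)]),
        )
        norm = normalize_counts(m)
        assert norm.size_factors["s1"] / norm.size_factors["s0"] == pytest.approx(2.0)
        pd.testing.assert_series_equal(
            norm.counts["s0"], norm.counts["s1"], check_names=False
        )

    def test_single_sample_raises(self):
        m = expr_matrix({"f1": [5.0]})
        m.counts.columns = ["s0"]
        with pytest.raises(ValueError, match="2 samples"):
            normalize_counts(m)

    def test_all_features_contain_zero_raises(self):
        m = expr_matrix({"f1": [0.0, 5.0], "f2": [3.0, 0.0]})
        m.counts.columns = ["s0", "s1"]
        with pytest.raises(ValueError, match="rpm"):
            normalize_counts(m)

    def test_spikein_stable_median_resists_endogenous_shift(self):
        # 5 endogenous features double in s1; 5 spike-ins stay flat.
        # The median ratio is driven toward the stable spike-in block.
        idx = [f"e{i}" for i in range(5)] + [f"sp{i}" for i in range(5)]
        base = np.array([100.0, 200, 300, 400, 500, 100, 200, 300, 400, 500])
        s1 = base.copy()
        s1[:5] *= 2
        m = ExpressionMatrix(
            counts=pd.DataFrame({"s0": base, "s1": s1}, index=idx),
            feature_class=pd.Series(
                ["endogenous_miRNA"] * 5 + ["spikein_small"] * 5, index=idx
            ),
        )
        norm = normalize_counts(m)
        ratio = norm.size_factors["s1"] / norm.size_factors["s0"]
        assert 1.0 <= ratio < 2.0  # pulled toward the spike-in-stable median
        assert ratio == pytest.approx(np.sqrt(2), rel=0.05)

    def test_scale_equivariance(self):
        """Per-sample rescaling enters the size factors as the scalars
        themselves, up to the global geometric-mean constant the
        median-of-ratios estimator absorbs into the reference."""
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(10, 1000, size=(12, 4)).astype(float),
            index=[f"f{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(4)],
        )
        cls = pd.Series("mRNA", index=counts.index)
        m1 = ExpressionMatrix(counts=counts, feature_class=cls)
        c = np.array([1.0, 2.0, 0.5, 3.0])
        m2 = ExpressionMatrix(counts=counts * c, feature_class=cls)
        f1 = normalize_counts(m1).size_factors
        f2 = normalize_counts(m2).size_factors
        gmean = np.exp(np.mean(np.log(c)))
        np.testing.assert_allclose(f2 / f1, c / gmean, rtol=1e-12)
        # hence normalized matrices agree up to that one global constant
        n1 = normalize_counts(m1).counts
        n2 = normalize_counts(m2).counts
        np.testing.assert_allclose(n2.values, gmean * n1.values, rtol=1e-12)

    def test_rpm_scaling_per_class(self):
        idx = ["m1", "m2", "g1"]
        m = ExpressionMatrix(
            counts=pd.DataFrame(
                {"s0": [30.0, 70.0, 500.0], "s1": [10.0, 10.0, 100.0]}, index=idx
            ),
            feature_class=pd.Series(
                ["endogenous_miRNA", "endogenous_miRNA", "mRNA"], index=idx
            ),
        )
        norm = normalize_counts(m, method="rpm")
        assert norm.counts.loc["m1", "s0"] == pytest.approx(0.3 * 1e6)
        assert norm.counts.loc["g1", "s0"] == pytest.approx(1e6)


class TestDeTrend:
    def _normalized(self, counts: pd.DataFrame) -> ExpressionMatrix:
        cls = pd.Series("mRNA", index=counts.index)
        return ExpressionMatrix(
            counts=counts, feature_class=cls, normalized=True,
            raw_totals=counts.sum(axis=1),
        )

    def test_exact_exponential_trend(self):
        ages = np.linspace(20, 120, 8)
        counts = pd.DataFrame(
            {f"s{i}": [2 ** (0.1 * a) - 0.5] for i, a in enumerate(ages)},
            index=["f"],
        )
        de = de_trend(self._normalized(counts), meta(8, ages=ages), min_total=0)
        assert de["estimate_age"].iloc[0] == pytest.approx(0.1, abs=1e-10)
        assert de["p"].iloc[0] < 1e-12
        assert de["direction"].iloc[0] == "up"

    def test_low_total_count_feature_removed(self):
        counts = pd.DataFrame(
            {"s0": [3.0, 100.0], "s1": [3.0, 100.0], "s2": [3.0, 100.0],
             "s3": [0.0, 100.0]},
            index=["low", "high"],
        )
        de = de_trend(self._normalized(counts), meta(4))
        assert de["feature_id"].tolist() == ["high"]

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(42)
        n, m = 32, 1000
        ages = np.tile([22.0, 40.0, 60.0, 120.0], 8)
        counts = pd.DataFrame(
            rng.lognormal(5, 0.4, size=(m, n)),
            index=[f"f{i}" for i in range(m)],
            columns=[f"s{i}" for i in range(n)],
        )
        de = de_trend(self._normalized(counts), meta(n, ages=ages))
        frac = (de["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_direction_consistent_with_estimate(self):
        rng = np.random.default_rng(3)
        n = 16
        ages = np.linspace(20, 120, n)
        counts = pd.DataFrame(
            {
                "up": 100 * 2 ** (0.02 * ages) * rng.lognormal(0, 0.05, n),
                "down": 100 * 2 ** (-0.02 * ages) * rng.lognormal(0, 0.05, n),
            }
        ).T
        counts.columns = [f"s{i}" for i in range(n)]
        de = de_trend(self._normalized(counts), meta(n, ages=ages)).set_index(
            "feature_id"
        )
        assert de.loc["up", "direction"] == "up"
        assert de.loc["down", "direction"] == "down"


class TestClustering:
    def _setup(self, n_up=6, n_down=6, n=16):
        ages = np.tile([22.0, 40.0, 60.0, 120.0], n // 4)
        rng = np.random.default_rng(1)
        rows = {}
        for i in range(n_up):
            rows[f"up{i}"] = (50 + i * 10) * 2 ** (0.02 * ages) * rng.lognormal(0, 0.02, n)
        for i in range(n_down):
            rows[f"down{i}"] = (50 + i * 10) * 2 ** (-0.02 * ages) * rng.lognormal(0, 0.02, n)
        counts = pd.DataFrame(rows).T
        counts.columns = [f"s{i}" for i in range(n)]
        cls = pd.Series("mRNA", index=counts.index)
        matrix = ExpressionMatrix(counts=counts, feature_class=cls, normalized=True,
                                  raw_totals=counts.sum(axis=1))
        md = meta(n, ages=ages)
        de = de_trend(matrix, md)
        return de, matrix, md

    def test_monotone_profiles_split_into_two_pure_clusters(self):
        de, matrix, md = self._setup()
        labels, profiles = cluster_patterns(de, matrix, md)
        assert labels.nunique() == 2
        up_labels = {labels[f] for f in labels.index if f.startswith("up")}
        down_labels = {labels[f] for f in labels.index if f.startswith("down")}
        assert len(up_labels) == 1 and len(down_labels) == 1
        assert up_labels != down_labels

    def test_duplicated_feature_same_label(self):
        de, matrix, md = self._setup()
        matrix.counts.loc["up0_copy"] = matrix.counts.loc["up0"]
        matrix.feature_class.loc["up0_copy"] = "mRNA"
        matrix.raw_totals.loc["up0_copy"] = matrix.raw_totals.loc["up0"]
        matrix = ExpressionMatrix(
            counts=matrix.counts, feature_class=matrix.feature_class,
            normalized=True, raw_totals=matrix.raw_totals,
        )
        de2 = de_trend(matrix, md)
        labels, _ = cluster_patterns(de2, matrix, md)
        assert labels["up0_copy"] == labels["up0"]

    def test_affine_rescaling_invariance(self):
        de, matrix, md = self._setup()
        scaled = ExpressionMatrix(
            counts=matrix.counts * 7.0, feature_class=matrix.feature_class,
            normalized=True, raw_totals=matrix.raw_totals,
        )
        l1, _ = cluster_patterns(de, matrix, md)
        l2, _ = cluster_patterns(de, scaled, md)
        pd.testing.assert_series_equal(l1, l2)

    def test_feature_reordering_invariance(self):
        de, matrix, md = self._setup()
        perm = matrix.counts.index[::-1]
        reordered = ExpressionMatrix(
            counts=matrix.counts.loc[perm], feature_class=matrix.feature_class.loc[perm],
            normalized=True, raw_totals=matrix.raw_totals.loc[perm],
        )
        l1, _ = cluster_patterns(de, matrix, md)
        l2, _ = cluster_patterns(de.iloc[::-1], reordered, md)
        # same partition (label ids may swap)
        merged = pd.DataFrame({"a": l1, "b": l2.loc[l1.index]})
        assert merged.groupby("a")["b"].nunique().eq(1).all()

    def test_too_few_significant_features_warns(self):
        de, matrix, md = self._setup()
        de_none = de.assign(fdr=1.0)
        with pytest.warns(UserWarning, match="significant"):
            labels, profiles = cluster_patterns(de_none, matrix, md)
        assert labels.empty and profiles.empty


class TestAgeBinsAndAbundance:
    @pytest.mark.parametrize(
        "age_days,expected",
        [
            (2, "infant"),
            (364, "infant"),
            (365, "child"),  # exactly 1 year, lower edge inclusive
            (15 * 365, "adolescent"),
            (25 * 365, "young adult"),
            (45 * 365, "adult"),
            (98 * 365, "elderly"),
        ],
    )
    def test_human_age_binning(self, age_days, expected):
        md = pd.DataFrame({"sample_id": ["s"], "age_days": [float(age_days)]})
        assert bin_human_ages(md).iloc[0] == expected

    def test_non_positive_age_raises(self):
        md = pd.DataFrame({"sample_id": ["s"], "age_days": [0.0]})
        with pytest.raises(ValueError):
            bin_human_ages(md)

    def test_all_ns_every_bin_pure(self):
        rng = np.random.default_rng(0)
        feats = [f"f{i}" for i in range(20)]
        de = pd.DataFrame(
            {"feature_id": feats, "estimate_age": 0.0, "p": 1.0, "fdr": 1.0,
             "direction": "ns", "cluster": pd.NA}
        )
        counts = pd.DataFrame(
            rng.lognormal(4, 1, size=(20, 4)), index=feats,
            columns=[f"s{i}" for i in range(4)],
        )
        m = ExpressionMatrix(counts=counts,
                             feature_class=pd.Series("mRNA", index=feats))
        freq = de_by_abundance(de, m, n_bins=5)
        assert (freq["ns"] == 1.0).all()
        assert np.allclose(freq.sum(axis=1), 1.0)

    def test_up_calls_concentrated_in_top_bin(self):
        feats = [f"f{i}" for i in range(20)]
        abundance = np.arange(1.0, 21.0)
        direction = ["up" if a > 16 else "ns" for a in abundance]
        de = pd.DataFrame(
            {"feature_id": feats, "estimate_age": 0.1, "p": 0.01, "fdr": 0.01,
             "direction": direction, "cluster": pd.NA}
        )
        counts = pd.DataFrame(
            {"s0": abundance, "s1": abundance}, index=feats
        )
        m = ExpressionMatrix(counts=counts,
                             feature_class=pd.Series("mRNA", index=feats))
        freq = de_by_abundance(de, m, n_bins=5)
        assert freq["up"].idxmax() == 5
        assert freq.loc[5, "up"] == pytest.approx(1.0)
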