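import numpy as np
import pandas as pd
import pytest

from mhss import (classify_quartiles, homogeneity_test, kde, spatial_lag,
                  spatial_transition_matrices, stationary_distribution,
                  transition_matrix)
from mhss.dynamics import TransitionMatrix, silverman_bandwidth
from mhss.synthetic import SynthConfig, generate_panel, noiseless
from mhss import score


def series_from(wide: dict[str, list], years) -> pd.Series:
    idx = pd.MultiIndex.from_tuples(
        [(p, y) for p in wide for y in years], names=["province", "year"])
    vals = [v for row in wide.values() for v in row]
    return pd.Series(vals, index=idx, dtype=float)


class TestKde:
    def test_single_point_kernel_value(self):
        curve = kde([0.0], bandwidth=1.0)
        at_zero = np.interp(0.0, curve.x, curve.f)
        assert at_zero == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-4)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(5)
        for sample in (rng.normal(size=40), rng.uniform(size=9),
                       np.array([0.1, 0.1, 0.9])):
            curve = kde(sample)
            assert curve.integral() == pytest.approx(1.0, abs=0.01)
            assert (curve.f >= 0).all()

    def test_bimodal_sample_has_two_modes(self):
        rng = np.random.default_rng(6)
        sample = np.concatenate([rng.normal(0, 0.3, 50),
                                 rng.normal(8, 0.3, 50)])
        assert kde(sample).n_modes() == 2

    def test_translation_equivariance(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=30)
        c1 = kde(v, bandwidth=0.4)
        c2 = kde(v + 5.0, bandwidth=0.4)
        np.testing.assert_allclose(c2.x, c1.x + 5.0, atol=1e-12)
        np.testing.assert_allclose(c2.f, c1.f, atol=1e-12)

    def test_silverman_rule_value(self):
        v = np.arange(10.0)
        sd = v.std(ddof=1)
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.34) * 10 ** -0.2
        assert silverman_bandwidth(v) == pytest.approx(expected)

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kde([1.0, 2.0], bandwidth=0.0)
        with pytest.raises(ValueError, match="at least 2"):
            kde([1.0])


class TestQuartileClasses:
    def test_eight_scores_split_evenly(self):
        s = series_from({f"P{i}": [float(i)] for i in range(1, 9)}, [2005])
        cls = classify_quartiles(s).classes
        got = {p: c for (p, y), c in cls.items()}
        assert got == {"P1": 1, "P2": 1, "P3": 2, "P4": 2,
                       "P5": 3, "P6": 3, "P7": 4, "P8": 4}

    def test_all_tied_assigns_class_one_with_warning(self):
        s = series_from({f"P{i}": [1.0] for i in range(5)}, [2005])
        with pytest.warns(UserWarning, match="tied"):
            cls = classify_quartiles(s).classes
        assert (cls == 1).all()

    def test_31_provinces_balanced_classes(self, default_scores):
        classes = classify_quartiles(default_scores.scores)
        for year in default_scores.years:
            counts = classes.classes.xs(int(year), level="year") \
                .value_counts()
            assert set(counts) <= {7, 8}
            assert counts.sum() == 31

    def test_monotone_transform_invariance(self, default_scores):
        c1 = classify_quartiles(default_scores.scores)
        c2 = classify_quartiles(np.exp(3.0 * default_scores.scores))
        pd.testing.assert_series_equal(c1.classes, c2.classes)

    def test_too_few_provinces_rejected(self):
        s = series_from({"A": [1.0], "B": [2.0], "C": [3.0]}, [2005])
        with pytest.raises(ValueError, match="4 provinces"):
            classify_quartiles(s)


class TestTransitionMatrix:
    def test_published_style_row_probabilities(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0] = [97, 25, 0, 0]
        m = TransitionMatrix(counts, ["I", "II", "III", "IV"])
        np.testing.assert_allclose(m.probabilities[0].round(4),
                                   [0.7951, 0.2049, 0.0, 0.0])
        assert m.row_totals[0] == 122

    def test_absorbing_state_identity_row(self):
        s = series_from({"A": [1, 1, 1], "B": [2, 2, 2], "C": [3, 3, 3],
                         "D": [9, 9, 9]}, [2005, 2006, 2007])
        m = transition_matrix(classify_quartiles(s))
        np.testing.assert_allclose(m.probabilities[3], [0, 0, 0, 1])

    def test_default_panel_total_transitions(self, default_scores):
        m = transition_matrix(classify_quartiles(default_scores.scores))
        assert m.n_transitions == 31 * 15 == 465

    def test_row_probabilities_sum_to_one(self, default_scores):
        m = transition_matrix(classify_quartiles(default_scores.scores))
        visited = m.row_totals > 0
        np.testing.assert_allclose(m.probabilities[visited].sum(axis=1),
                                   1.0, atol=1e-12)

    def test_low_noise_transitions_stay_adjacent(self):
        cfg = SynthConfig(sigma_eps=0.01, sigma_indicator=0.005,
                          missing_rate=0.0)
        panel, _, _, _ = generate_panel(cfg, seed=12)
        ss = score(panel)
        m = transition_matrix(classify_quartiles(ss.scores))
        off = sum(m.counts[i, j] for i in range(4) for j in range(4)
                  if abs(i - j) > 1)
        assert off / m.n_transitions < 0.02

    def test_non_consecutive_years_rejected(self):
        s = series_from({f"P{i}": [1.0 * i, 2.0 * i] for i in range(4)},
                        [2005, 2007])
        with pytest.raises(ValueError):
            transition_matrix(classify_quartiles(s))


class TestSpatialLag:
    def test_two_neighbours_average(self):
        s = series_from({"A": [5.0], "B": [1.0], "C": [3.0]}, [2005])
        W = pd.DataFrame(
            [[0, 1, 1], [1, 0, 0], [1, 0, 0]],
            index=["A", "B", "C"], columns=["A", "B", "C"], dtype=float)
        lag = spatial_lag(s, W)
        assert lag[("A", 2005)] == pytest.approx(2.0)  # mean of 1 and 3
        assert lag[("B", 2005)] == pytest.approx(5.0)  # single neighbour

    def test_linearity_in_scores(self, default_scores, default_run):
        W = default_run[3].adjacency
        lag1 = spatial_lag(default_scores.scores, W)
        lag2 = spatial_lag(3.0 * default_scores.scores, W)
        np.testing.assert_allclose(lag2, 3.0 * lag1, atol=1e-12)

    def test_isolated_province_rejected(self):
        s = series_from({"A": [1.0], "B": [2.0]}, [2005])
        W = pd.DataFrame(0.0, index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="isolated"):
            spatial_lag(s, W)


class TestSpatialMarkov:
    def test_conditional_counts_partition_unconditional(self,
                                                        default_scores,
                                                        default_run):
        classes = classify_quartiles(default_scores.scores)
        lags = spatial_lag(default_scores.scores, default_run[3].adjacency)
        sp = spatial_transition_matrices(classes, lags)
        assert sp.check_conservation()
        total = sum(m.n_transitions for m in sp.conditionals.values())
        assert total == sp.unconditional.n_transitions == 465

    def test_no_spillover_gives_homogeneous_conditionals(self):
        # under rho = 0 the lag class carries no information about moves
        pvals = []
        for seed in range(5):
            cfg = SynthConfig(rho=0.0, missing_rate=0.0)
            panel, _, _, truth = generate_panel(cfg, seed=seed)
            ss = score(panel)
            classes = classify_quartiles(ss.scores)
            lags = spatial_lag(ss.scores, truth.adjacency)
            sp = spatial_transition_matrices(classes, lags)
            pvals.append(homogeneity_test(sp, n_permutations=299,
                                          seed=seed))
        assert sum(p > 0.01 for p in pvals) >= 4

    def test_positive_spillover_raises_upward_mobility(self):
        # with rho > 0, provinces in high-lag neighbourhoods move up more
        wins = 0
        for seed in range(12):
            cfg = SynthConfig(rho=0.15, missing_rate=0.0)
            panel, _, _, truth = generate_panel(cfg, seed=seed)
            ss = score(panel)
            classes = classify_quartiles(ss.scores)
            lags = spatial_lag(ss.scores, truth.adjacency)
            sp = spatial_transition_matrices(classes, lags)
            lo = (sp.conditionals["I"].counts[1]
                  + sp.conditionals["II"].counts[1])
            hi = (sp.conditionals["III"].counts[1]
                  + sp.conditionals["IV"].counts[1])
            if lo.sum() == 0 or hi.sum() == 0:
                continue
            p_lo = (lo[2] + lo[3]) / lo.sum()
            p_hi = (hi[2] + hi[3]) / hi.sum()
            wins += p_hi > p_lo
        assert wins >= 8


class TestStationaryDistribution:
    def test_symmetric_two_state_chain(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0] = [5, 5, 0, 0]
        counts[1] = [5, 5, 0, 0]
        m = TransitionMatrix(counts, ["I", "II", "III", "IV"])
        pi = stationary_distribution(m)
        np.testing.assert_allclose(pi, [0.5, 0.5, 0, 0], atol=1e-12)

    def test_identity_matrix_warns_and_returns_uniform(self):
        counts = np.diag([3, 3, 3, 3])
        m = TransitionMatrix(counts, ["I", "II", "III", "IV"])
        with pytest.warns(UserWarning, match="not unique"):
            pi = stationary_distribution(m)
        np.testing.assert_allclose(pi, 0.25)

    def test_absorbing_chain_concentrates_on_top_class(self):
        # upward-drifting chain with absorbing high state
        counts = np.array([[97, 25, 0, 0], [1, 95, 28, 0],
                           [0, 0, 97, 21], [0, 0, 0, 101]])
        m = TransitionMatrix(counts, ["I", "II", "III", "IV"])
        pi = stationary_distribution(m)
        assert pi[3] == pytest.approx(1.0, abs=1e-8)
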