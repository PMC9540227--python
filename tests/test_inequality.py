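from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhss import (GroupedScores, beta_convergence, convergence_speed,
                  dagum_decompose, decline_rate, generate_panel,
                  gini_series, overall_gini)
from mhss.panel import RegionScheme
from mhss.synthetic import SynthConfig, noiseless


def grouped(**regions):
    scheme = RegionScheme({f"{r}{i}": r for r, vals in regions.items()
                           for i in range(len(vals))})
    scores = pd.Series({f"{r}{i}": v for r, vals in regions.items()
                        for i, v in enumerate(vals)})
    return GroupedScores.from_scores(scores, scheme)


def enumeration_gini(y):
    """Independent oracle: direct double loop over ordered pairs."""
    y = np.asarray(y, dtype=float)
    total = sum(abs(a - b) for a, b in product(y, y))
    return total / (2 * len(y) ** 2 * y.mean())


class TestOverallGini:
    def test_two_point_closed_form(self):
        assert overall_gini(np.array([1.0, 3.0])) == pytest.approx(0.25)

    def test_equal_scores_zero(self):
        assert overall_gini(np.array([2.0, 2.0, 2.0])) == 0.0

    def test_four_point_enumeration(self):
        # sum |diff| = 20 over ordered pairs; 20 / (2 * 16 * 2.5) = 0.25
        assert overall_gini(np.array([1.0, 2, 3, 4])) == \
            pytest.approx(enumeration_gini([1.0, 2, 3, 4]), abs=1e-15)
        assert overall_gini(np.array([1.0, 2, 3, 4])) == \
            pytest.approx(0.25, abs=1e-15)

    def test_agrees_with_pairwise_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.uniform(0.1, 5.0, size=rng.integers(2, 13))
            assert overall_gini(y) == pytest.approx(enumeration_gini(y),
                                                    abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            overall_gini(np.array([-1.0, 0.5]))


class TestDagumDecomposition:
    def test_four_point_worked_example(self):
        g = grouped(A=[1.0, 2.0], B=[3.0, 4.0])
        d = dagum_decompose(g)
        assert d.G == pytest.approx(0.25, abs=1e-12)
        assert d.G_w == pytest.approx(0.05, abs=1e-12)
        assert d.G_nb == pytest.approx(0.20, abs=1e-12)
        assert d.G_t == pytest.approx(0.0, abs=1e-12)
        # no overlap between the two regional distributions
        assert list(d.D.values()) == [pytest.approx(1.0)]

    def test_all_equal_everything_zero(self):
        d = dagum_decompose(grouped(A=[2.0, 2.0], B=[2.0, 2.0]))
        assert d.G == d.G_w == d.G_nb == d.G_t == 0.0

    def test_identical_multisets_pure_transvariation(self):
        d = dagum_decompose(grouped(A=[1.0, 5.0], B=[1.0, 5.0]))
        assert list(d.D.values()) == [pytest.approx(0.0)]
        assert d.G_nb == pytest.approx(0.0, abs=1e-12)
        assert d.G_t > 0

    def test_single_region_reduces_to_within(self):
        d = dagum_decompose(grouped(A=[1.0, 2.0, 3.0]))
        assert d.G == pytest.approx(d.G_w, abs=1e-15)
        assert d.G_nb == 0.0 and d.G_t == 0.0
        assert d.G == pytest.approx(overall_gini(np.array([1.0, 2, 3])))

    def test_scale_invariance(self):
        g1 = grouped(A=[1.0, 2.0, 7.0], B=[3.0, 4.0], C=[0.5, 9.0])
        g2 = grouped(A=[3.0, 6.0, 21.0], B=[9.0, 12.0], C=[1.5, 27.0])
        d1, d2 = dagum_decompose(g1), dagum_decompose(g2)
        assert d1.G == pytest.approx(d2.G, abs=1e-14)
        assert d1.G_w == pytest.approx(d2.G_w, abs=1e-14)
        assert d1.G_nb == pytest.approx(d2.G_nb, abs=1e-14)
        assert d1.G_t == pytest.approx(d2.G_t, abs=1e-14)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8),
           st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8))
    def test_decomposition_identity(self, a, b, c):
        d = dagum_decompose(grouped(A=a, B=b, C=c))
        assert d.G == pytest.approx(d.G_w + d.G_nb + d.G_t, abs=1e-12)
        assert d.G == pytest.approx(enumeration_gini(a + b + c), abs=1e-12)
        assert min(d.G_w, d.G_nb, d.G_t) >= -1e-15
        for v in d.D.values():
            assert -1e-12 <= v <= 1 + 1e-12

    def test_contribution_rates_sum_to_100(self, default_scores):
        from mhss import default_region_scheme
        frame, _ = gini_series(default_scores.scores,
                               default_region_scheme())
        total = (frame["contrib_within_pct"] + frame["contrib_between_pct"]
                 + frame["contrib_transvariation_pct"])
        np.testing.assert_allclose(total, 100.0, atol=1e-9)


class TestGiniSeries:
    def test_paper_endpoint_decline_rate(self):
        assert decline_rate(0.2584, 0.1091) == pytest.approx(57.78,
                                                             abs=0.005)

    def test_constant_scores_zero_decline(self):
        assert decline_rate(0.2, 0.2) == 0.0

    def test_convergent_dynamics_shrink_gini(self):
        # low noise + beta < 0: dispersion falls monotonically
        cfg = noiseless(beta_true=-0.2)
        panel, _, scheme, truth = generate_panel(cfg, seed=4)
        scores = np.exp(truth.latent_series())
        frame, summary = gini_series(scores, scheme)
        g = frame["G"].to_numpy()
        assert np.all(np.diff(g) < 0)
        assert summary["decline_rate_pct"] > 0


class TestBetaConvergence:
    def test_noiseless_identification_exact(self):
        cfg = noiseless(beta_true=-0.2)
        _, _, _, truth = generate_panel(cfg, seed=2)
        res = beta_convergence(np.exp(truth.latent_series()),
                               cluster=False)
        assert res.beta == pytest.approx(-0.2, abs=1e-8)

    def test_default_run_has_465_growth_observations(self, default_scores):
        res = beta_convergence(default_scores.scores)
        assert res.n_obs == 31 * 15 == 465
        assert res.n_transitions == 15

    def test_conditional_model_reports_five_controls(self, default_run):
        from mhss import interpolate_missing, score
        panel, controls, scheme, truth = default_run
        ss = score(interpolate_missing(panel))
        res = beta_convergence(ss.scores, controls=controls)
        assert set(res.controls) == {"lnPGDP", "UR", "FSS", "ISU",
                                     "lnPFDI"}
        assert res.beta < 0

    def test_regional_scope_restricts_sample(self, default_run,
                                             default_scores):
        scheme = default_run[2]
        east = [p for p, r in scheme.mapping.items() if r == "eastern"]
        res = beta_convergence(default_scores.scores, provinces=east)
        assert res.n_obs == 11 * 15

    def test_nonpositive_scores_rejected(self):
        idx = pd.MultiIndex.from_product(
            [["A", "B", "C", "D"], [2005, 2006, 2007]],
            names=["province", "year"])
        s = pd.Series(1.0, index=idx)
        s.iloc[0] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            beta_convergence(s)


class TestConvergenceSpeed:
    @pytest.mark.parametrize("beta,expected", [
        (-0.172, 0.0126),   # overall absolute model
        (-0.206, 0.0154),   # eastern absolute
        (-0.267, 0.0207),   # central absolute
        (-0.185, 0.0136),   # western absolute
        (-0.288, 0.0226),   # eastern conditional
        (-0.321, 0.0258),   # central conditional
        (-0.216, 0.0162),   # western conditional
    ])
    def test_published_speed_transforms(self, beta, expected):
        assert round(convergence_speed(beta, 15), 4) == expected

    def test_zero_beta_zero_speed(self):
        assert convergence_speed(0.0, 15) == 0.0

    def test_beta_at_most_minus_one_rejected(self):
        with pytest.raises(ValueError, match="-1"):
            convergence_speed(-1.0, 15)
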