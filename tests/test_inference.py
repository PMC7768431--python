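"""Random-network nulls, Z-tests, bootstrap comparisons and McNemar."""

import numpy as np
import pandas as pd
import pytest

from fluencynet.exceptions import ValidationError
from fluencynet.inference import (
    NullDistribution,
    bootstrap_partial,
    mcnemar_from_counts,
    mcnemar_unique,
    random_network_null,
    z_test,
)


class TestRandomNetworkNull:
    def test_k4_density_collapses_all_measures(self):
        null = random_network_null(4, 6, n_sims=100, seed=0)
        assert null["cc"].mean == pytest.approx(1.0) and null["cc"].sd == 0
        assert null["aspl"].mean == pytest.approx(1.0) and null["aspl"].sd == 0

    def test_mean_cc_approximates_density(self):
        # E[CC] of an Erdos-Renyi graph is its edge density
        null = random_network_null(31, 87, n_sims=300, seed=1)
        assert null["cc"].mean == pytest.approx(87 / 465, abs=0.01)

    def test_mean_aspl_matches_distance_expansion(self):
        # analytic two-step expansion: P(d=1)=p, P(d=2)~(1-p)(1-(1-p^2)^(n-2))
        n, m = 33, 93
        p = m / (n * (n - 1) / 2)
        p2 = (1 - p) * (1 - (1 - p * p) ** (n - 2))
        expected = p + 2 * p2 + 3 * (1 - p - p2)
        null = random_network_null(n, m, n_sims=300, seed=2)
        assert null["aspl"].mean == pytest.approx(expected, abs=0.1)

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValidationError):
            random_network_null(5, 11, n_sims=10, seed=0)


class TestZTest:
    def test_arithmetic(self):
        null = NullDistribution("x", np.array([7.0, 8, 9, 8, 8, 8]))
        null.mean, null.sd = 8.0, 1.0  # fix exact moments for the arithmetic check
        z, p = z_test(10.0, null)
        assert z == pytest.approx(2.0) and p == pytest.approx(0.0455, abs=1e-3)
        z, p = z_test(8.0, null)
        assert z == 0 and p == pytest.approx(1.0)
        z, p = z_test(8 + 1.96, null)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_sd_rejected(self):
        null = NullDistribution("x", np.ones(5))
        with pytest.raises(ValidationError):
            z_test(1.5, null)


class TestMcNemar:
    @pytest.mark.parametrize(
        "b, c, n, chi2, phi",
        [
            (45, 24, 129, 5.797, 0.212),  # only the continuity-corrected
            (38, 29, 129, 0.955, 0.09),   # statistic reproduces these pairs
            (10, 10, 129, 0.05, None),    # symmetric discordance
        ],
    )
    def test_continuity_corrected_statistic(self, b, c, n, chi2, phi):
        got_chi2, p, got_phi = mcnemar_from_counts(b, c, n)
        assert got_chi2 == pytest.approx(chi2, abs=5e-4)
        if phi is not None:
            assert got_phi == pytest.approx(phi, abs=5e-3)

    def test_agrees_with_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        chi2, p, _ = mcnemar_from_counts(45, 24, 129)
        table = [[60, 45], [24, 0]]
        res = sm.mcnemar(table, exact=False, correction=True)
        assert chi2 == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_counts_and_symmetry_from_matrices(self):
        low = pd.DataFrame({"a": [1, 0], "b": [1, 1], "c": [0, 0]})
        high = pd.DataFrame({"a": [0, 0], "b": [1, 0], "c": [1, 1]})
        counts, chi2, p, phi = mcnemar_unique(low, high)
        assert (counts.both, counts.high_only, counts.low_only) == (1, 1, 1)
        assert counts.n_total == 3
        counts_sw, chi2_sw, p_sw, phi_sw = mcnemar_unique(high, low)
        assert (chi2_sw, p_sw, phi_sw) == (chi2, p, phi)

    def test_no_discordance_reported(self):
        mat = pd.DataFrame({"a": [1], "b": [1]})
        with pytest.warns(UserWarning, match="no discordant"):
            counts, chi2, p, phi = mcnemar_unique(mat, mat)
        assert np.isnan(chi2)


class TestBootstrapPartial:
    def test_identical_groups_are_null(self, equated_matrices):
        mat_low, _ = equated_matrices
        results = bootstrap_partial(mat_low, mat_low.copy(), proportions=(0.6,),
                                    n_boot=60, seed=4)
        for r in results:
            assert r.t == pytest.approx(0.0, abs=1e-9)
            assert abs(r.d) < 0.1

    def test_reported_df_matches_sample_sizes(self, equated_matrices):
        results = bootstrap_partial(*equated_matrices, proportions=(0.8,),
                                    n_boot=30, seed=5, measures=("q",))
        assert results[0].df == 58

    def test_swapping_groups_negates_t_and_preserves_d(self, equated_matrices):
        mat_low, mat_high = equated_matrices
        fwd = bootstrap_partial(mat_low, mat_high, proportions=(0.7,),
                                n_boot=25, seed=6, measures=("aspl", "q"))
        rev = bootstrap_partial(mat_high, mat_low, proportions=(0.7,),
                                n_boot=25, seed=6, measures=("aspl", "q"))
        for f, r in zip(fwd, rev):
            assert f.t == pytest.approx(-r.t)
            assert abs(f.d) == pytest.approx(abs(r.d))

    def test_same_subset_applied_to_both_groups(self, equated_matrices, monkeypatch):
        # networks per realization must share their node set
        from fluencynet import inference
        seen = []
        original = inference.estimate_network

        def spy(mat):
            seen.append(tuple(mat.columns))
            return original(mat)

        monkeypatch.setattr(inference, "estimate_network", spy)
        bootstrap_partial(*equated_matrices, proportions=(0.5,), n_boot=5, seed=7,
                          measures=("cc",))
        assert len(seen) == 10
        for low_cols, high_cols in zip(seen[::2], seen[1::2]):
            assert low_cols == high_cols

    def test_extending_n_boot_preserves_earlier_draws(self, equated_matrices):
        short = bootstrap_partial(*equated_matrices, proportions=(0.9,),
                                  n_boot=8, seed=8, measures=("cc",))
        long = bootstrap_partial(*equated_matrices, proportions=(0.9,),
                                 n_boot=16, seed=8, measures=("cc",))
        np.testing.assert_allclose(short[0].low_values, long[0].low_values[:8])

    def test_unequated_matrices_rejected(self, equated_matrices):
        mat_low, mat_high = equated_matrices
        with pytest.raises(ValidationError, match="equated"):
            bootstrap_partial(mat_low, mat_high.iloc[:, :-1])

    def test_subset_below_four_nodes_rejected(self, equated_matrices):
        mat_low, mat_high = equated_matrices
        small_low, small_high = mat_low.iloc[:, :5], mat_high.iloc[:, :5]
        with pytest.raises(ValidationError, match="fewer than 4"):
            bootstrap_partial(small_low, small_high, proportions=(0.5,))
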