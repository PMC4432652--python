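import numpy as np
import pytest

from screenkit.formats import GctMatrix
from screenkit.paris import (
    DensityGrid,
    EntropyUnderflowError,
    TargetProfile,
    cv_bandwidth,
    estimate_density,
    joint_entropy,
    mutual_information,
    nmi,
    permutation_significance,
    rnmi,
    score_all,
    self_nmi,
    silverman_bandwidth,
)
from screenkit.simulate import simulate_context_dataset


def _gaussian_grid(rho, size=201, span=5.0):
    """Analytic standard bivariate normal density on a grid (no KDE)."""
    g = np.linspace(-span, span, size)
    d = g[1] - g[0]
    T, X = np.meshgrid(g, g, indexing="ij")
    det = 1 - rho**2
    P = np.exp(-(T**2 - 2 * rho * T * X + X**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det)
    )
    P /= P.sum() * d * d
    mt = P.sum(axis=1) * d
    mx = P.sum(axis=0) * d
    return DensityGrid(g, g, P, mt, mx, (1.0, 1.0), d, d, discrete_t=False)


class TestDensityGrid:
    def test_grid_mass_sums_to_one(self, rng):
        g = estimate_density(rng.normal(size=80), rng.normal(size=80))
        assert g.joint.sum() * g.cell_area == pytest.approx(1.0, abs=1e-6)

    def test_marginals_consistent_with_joint(self, rng):
        g = estimate_density(rng.normal(size=60), rng.normal(size=60))
        np.testing.assert_allclose(g.marginal_t, g.joint.sum(axis=1) * g.dx, atol=1e-12)

    def test_binary_target_class_priors(self, rng):
        t = np.array([1.0] * 30 + [0.0] * 70)
        g = estimate_density(t, rng.normal(size=100))
        assert g.discrete_t
        np.testing.assert_allclose(sorted(g.marginal_t), [0.3, 0.7])

    def test_independent_profiles_factorize(self, rng):
        t = rng.normal(size=400)
        x = rng.normal(size=400)
        g = estimate_density(t, x, bandwidth="silverman")
        prod = np.outer(g.marginal_t, g.marginal_x)
        assert np.abs(g.joint - prod).max() < 0.05

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_density(np.ones(20), np.arange(20.0))


class TestEntropyAndMi:
    def test_uniform_density_zero_entropy(self):
        # uniform on the unit square: -integral 1*log(1) = 0
        size = 50
        g = np.linspace(0, 1, size)
        d = g[1] - g[0]
        P = np.ones((size, size))
        P /= P.sum() * d * d
        grid = DensityGrid(g, g, P, P.sum(1) * d, P.sum(0) * d, (1, 1), d, d, False)
        assert joint_entropy(grid) == pytest.approx(0.0, abs=5e-2)

    def test_gaussian_entropy_closed_form(self):
        # independent standard normal pair: H = 2 * 0.5*log(2*pi*e)
        grid = _gaussian_grid(0.0)
        assert joint_entropy(grid) == pytest.approx(np.log(2 * np.pi * np.e), rel=1e-3)

    def test_gaussian_mi_closed_form(self):
        grid = _gaussian_grid(0.9)
        assert mutual_information(grid) == pytest.approx(
            -0.5 * np.log(1 - 0.81), rel=1e-2
        )

    def test_entropy_decreases_with_correlation(self):
        hs = [joint_entropy(_gaussian_grid(r)) for r in (0.0, 0.5, 0.9)]
        assert hs[0] > hs[1] > hs[2]

    def test_mi_zero_on_constructed_independent_grid(self):
        grid = _gaussian_grid(0.0)
        assert mutual_information(grid) == pytest.approx(0.0, abs=1e-9)

    def test_mi_symmetric_under_argument_swap(self, rng):
        t, x = rng.normal(size=150), rng.normal(size=150)
        a = mutual_information(estimate_density(t, x, bandwidth="silverman"))
        b = mutual_information(estimate_density(x, t, bandwidth="silverman"))
        assert a == pytest.approx(b, abs=1e-9)

    def test_kde_mi_tracks_gaussian_oracle(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=2000)
        g = estimate_density(z[:, 0], z[:, 1], grid_size=96, bandwidth="silverman")
        # KDE smoothing biases MI down; agreement is to estimator tolerance
        assert mutual_information(g) == pytest.approx(-0.5 * np.log(1 - 0.81), abs=0.2)


class TestBandwidths:
    def test_cv_stays_on_ladder_around_rule_of_thumb(self, rng):
        v = rng.normal(size=200)
        ratio = cv_bandwidth(v) / silverman_bandwidth(v)
        assert 0.25 <= ratio <= 4.0

    def test_silverman_positive_scales_with_sd(self, rng):
        v = rng.normal(size=100)
        assert silverman_bandwidth(3 * v) == pytest.approx(3 * silverman_bandwidth(v))


class TestRnmi:
    def test_self_match_is_exactly_one(self, rng):
        t = rng.normal(size=100)
        assert rnmi(t, t.copy()).RNMI == 1.0

    def test_anti_match_is_minus_one(self, rng):
        t = rng.normal(size=100)
        assert rnmi(t, -t).RNMI == pytest.approx(-1.0, abs=1e-9)

    def test_binary_self_score_is_one(self):
        t = np.array([0.0] * 40 + [1.0] * 20)
        assert self_nmi(t) == 1.0

    def test_independent_profiles_score_near_zero(self, rng):
        vals = [rnmi(rng.normal(size=100), rng.normal(size=100)).RNMI for _ in range(30)]
        assert abs(np.mean(vals)) < 0.06

    def test_reflection_invariance_of_nmi(self, rng):
        t, x = rng.normal(size=90), rng.normal(size=90)
        assert nmi(t, x) == pytest.approx(nmi(t, -x), abs=1e-9)

    def test_joint_sample_reordering_invariance(self, rng):
        t, x = rng.normal(size=70), rng.normal(size=70)
        perm = rng.permutation(70)
        assert rnmi(t, x).RNMI == pytest.approx(rnmi(t[perm], x[perm]).RNMI, abs=1e-12)

    def test_nonlinear_association_seen_by_nmi_not_rnmi(self, rng):
        # x = t^2: Pearson rho ~ 0 but the dependence is strong
        t = rng.normal(size=300)
        x = t**2
        noise_nmi = np.mean(
            [nmi(t, rng.normal(size=300), bandwidth="silverman") for _ in range(5)]
        )
        s = rnmi(t, x, bandwidth="silverman")
        assert s.NMI > 3 * noise_nmi  # dependence invisible to Pearson rho
        assert abs(s.rho) < 0.2

    def test_peaked_profile_raises_entropy_underflow(self):
        t = np.concatenate([np.zeros(30), np.full(30, 1e-4), [1e-3, 2e-3]])
        x = np.linspace(0, 1, 62)
        with pytest.raises((EntropyUnderflowError, ValueError)):
            rnmi(t + 1e-9 * np.arange(62), x)


class TestScoreAll:
    def _matrix(self, rows, ids, cols):
        return GctMatrix(ids, [""] * len(ids), cols, np.asarray(rows, dtype=float))

    def test_target_row_ranks_first_with_score_one(self, rng):
        cols = [f"S{i}" for i in range(40)]
        t = TargetProfile(cols, rng.normal(size=40))
        rows = [t.values, rng.normal(size=40), rng.normal(size=40)]
        scores = score_all(t, self._matrix(rows, ["self", "n1", "n2"], cols))
        by_id = {s.feature_id: s.RNMI for s in scores}
        assert by_id["self"] == 1.0
        assert by_id["self"] > max(abs(by_id["n1"]), abs(by_id["n2"]))

    def test_single_row_equals_direct_rnmi(self, rng):
        cols = [f"S{i}" for i in range(30)]
        t = TargetProfile(cols, rng.normal(size=30))
        x = rng.normal(size=30)
        scores = score_all(t, self._matrix([x], ["f"], cols))
        direct = rnmi(t.values, x, bandwidth="silverman")
        assert scores[0].RNMI == pytest.approx(direct.RNMI, abs=1e-12)

    def test_too_few_shared_samples_rejected(self, rng):
        cols = [f"S{i}" for i in range(5)]
        with pytest.raises(ValueError):
            TargetProfile(cols, rng.normal(size=5))


class TestPermutationSignificance:
    def test_same_seed_identical_result(self):
        m, t, _ = simulate_context_dataset(n_lines=30, n_features=20, seed=2)
        a = permutation_significance(t, m, n_perm=100, seed=7)
        b = permutation_significance(t, m, n_perm=100, seed=7)
        assert a.table.equals(b.table)

    def test_planted_feature_tops_its_sign_family(self):
        m, t, truth = simulate_context_dataset(seed=1)
        res = permutation_significance(t, m, n_perm=200, seed=1)
        tab = res.table.set_index("feature")
        planted = truth["planted_feature"]
        neg = tab[tab["rho"] < 0]
        assert neg["RNMI"].idxmin() == planted
        assert tab.loc[planted, "p"] == tab["p"].min()

    def test_pvalues_in_unit_interval_and_fdr_monotone(self):
        m, t, _ = simulate_context_dataset(n_lines=30, n_features=30, seed=4, effect=0.0)
        res = permutation_significance(t, m, n_perm=120, seed=4)
        assert ((res.table["p"] > 0) & (res.table["p"] <= 1)).all()
        assert ((res.table["fdr"] >= 0) & (res.table["fdr"] <= 1)).all()

    def test_two_sided_mode_uses_magnitude(self):
        m, t, truth = simulate_context_dataset(n_lines=40, n_features=30, seed=6)
        res = permutation_significance(t, m, n_perm=150, seed=6, two_sided=True)
        tab = res.table.set_index("feature")
        assert tab.loc[truth["planted_feature"], "p"] == tab["p"].min()
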