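"""Brownian-motion rate estimation, comparison tests, bootstrap CIs."""
import numpy as np
import pytest

import valvemorph as vm
import valvemorph.io as mio
from valvemorph.evorates import _pooled_sigma0
from valvemorph.phylo import phylo_covariance


@pytest.fixture(scope="module")
def C64():
    return phylo_covariance(vm.simulate_tree(64, seed=23))


class TestSigma2:
    def test_two_tip_hand_case(self):
        C = vm.PhyloCovariance(np.eye(2), ["A", "B"])
        assert vm.sigma2_mult(np.array([0.0, 2.0]), C) == pytest.approx(1.0)

    def test_zero_at_phylogenetic_mean(self, C64):
        Y = np.ones((C64.n, 4)) * 3.3
        assert vm.sigma2_mult(Y, C64) == pytest.approx(0.0, abs=1e-20)

    def test_per_dimension_flag(self, C64, rng):
        Y = rng.normal(size=(C64.n, 5))
        assert vm.sigma2_mult(Y, C64, per_dimension=False) == pytest.approx(
            5 * vm.sigma2_mult(Y, C64)
        )

    def test_branch_length_scaling_exact(self, C64, rng):
        """Rescaling all branch lengths by c rescales sigma2 by 1/c."""
        Y = rng.normal(size=(C64.n, 3))
        s1 = vm.sigma2_mult(Y, C64)
        C_scaled = vm.PhyloCovariance(4.0 * C64.C, C64.species_order)
        assert vm.sigma2_mult(Y, C_scaled) == pytest.approx(s1 / 4.0, rel=1e-10)

    def test_data_scaling_exact(self, C64, rng):
        Y = rng.normal(size=(C64.n, 3))
        assert vm.sigma2_mult(3.0 * Y, C64) == pytest.approx(
            9.0 * vm.sigma2_mult(Y, C64), rel=1e-10
        )

    def test_consistency_bias_shrinks_with_n(self, rng):
        biases = []
        for n in (16, 64, 256):
            C = phylo_covariance(vm.simulate_tree(n, seed=n))
            ests = [
                vm.sigma2_mult(vm.simulate_bm_tips(C, np.eye(2), rng), C)
                for _ in range(150)
            ]
            biases.append(abs(np.mean(ests) - 1.0))
        assert biases[2] < biases[0]


class TestSimulateBM:
    def test_zero_rate_matrix(self, C64):
        Y = vm.simulate_bm_tips(C64, np.zeros((3, 3)), seed=1)
        assert np.abs(Y).max() == 0.0

    def test_star_tree_tip_variance(self, rng):
        t = 2.0
        C = vm.PhyloCovariance(t * np.eye(50), [f"s{i}" for i in range(50)])
        draws = vm.simulate_bm_tips(C, np.array([[1.5]]), rng, size=400)
        assert draws.var() == pytest.approx(1.5 * t, rel=0.05)

    def test_correlated_dimensions(self, C64, rng):
        rho = 0.8
        R = np.array([[1.0, rho], [rho, 1.0]])
        draws = vm.simulate_bm_tips(C64, R, rng, size=300)
        # cross-correlation of whitened contrasts
        from valvemorph.phylo import inv_sqrt

        M = inv_sqrt(C64)
        U = M @ draws
        flat = U.reshape(-1, 2)
        assert np.corrcoef(flat.T)[0, 1] == pytest.approx(rho, abs=0.05)

    def test_non_psd_rejected(self, C64):
        with pytest.raises(ValueError, match="positive semidefinite"):
            vm.simulate_bm_tips(C64, np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestGroupRates:
    def test_pvalue_floor_and_determinism(self, C64, rng):
        Y = vm.simulate_bm_tips(C64, np.eye(2), rng)
        groups = ["a"] * 32 + ["b"] * 32
        r1 = vm.compare_rates_groups(Y, groups, C64, n_sim=99, seed=3)
        r2 = vm.compare_rates_groups(Y, groups, C64, n_sim=99, seed=3)
        assert r1.p_value == r2.p_value > 0
        assert r1.ratio >= 1.0
        assert set(r1.pairwise_p) == {("a", "b")}

    def test_single_species_group_flagged(self, C64, rng):
        Y = vm.simulate_bm_tips(C64, np.eye(2), rng)
        groups = ["solo"] + ["rest"] * 63
        res = vm.compare_rates_groups(Y, groups, C64, n_sim=0)
        assert "solo" in res.flags
        assert res.sigma2["solo"] >= 0.0

    def test_rate_monotone_in_group_multiplier(self, C64, rng):
        """Scaling one group's evolutionary variance raises its estimate."""
        groups = np.array(["a"] * 32 + ["b"] * 32)
        means = []
        for mult in (1.0, 2.0, 4.0):
            ests = []
            for _ in range(60):
                Y = vm.simulate_bm_tips(C64, np.eye(2), rng)
                Y[groups == "b"] *= np.sqrt(mult)
                ests.append(vm.compare_rates_groups(Y, list(groups), C64, n_sim=0).sigma2["b"])
            means.append(np.mean(ests))
        assert means[0] < means[1] < means[2]


class TestTraitRates:
    def test_identical_blocks_unit_ratio(self, C64, rng):
        Y = vm.simulate_bm_tips(C64, np.eye(3), rng)
        res = vm.compare_rates_traits({"left": Y, "right": Y}, C64, n_sim=0)
        assert res.ratio == pytest.approx(1.0)
        assert res.sigma2["left"] == res.sigma2["right"]

    def test_unequal_dimensions_rejected(self, C64, rng):
        with pytest.raises(ValueError, match="dimensionality"):
            vm.compare_rates_traits(
                {"a": rng.normal(size=(64, 2)), "b": rng.normal(size=(64, 3))},
                C64,
                n_sim=0,
            )

    def test_null_covariance_preserves_pooled_rate(self, C64, rng):
        U = rng.normal(size=(C64.n, 4))
        Sigma0 = _pooled_sigma0(U)
        pooled = (U**2).sum() / (C64.n * 4)
        assert np.trace(Sigma0) / 4 == pytest.approx(pooled, rel=1e-10)


class TestWithinGroups:
    def test_identical_valves_unit_ratio_everywhere(self, C64, rng):
        Y = vm.simulate_bm_tips(C64, np.eye(2), rng)
        groups = dict(zip(C64.species_order, ["a"] * 40 + ["b"] * 24))
        out = vm.rates_within_groups(Y, Y, groups, C64, n_sim=99, seed=2)
        for g, res in out.items():
            assert res.ratio == pytest.approx(1.0)

    def test_single_and_two_species_groups_untested(self, C64, rng):
        Y = vm.simulate_bm_tips(C64, np.eye(2), rng)
        groups = ["solo"] + ["duo"] * 2 + ["rest"] * 61
        out = vm.rates_within_groups(
            Y, Y + 0.1, dict(zip(C64.species_order, groups)), C64, n_sim=99, seed=2
        )
        assert np.isnan(out["solo"].ratio)
        assert out["duo"].p_value is None and out["duo"].flags
        assert out["rest"].p_value is not None

    def test_ratio_ordering_recovered(self, rng):
        """Group with true R/L variance ratio 2 shows the larger estimate."""
        phy = vm.simulate_tree(40, seed=41)
        C = phylo_covariance(phy)
        groups = dict(zip(C.species_order, ["hi"] * 20 + ["lo"] * 20))
        wins = 0
        for _ in range(40):
            L = vm.simulate_bm_tips(C, np.eye(2), rng)
            R = vm.simulate_bm_tips(C, np.eye(2), rng)
            hi = np.array([groups[s] == "hi" for s in C.species_order])
            R[hi] *= np.sqrt(2.0)
            out = vm.rates_within_groups(L, R, groups, C, n_sim=0, seed=1)
            wins += int(out["hi"].ratio > out["lo"].ratio)
        assert wins >= 0.8 * 40


class TestBootstrap:
    def test_singleton_species_zero_width(self, C64):
        values = np.arange(C64.n, dtype=float)[:, None]
        labels = list(C64.species_order)  # one specimen per species

        def stat(M):
            return {"rate": vm.sigma2_mult(M, C64)}

        lo, hi = vm.bootstrap_rate_ci(
            values, labels, C64.species_order, stat, n_boot=100, seed=0
        )
        assert lo["rate"] == hi["rate"] == pytest.approx(vm.sigma2_mult(values, C64))

    def test_ci_brackets_point_estimate(self, C64, rng):
        # 3 specimens per species with noise
        per = 3
        species = np.repeat(C64.species_order, per)
        truth = vm.simulate_bm_tips(C64, np.eye(2), rng)
        values = np.repeat(truth, per, axis=0) + 0.05 * rng.normal(size=(C64.n * per, 2))

        def stat(M):
            return {"rate": vm.sigma2_mult(M, C64)}

        lo, hi = vm.bootstrap_rate_ci(
            values, list(species), C64.species_order, stat, n_boot=200, seed=1
        )
        point = vm.sigma2_mult(
            np.stack([values[species == sp].mean(axis=0) for sp in C64.species_order]),
            C64,
        )
        assert lo["rate"] <= point <= hi["rate"]
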