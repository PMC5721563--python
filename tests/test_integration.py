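"""Two-block PLS, its permutation test, and effect-size comparisons."""
import numpy as np
import pytest
from scipy import stats

import valvemorph as vm
from valvemorph.exceptions import MissingDistributionError
from valvemorph.phylo import phylo_covariance

from conftest import _euler_grid


def _grid_pls_oracle(Y1, Y2):
    """Maximize score covariance over unit-vector grids (PLS definition),
    then report |corr| at the covariance-maximizing pair. Two-level
    angular grid (p1 = 2 as a circle angle, p2 = 3 as spherical angles)."""
    Y1c = Y1 - Y1.mean(axis=0)
    Y2c = Y2 - Y2.mean(axis=0)

    def search(a0, th0, ph0, half, n):
        a = np.linspace(a0 - half, a0 + half, n)
        th = np.linspace(th0 - half, th0 + half, n)
        ph = np.linspace(ph0 - half, ph0 + half, n)
        U = np.column_stack([np.cos(a), np.sin(a)])
        TH, PH = np.meshgrid(th, ph, indexing="ij")
        V = np.column_stack(
            [
                (np.sin(TH) * np.cos(PH)).ravel(),
                (np.sin(TH) * np.sin(PH)).ravel(),
                np.cos(TH).ravel(),
            ]
        )
        S1 = Y1c @ U.T
        S2 = Y2c @ V.T
        cov = np.abs(S1.T @ S2)
        i, j = np.unravel_index(np.argmax(cov), cov.shape)
        r = abs(np.corrcoef(S1[:, i], S2[:, j])[0, 1])
        return r, a[i], th[j // len(ph)], ph[j % len(ph)]

    _, a0, th0, ph0 = search(np.pi, np.pi / 2, np.pi, np.pi, 121)
    half = np.pi / 50
    for _ in range(2):
        r, a0, th0, ph0 = search(a0, th0, ph0, half, 41)
        half /= 15
    return r


class TestTwoBlockPLS:
    def test_identical_blocks_give_r_one(self, rng):
        Y = rng.normal(size=(10, 4))
        res = vm.two_block_pls(Y, Y)
        assert res.r_pls == pytest.approx(1.0, abs=1e-10)

    def test_univariate_blocks_reduce_to_pearson(self, rng):
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(size=12)
        res = vm.two_block_pls(x[:, None], y[:, None])
        assert res.r_pls == pytest.approx(abs(stats.pearsonr(x, y)[0]), abs=1e-12)

    def test_matches_grid_oracle_on_fixed_blocks(self):
        rng = np.random.default_rng(8)
        Y1 = rng.normal(size=(6, 2))
        Y2 = Y1 @ rng.normal(size=(2, 3)) + 0.4 * rng.normal(size=(6, 3))
        res = vm.two_block_pls(Y1, Y2)
        assert res.r_pls == pytest.approx(_grid_pls_oracle(Y1, Y2), abs=2e-4)

    def test_zero_cross_covariance_degenerate(self):
        Y1 = np.zeros((5, 2))
        Y2 = np.arange(10.0).reshape(5, 2)
        res = vm.two_block_pls(Y1, Y2)
        assert res.degenerate and res.r_pls == 0.0

    def test_invariance_to_rotation_and_scaling(self, rng):
        Y1 = rng.normal(size=(15, 3))
        Y2 = 0.5 * Y1 @ rng.normal(size=(3, 4)) + rng.normal(size=(15, 4))
        base = vm.two_block_pls(Y1, Y2).r_pls
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert vm.two_block_pls(3.7 * Y1 @ Q, Y2).r_pls == pytest.approx(base, abs=1e-10)
        Q2, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert vm.two_block_pls(Y1, 0.01 * Y2 @ Q2).r_pls == pytest.approx(base, abs=1e-10)


class TestPhyloPLS:
    def test_star_tree_equals_ordinary_pls(self, rng):
        C = vm.PhyloCovariance(np.eye(9), [f"s{i}" for i in range(9)])
        Y1 = rng.normal(size=(9, 3))
        Y2 = rng.normal(size=(9, 2))
        assert vm.phylo_pls(Y1, Y2, C).r_pls == pytest.approx(
            vm.two_block_pls(Y1, Y2).r_pls, abs=1e-12
        )

    def test_identical_transformed_blocks(self, tree86, rng):
        C = phylo_covariance(tree86)
        Y = rng.normal(size=(C.n, 5))
        assert vm.phylo_pls(Y, Y, C).r_pls == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_reference_implementation(self, rng):
        """Straight-line reimplementation with scipy's matrix power as the
        whitening route, on BM-correlated blocks."""
        from scipy.linalg import fractional_matrix_power
        from valvemorph.evorates import simulate_bm_tips

        phy = vm.simulate_tree(64, seed=31)
        C = phylo_covariance(phy)
        rho = 0.9
        p = 3
        Sig = np.block(
            [[np.eye(p), rho * np.eye(p)], [rho * np.eye(p), np.eye(p)]]
        )
        diffs = []
        for _ in range(20):
            Y = simulate_bm_tips(C, Sig, rng)
            Y1, Y2 = Y[:, :p], Y[:, p:]
            mine = vm.phylo_pls(Y1, Y2, C).r_pls

            Minv = np.real(fractional_matrix_power(C.C, -0.5))
            ones = np.ones((C.n, 1))
            ref_r = []
            blocks = []
            for B in (Y1, Y2):
                a = np.linalg.lstsq(Minv @ ones, Minv @ B, rcond=None)[0]
                blocks.append(Minv @ (B - ones @ a))
            B1 = blocks[0] - blocks[0].mean(axis=0)
            B2 = blocks[1] - blocks[1].mean(axis=0)
            u, s, vt = np.linalg.svd(np.cov(B1.T, B2.T)[:p, p:])
            s1, s2 = B1 @ u[:, 0], B2 @ vt[0]
            ref = abs(np.corrcoef(s1, s2)[0, 1])
            diffs.append(mine - ref)
        assert np.abs(diffs).max() < 1e-8


class TestPermutation:
    def test_identical_blocks_minimal_p(self, rng):
        Y = rng.normal(size=(8, 3))
        res = vm.pls_permutation(Y, Y, None, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.z_score > 2

    def test_p_value_never_zero_and_determinism(self, tree86, rng):
        C = phylo_covariance(tree86)
        Y1 = rng.normal(size=(C.n, 2))
        Y2 = rng.normal(size=(C.n, 2))
        r1 = vm.pls_permutation(Y1, Y2, C, n_perm=199, seed=7)
        r2 = vm.pls_permutation(Y1, Y2, C, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value and r1.z_score == r2.z_score
        assert r1.p_value > 0
        assert len(r1.permuted_r) == 199

    def test_power_on_strongly_integrated_blocks(self):
        """True correlation 0.95 vs 0.50: the comparison should separate
        them in most replicates."""
        from valvemorph.evorates import simulate_bm_tips

        rng = np.random.default_rng(55)
        phy = vm.simulate_tree(40, seed=13)
        C = phylo_covariance(phy)
        p = 2
        reject = 0
        n_rep = 40
        for _ in range(n_rep):
            results = []
            for rho in (0.95, 0.50):
                Sig = np.block([[np.eye(p), rho * np.eye(p)], [rho * np.eye(p), np.eye(p)]])
                Y = simulate_bm_tips(C, Sig, rng)
                results.append(
                    vm.pls_permutation(
                        Y[:, :p], Y[:, p:], C, n_perm=199, seed=int(rng.integers(2**31))
                    )
                )
            cmp = vm.compare_pls_effects(results, ["hi", "lo"])
            reject += int(cmp["p"].iloc[0] <= 0.05)
        assert reject >= 0.7 * n_rep


class TestCompareEffects:
    def test_self_comparison_is_null(self, rng):
        Y = rng.normal(size=(10, 3))
        res = vm.pls_permutation(Y, Y + rng.normal(size=(10, 3)), None, n_perm=199, seed=3)
        cmp = vm.compare_pls_effects([res, res], ["a", "b"])
        assert cmp["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert cmp["p"].iloc[0] == pytest.approx(1.0)

    def test_missing_distribution_raises(self, rng):
        Y = rng.normal(size=(8, 2))
        bare = vm.two_block_pls(Y, Y)
        with pytest.raises(MissingDistributionError):
            vm.compare_pls_effects([bare, bare])
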