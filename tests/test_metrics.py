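"""Nestedness indices: worked examples, independent oracles, invariants."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bipnest import (
    BipartiteNetwork,
    MetricConfig,
    U_MAX,
    UndefinedMetricError,
    atc,
    canonical_nested,
    compute_all,
    discrepancy,
    gen_noisy_nested,
    nir,
    nmd,
    nodf,
    normalized_spectral_radius,
    pack,
    spectral_radius,
    stable_nodf,
    temperature,
)
from conftest import random_networks

# canonical matrices whose staircase covers every row and column (no
# zero-degree nodes), where the perfect-nested identities are exact
FULL_STAIRCASES = [(2, 2, 3), (5, 5, 15), (10, 10, 55), (4, 9, 27), (8, 5, 30)]


def random_net_battery():
    yield from random_networks(10, 7, 9, 0.35, seed=11)
    yield from random_networks(5, 12, 6, 0.2, seed=12)


class TestTemperature:
    @pytest.mark.parametrize("nme", FULL_STAIRCASES)
    def test_perfectly_nested_is_zero(self, nme):
        t_ap, t = temperature(canonical_nested(*nme))
        assert t_ap == 0.0 and t == 100.0

    def test_all_ones(self):
        assert temperature(BipartiteNetwork(np.ones((3, 4), dtype=int)))[0] == 0.0

    def test_anti_nested_geometry(self, anti_nested):
        # Packed form is [[0,1],[1,0]] against boundary c=(2,0).  By hand:
        # the absence at cell center (0.25,0.25) crosses the staircase at
        # the y=0.5 connector, d/D = 0.25/1.0 -> u = 0.0625; the presence
        # at (0.25,0.75) crosses at the same connector, d/D = 0.25/0.5 ->
        # u = 0.25.
        expected = 100.0 * (0.0625 + 0.25) / (U_MAX * 4)
        t_ap, t = temperature(anti_nested)
        assert t_ap == pytest.approx(expected, abs=1e-9)
        assert t == 0.0  # clamped: T_AP exceeds 100 on this tiny matrix

    def test_undefined_for_empty(self):
        with pytest.raises(UndefinedMetricError):
            temperature(BipartiteNetwork(np.zeros((2, 2), dtype=int)))


class TestNMD:
    def test_nested_2x2_by_hand(self):
        # cells (1,1),(1,2),(2,1): distances 0.5, 1.0, 1.0 -> d = 2.5 =
        # d_nest; d_rand = 3
        tau, nmd_v = nmd(canonical_nested(2, 2, 3))
        assert tau == 0.0 and nmd_v == 100.0

    @pytest.mark.parametrize("nme", FULL_STAIRCASES[1:] + [(6, 8, 11), (9, 4, 7)])
    def test_any_perfectly_nested_has_tau_zero(self, nme):
        assert nmd(canonical_nested(*nme))[0] == 0.0

    def test_anti_nested_by_hand(self, anti_nested):
        # packed distances 0.5 + 1.5 = 2.0; d_nest(E=2) = 0.5 + 1.0 = 1.5;
        # d_rand = 2.0
        tau, nmd_v = nmd(anti_nested)
        assert tau == pytest.approx(1.0)
        assert nmd_v == pytest.approx(0.0)

    def test_d_rand_matches_uniform_sampling(self):
        # the analytic normalization d_rand = E is the expectation of the
        # Manhattan sum under uniform placement of E links
        n, m, e = 6, 8, 14
        x = (np.arange(m) + 0.5) / m
        y = (np.arange(n) + 0.5) / n
        dist = (x[None, :] + y[:, None]).ravel()
        rng = np.random.default_rng(7)
        sums = [
            dist[rng.choice(n * m, size=e, replace=False)].sum()
            for _ in range(4000)
        ]
        se = np.std(sums, ddof=1) / np.sqrt(len(sums))
        assert np.mean(sums) == pytest.approx(e, abs=4 * se)

    def test_undefined_at_complete_fill(self):
        with pytest.raises(UndefinedMetricError):
            nmd(BipartiteNetwork(np.ones((3, 3), dtype=int)))


def nodf_bruteforce(matrix: np.ndarray, stable: bool) -> float:
    """Independent oracle: literal pairwise definition, no vectorization."""
    n, m = matrix.shape

    def guild_sum(mat):
        degs = [sum(r) for r in mat]
        order = sorted(range(len(mat)), key=lambda i: -degs[i])
        total = 0.0
        for a in range(len(mat)):
            for b in range(a + 1, len(mat)):
                i, j = order[a], order[b]
                if degs[j] == 0:
                    continue
                if not stable and degs[j] >= degs[i]:
                    continue
                shared = sum(1 for k in range(len(mat[0])) if mat[i][k] and mat[j][k])
                total += shared / degs[j]
        return total

    k = (n * (n - 1) + m * (m - 1)) / 200
    return (guild_sum(matrix.tolist()) + guild_sum(matrix.T.tolist())) / k


class TestOverlapIndices:
    def test_nodf_examples(self, chain_2x2):
        assert nodf(chain_2x2) == pytest.approx(100.0)
        assert nodf(BipartiteNetwork(np.ones((2, 2), dtype=int))) == 0.0
        assert nodf(BipartiteNetwork(np.zeros((3, 3), dtype=int))) == 0.0

    def test_stable_nodf_examples(self, chain_2x2, anti_nested):
        assert stable_nodf(BipartiteNetwork(np.ones((2, 2), dtype=int))) == 100.0
        assert stable_nodf(chain_2x2) == pytest.approx(100.0)
        assert stable_nodf(anti_nested) == 0.0

    @pytest.mark.parametrize("stable", [False, True])
    def test_closed_form_equals_bruteforce_oracle(self, stable):
        fn = stable_nodf if stable else nodf
        count = 0
        for net in random_networks(100, 15, 20, 0.3, seed=99):
            assert fn(net) == pytest.approx(
                nodf_bruteforce(net.matrix, stable), abs=1e-9
            )
            count += 1
        assert count == 100


class TestDiscrepancy:
    @pytest.mark.parametrize("nme", FULL_STAIRCASES)
    def test_perfectly_nested_is_zero(self, nme):
        delta, dprime = discrepancy(canonical_nested(*nme))
        assert delta == 0.0 and dprime == 100.0

    def test_anti_nested_by_hand(self, anti_nested):
        delta, dprime = discrepancy(anti_nested)
        assert delta == 1.0 and dprime == 50.0

    def test_all_ones(self):
        assert discrepancy(BipartiteNetwork(np.ones((3, 3), dtype=int)))[0] == 0.0


class TestATC:
    def test_nested_2x2_idr(self):
        curve = atc(canonical_nested(2, 2, 3), "cols", "IDR", tie_seed=0)
        assert curve.surviving_fraction == (1.0, 1.0)
        assert curve.area == 1.0

    def test_nested_2x2_ddr_area_is_fill(self):
        curve = atc(canonical_nested(2, 2, 3), "cols", "DDR", tie_seed=0)
        assert curve.surviving_fraction == (1.0, 0.5)
        assert curve.area == 0.75

    def test_all_zero_matrix(self):
        curve = atc(BipartiteNetwork(np.zeros((3, 4), dtype=int)), "cols", "IDR", 0)
        assert set(curve.surviving_fraction) == {0.0}
        assert curve.area == 0.0

    @given(seed=st.integers(0, 30))
    def test_curve_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        net = BipartiteNetwork((rng.random((6, 9)) < 0.3).astype(int))
        for strategy in ("DDR", "IDR"):
            curve = atc(net, "cols", strategy, tie_seed=seed)
            arr = np.asarray(curve.surviving_fraction)
            assert (np.diff(arr) <= 1e-12).all()
            assert 0.0 <= curve.area <= 1.0


class TestNIR:
    def test_nested_2x2_exact(self):
        assert nir(canonical_nested(2, 2, 3), n_orderings=5, seed=0) == pytest.approx(1.0)

    @pytest.mark.parametrize("nme", [(10, 10, 55), (50, 50, 500), (8, 5, 30)])
    def test_perfectly_nested_is_one(self, nme):
        n, m, _ = nme
        value = nir(canonical_nested(*nme), n_orderings=20, seed=1)
        assert value == pytest.approx(1.0, abs=1 / min(n, m))

    def test_random_below_nested(self):
        nested = nir(canonical_nested(50, 50, 500), n_orderings=10, seed=0)
        rng = np.random.default_rng(5)
        rand = nir(
            BipartiteNetwork((rng.random((50, 50)) < 0.2).astype(int)),
            n_orderings=10,
            seed=0,
        )
        assert rand < nested

    def test_near_complete_fill_is_finite(self):
        value = nir(canonical_nested(4, 4, 15), n_orderings=10, seed=0)
        assert np.isfinite(value)

    def test_undefined_at_complete_fill(self):
        with pytest.raises(UndefinedMetricError):
            nir(BipartiteNetwork(np.ones((3, 3), dtype=int)))


class TestSpectralRadius:
    def test_path_graph_golden_ratio(self, chain_2x2):
        assert spectral_radius(chain_2x2) == pytest.approx((1 + np.sqrt(5)) / 2, abs=1e-9)

    def test_rank_one(self):
        assert spectral_radius(BipartiteNetwork(np.ones((2, 2), dtype=int))) == pytest.approx(2.0)

    def test_permutation_invariance(self, random_net):
        rng = np.random.default_rng(3)
        perm = random_net.permuted(
            rng.permutation(random_net.n_rows), rng.permutation(random_net.n_cols)
        )
        assert spectral_radius(perm) == pytest.approx(spectral_radius(random_net), abs=1e-9)
        assert normalized_spectral_radius(perm) == pytest.approx(
            normalized_spectral_radius(random_net), abs=1e-9
        )

    @pytest.mark.parametrize("nme", FULL_STAIRCASES)
    def test_nested_reference_normalizes_to_100(self, nme):
        assert normalized_spectral_radius(canonical_nested(*nme)) == pytest.approx(100.0)

    def test_anti_nested_by_hand(self, anti_nested):
        # rho = 1; the nested reference for E=2 is [[1,1],[0,0]] with
        # rho_max = sqrt(2)
        assert normalized_spectral_radius(anti_nested) == pytest.approx(
            100 / np.sqrt(2), abs=1e-9
        )


class TestInvariants:
    def test_bounds_on_random_matrices(self):
        for net in random_net_battery():
            if net.n_links == 0:
                continue
            for value in (
                temperature(net)[1],
                nmd(net)[1],
                nodf(net),
                stable_nodf(net),
                discrepancy(net)[1],
                normalized_spectral_radius(net),
            ):
                assert 0.0 <= value <= 100.0 + 1e-9
            trimmed = net.trimmed()
            assert nir(net, n_orderings=10, seed=0) <= 1 + 1 / min(
                trimmed.n_rows, trimmed.n_cols
            )

    def test_zero_degree_rows_never_raise(self):
        mat = np.zeros((5, 6), dtype=int)
        mat[:3, :4] = canonical_nested(3, 4, 9).matrix
        net = BipartiteNetwork(mat)
        for fn in (temperature, nmd, nodf, stable_nodf, discrepancy,
                   spectral_radius, normalized_spectral_radius):
            fn(net)
        nir(net, n_orderings=5, seed=0)

    def test_noise_degrades_nestedness_in_expectation(self):
        # stable-NODF and rho at heavy degree-preserving noise stay at or
        # below their perfectly nested values, as a mean over seeds
        n, m, e = 20, 20, 210
        base = canonical_nested(n, m, e)
        base_sn, base_rho = stable_nodf(base), spectral_radius(base)
        noisy_sn = np.mean(
            [stable_nodf(gen_noisy_nested(n, m, e, 2000, seed=s)) for s in range(12)]
        )
        noisy_rho = np.mean(
            [spectral_radius(gen_noisy_nested(n, m, e, 2000, seed=s)) for s in range(12)]
        )
        assert noisy_sn < base_sn
        assert noisy_rho < base_rho


class TestReport:
    def test_perfectly_nested_report(self):
        report = compute_all(
            canonical_nested(10, 10, 55), MetricConfig(nir_orderings=20, seed=0)
        )
        for name in ("temperature", "nmd", "nodf", "stable_nodf", "discrepancy", "rho_norm"):
            assert report[name].defined
            assert report[name].transformed_value == pytest.approx(100.0)
        assert report["nir"].raw_value == pytest.approx(1.0, abs=1 / 10)

    def test_edgeless_network_flags(self):
        report = compute_all(BipartiteNetwork(np.zeros((3, 3), dtype=int)))
        assert report["nodf"].defined and report["nodf"].raw_value == 0.0
        assert report["stable_nodf"].defined and report["stable_nodf"].raw_value == 0.0
        assert report["spectral_radius"].defined and report["spectral_radius"].raw_value == 0.0
        for name in ("temperature", "nmd", "discrepancy", "nir", "rho_norm"):
            assert not report[name].defined
            assert report[name].note  # reason carried along

    def test_json_roundtrip(self, random_net):
        report = compute_all(random_net, MetricConfig(nir_orderings=5, seed=0))
        recovered = type(report).from_json(report.to_json())
        assert recovered == report
        # and the flat row has raw + transformed columns per metric
        row = report.to_csv_row()
        assert json.dumps(row)  # serializable
        assert "nodf_raw" in row and "temperature_transformed" in row
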