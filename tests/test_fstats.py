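"""f-statistics against a naive per-site oracle, plus jackknife behaviour."""

import numpy as np
import pytest

from woolgen.fstats import (
    InsufficientDataError,
    assign_blocks,
    block_jackknife,
    d_statistic,
    f4,
    f4_ratio,
    outgroup_f3,
    scan_panel,
)
from woolgen.genotype import MISSING

from conftest import build_matrix, random_matrix


# ---------------------------------------------------------------------
# naive per-site oracle: explicit loops, no shared code with the package
# ---------------------------------------------------------------------

def _naive_freqs(matrix, pop):
    cols = [
        j
        for j in range(matrix.n_samples)
        if matrix.samples["population"].iloc[j] == pop
    ]
    out = []
    for i in range(matrix.n_sites):
        alt = tot = 0
        for j in cols:
            c = matrix.calls[i, j]
            if c != MISSING:
                alt += int(c)
                tot += int(matrix.ploidy[j])
        out.append((alt / tot, tot) if tot else (np.nan, 0))
    return out


def _naive_stat(matrix, pops, num_fn, den_fn):
    freqs = {p: _naive_freqs(matrix, p) for p in set(pops)}
    num = den = 0.0
    for i in range(matrix.n_sites):
        if not matrix.sites["is_transversion"].iloc[i]:
            continue
        vals = [freqs[p][i] for p in pops]
        if any(t == 0 for _, t in vals):
            continue
        fs = [f for f, _ in vals]
        num += num_fn(*fs)
        den += den_fn(*fs)
    return num / den


def naive_f3(matrix, o, a, b):
    return _naive_stat(
        matrix, (o, a, b), lambda o_, a_, b_: (o_ - a_) * (o_ - b_),
        lambda *_: 1.0,
    )


def naive_d(matrix, w, x, y, z):
    return _naive_stat(
        matrix, (w, x, y, z),
        lambda w_, x_, y_, z_: (x_ - w_) * (y_ - z_),
        lambda w_, x_, y_, z_: (w_ + x_ - 2 * w_ * x_) * (y_ + z_ - 2 * y_ * z_),
    )


def naive_f4(matrix, a, o, x, c):
    return _naive_stat(
        matrix, (a, o, x, c),
        lambda a_, o_, x_, c_: (a_ - o_) * (x_ - c_),
        lambda *_: 1.0,
    )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_f3_d_f4_match_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(
            rng, n_sites=150, pops=("O", "O", "A", "A", "B", "C"),
            missing_rate=0.15,
        )
        assert abs(
            outgroup_f3(m, "O", "A", "B").estimate - naive_f3(m, "O", "A", "B")
        ) < 1e-12
        assert abs(
            d_statistic(m, "A", "B", "C", "O").estimate
            - naive_d(m, "A", "B", "C", "O")
        ) < 1e-12
        assert abs(
            f4(m, "A", "O", "B", "C").estimate - naive_f4(m, "A", "O", "B", "C")
        ) < 1e-12

    def test_estimate_invariant_to_block_span(self, rng):
        m = random_matrix(rng, n_sites=100, pops=("O", "A", "B", "B"))
        a = outgroup_f3(m, "O", "A", "B", block_span=50_000)
        b = outgroup_f3(m, "O", "A", "B", block_span=5_000_000)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-15)
        assert a.n_blocks > b.n_blocks


class TestOutgroupF3:
    def test_identical_fixed_populations_give_zero(self):
        calls = np.ones((10, 3), dtype=int)
        m = build_matrix(calls, ["O", "A", "B"], ploidy=[1, 1, 1],
                         chrom=["1"] * 5 + ["2"] * 5)
        assert outgroup_f3(m, "O", "A", "B").estimate == 0.0

    def test_hand_derived_haploid_value(self):
        # o=0 everywhere, a=[1,1,0,0], b=[1,0,1,0]: mean(a*b) = 0.25
        calls = np.array([[0, 1, 1], [0, 1, 0], [0, 0, 1], [0, 0, 0]])
        m = build_matrix(calls, ["O", "A", "B"], ploidy=[1, 1, 1],
                         chrom=["1", "1", "2", "2"])
        res = outgroup_f3(m, "O", "A", "B")
        assert res.estimate == pytest.approx(0.25)

    def test_symmetric_in_a_and_b(self, rng):
        m = random_matrix(rng, pops=("O", "A", "B", "B"))
        assert outgroup_f3(m, "O", "A", "B").estimate == pytest.approx(
            outgroup_f3(m, "O", "B", "A").estimate
        )


class TestDStatistic:
    def test_abba_baba_pattern_counts(self):
        # haploid: 3 ABBA (x=y=1, w=z=0), 1 BABA, 6 uninformative
        rows = [[0, 1, 1, 0]] * 3 + [[1, 0, 1, 0]] + [[0, 0, 0, 0]] * 3 + [[1, 1, 1, 1]] * 3
        m = build_matrix(
            np.array(rows), ["W", "X", "Y", "Z"], ploidy=[1] * 4,
            chrom=["1"] * 5 + ["2"] * 5,
        )
        res = d_statistic(m, "W", "X", "Y", "Z")
        assert res.estimate == pytest.approx((3 - 1) / (3 + 1))
        assert res.n_sites == 10

    def test_antisymmetric_in_w_and_x(self, rng):
        m = random_matrix(rng, pops=("W", "X", "Y", "Z"))
        a = d_statistic(m, "W", "X", "Y", "Z").estimate
        b = d_statistic(m, "X", "W", "Y", "Z").estimate
        assert a == pytest.approx(-b)

    def test_bounded_for_haploid_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = random_matrix(rng, n_sites=40, pops=("W", "X", "Y", "Z"),
                              haploid=True, missing_rate=0.0)
            try:
                d = d_statistic(m, "W", "X", "Y", "Z").estimate
            except InsufficientDataError:
                continue
            assert -1.0 <= d <= 1.0

    def test_no_informative_sites_distinguished_from_no_data(self):
        calls = np.zeros((6, 4), dtype=int)  # all fixed ref: no ABBA/BABA
        m = build_matrix(calls, ["W", "X", "Y", "Z"], ploidy=[1] * 4)
        with pytest.raises(InsufficientDataError, match="informative"):
            d_statistic(m, "W", "X", "Y", "Z")
        empty = np.full((6, 4), MISSING)
        m2 = build_matrix(empty, ["W", "X", "Y", "Z"], ploidy=[1] * 4)
        with pytest.raises(InsufficientDataError, match="no site has data"):
            d_statistic(m2, "W", "X", "Y", "Z")


class TestF4:
    def test_zero_when_x_equals_c(self, rng):
        m = random_matrix(rng, pops=("A", "O", "X", "X"))
        assert f4(m, "A", "O", "X", "X").estimate == pytest.approx(0.0)

    def test_antisymmetric_in_last_pair(self, rng):
        m = random_matrix(rng, pops=("A", "O", "X", "C"))
        assert f4(m, "A", "O", "X", "C").estimate == pytest.approx(
            -f4(m, "A", "O", "C", "X").estimate
        )


class TestF4Ratio:
    def test_alpha_zero_and_one_limits(self, rng):
        m = random_matrix(rng, n_sites=80, pops=("A", "B", "O", "C", "C"))
        assert f4_ratio(m, "A", "B", "O", "C", "C").estimate == pytest.approx(0.0)
        assert f4_ratio(m, "A", "B", "O", "B", "C").estimate == pytest.approx(1.0)

    def test_uninformative_reference_quartet_raises(self):
        calls = np.zeros((8, 5), dtype=int)
        m = build_matrix(calls, ["A", "B", "O", "X", "C"], ploidy=[1] * 5)
        with pytest.raises(InsufficientDataError, match="uninformative"):
            f4_ratio(m, "A", "B", "O", "X", "C")

    def test_recovers_simulated_admixture_fraction(self):
        from woolgen.simulate import AdmixtureGraphSpec, simulate_admixed_genotypes

        spec = AdmixtureGraphSpec(n_sites=50_000, alpha=0.25, unlinked=True)
        m, truth, _ = simulate_admixed_genotypes(spec, 77)
        res = f4_ratio(m, "EurA", "EurB", "GrayFox", "Woolly", "PCD_PaC")
        assert abs(res.estimate - 0.25) < 3 * res.se


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        est, se = block_jackknife([1.0] * 5, [2.0] * 5, [10] * 5)
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.0, abs=1e-14)

    def test_single_block_raises(self):
        with pytest.raises(InsufficientDataError, match=">=2 blocks"):
            block_jackknife([1.0], [2.0], [10])

    def test_three_block_weighted_value_matches_scalar_arithmetic(self):
        # independent scalar-arithmetic evaluation of the weighted jackknife
        num = [2.0, 3.0, 1.0]
        den = [4.0, 5.0, 3.0]
        w = [10.0, 20.0, 5.0]
        n = sum(w)
        theta = sum(num) / sum(den)
        loo = [
            (sum(num) - num[j]) / (sum(den) - den[j]) for j in range(3)
        ]
        h = [n / wj for wj in w]
        theta_j = 3 * theta - sum(
            (1 - w[j] / n) * loo[j] for j in range(3)
        )
        tau = [h[j] * theta - (h[j] - 1) * loo[j] for j in range(3)]
        var = sum((tau[j] - theta_j) ** 2 / (h[j] - 1) for j in range(3)) / 3
        est, se = block_jackknife(num, den, w)
        assert est == pytest.approx(theta)
        assert se == pytest.approx(np.sqrt(var))

    def test_se_shrinks_roughly_with_sqrt_sites(self):
        from woolgen.simulate import AdmixtureGraphSpec, simulate_admixed_genotypes

        ratios = []
        for seed in range(3):
            ses = []
            for n in (20_000, 40_000):
                spec = AdmixtureGraphSpec(n_sites=n, alpha=0.16, unlinked=True)
                m, _, _ = simulate_admixed_genotypes(spec, seed)
                ses.append(outgroup_f3(m, "GrayFox", "Woolly", "PCD").se)
            ratios.append(ses[1] / ses[0])
        assert 0.6 <= np.median(ratios) <= 0.8

    def test_blocks_never_cross_chromosomes(self):
        import pandas as pd

        sites = pd.DataFrame(
            {"chrom": ["1", "1", "2", "2"], "pos": [1, 2, 1, 2]}
        )
        blocks = assign_blocks(sites, block_span=10**9)
        assert list(blocks) == [0, 0, 1, 1]


class TestScanPanel:
    def test_panel_of_one_matches_single_call(self, rng):
        m = random_matrix(rng, pops=("O", "F", "B", "B"))
        table = scan_panel(m, "F", ["B"], {"stat": "f3", "outgroup": "O"})
        single = outgroup_f3(m, "O", "F", "B")
        assert table["estimate"].iloc[0] == pytest.approx(single.estimate)

    def test_empty_panel_returns_empty_table(self, rng):
        m = random_matrix(rng, pops=("O", "F", "B", "B"))
        table = scan_panel(m, "F", [], {"stat": "f3", "outgroup": "O"})
        assert len(table) == 0

    def test_failures_recorded_and_scan_continues(self, rng):
        m = random_matrix(rng, pops=("O", "F", "B", "B"))
        table = scan_panel(
            m, "F", ["B", "ghost"], {"stat": "f3", "outgroup": "O"}
        )
        assert len(table) == 2
        bad = table[table["panel"] == "ghost"]
        assert bad["error"].iloc[0] != ""
        assert np.isnan(bad["estimate"].iloc[0])

    def test_shared_drift_population_ranks_first(self):
        from woolgen.simulate import AdmixtureGraphSpec, simulate_admixed_genotypes

        # focal is mostly PCD: the PCD panel shares the longest drift path
        spec = AdmixtureGraphSpec(n_sites=30_000, alpha=0.1, unlinked=True)
        m, _, _ = simulate_admixed_genotypes(spec, 3)
        table = scan_panel(
            m, "Woolly", ["EurA", "EurB", "PCD", "PCD_PaC"],
            {"stat": "f3", "outgroup": "GrayFox"},
        )
        assert table["panel"].iloc[0] in ("PCD", "PCD_PaC")
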