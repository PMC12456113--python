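"""Summary statistics: brute-force oracles, f-statistic algebra, jackknife."""

import numpy as np
import pytest

from betulabc.coalsim import GenotypeMatrix, simulate_dataset
from betulabc.sumstats import (AlleleFrequencyTable, SumStatConfig,
                               allele_frequencies, block_jackknife,
                               expected_heterozygosity, f3, f4, f4_ratio,
                               hudson_fst, patterson_d, summary_vector)

from conftest import fixed_draw


def _random_matrix(rng, n_ind=20, n_loci=50, n_pops=2, missing=0.1):
    gt = rng.integers(0, 3, size=(n_ind, n_loci)).astype(np.int8)
    gt[rng.random(gt.shape) < missing] = -1
    pops = [f"p{i % n_pops}" for i in range(n_ind)]
    return GenotypeMatrix(gt, [f"i{i}" for i in range(n_ind)], pops)


def test_allele_frequencies_counting(toy_matrix):
    freqs = allele_frequencies(toy_matrix)
    # pa at locus 0: genotypes (0, 1) -> 1/4
    assert freqs.freq[freqs.index("pa"), 0] == pytest.approx(0.25)
    # pa at locus 4: (-1, 0) -> 0/2
    assert freqs.freq[freqs.index("pa"), 4] == pytest.approx(0.0)
    assert freqs.n_alleles[freqs.index("pa"), 4] == 2


def test_allele_frequencies_absent_population_flagged():
    gt = np.array([[0, -1], [1, -1]], dtype=np.int8)
    g = GenotypeMatrix(gt, ["i0", "i1"], ["pa", "pa"])
    freqs = allele_frequencies(g)
    assert np.isnan(freqs.freq[0, 1])
    assert freqs.n_alleles[0, 1] == 0


def test_allele_frequencies_match_naive_double_loop():
    rng = np.random.default_rng(2)
    for _ in range(5):
        g = _random_matrix(rng)
        freqs = allele_frequencies(g)
        for pi, pop in enumerate(freqs.populations):
            rows = [i for i, p in enumerate(g.populations) if p == pop]
            for locus in range(g.n_loci):
                derived = tot = 0
                for i in rows:
                    x = g.genotypes[i, locus]
                    if x >= 0:
                        derived += x
                        tot += 2
                if tot == 0:
                    assert np.isnan(freqs.freq[pi, locus])
                else:
                    assert freqs.freq[pi, locus] == pytest.approx(derived / tot)


def test_expected_heterozygosity_unbiased_formula():
    # p = 0.5 with n = 4 alleles: He = (4/3) * 0.5 = 2/3
    gt = np.array([[0], [2]], dtype=np.int8)
    g = GenotypeMatrix(gt, ["i0", "i1"], ["pa", "pa"])
    mean, var, he = expected_heterozygosity(allele_frequencies(g), "pa")
    assert mean == pytest.approx(2 / 3)
    # monomorphic locus: He = 0
    gt = np.array([[2], [2]], dtype=np.int8)
    g = GenotypeMatrix(gt, ["i0", "i1"], ["pa", "pa"])
    mean, _, _ = expected_heterozygosity(allele_frequencies(g), "pa")
    assert mean == 0.0


def test_hudson_fst_limits():
    rng = np.random.default_rng(3)
    # panmixia: both populations drawn from the same frequencies
    n, L = 100, 500
    p = rng.uniform(0.05, 0.95, L)
    gt = (rng.random((2 * n, L, 2)) < p[None, :, None]).sum(axis=2).astype(np.int8)
    g = GenotypeMatrix(gt, [f"i{i}" for i in range(2 * n)],
                       ["a"] * n + ["b"] * n)
    fst = hudson_fst(allele_frequencies(g), "a", "b")
    assert abs(fst) < 0.01
    # fixed difference
    gt = np.array([[2] * 5, [2] * 5, [0] * 5, [0] * 5], dtype=np.int8)
    g = GenotypeMatrix(gt, list("wxyz"), ["a", "a", "b", "b"])
    assert hudson_fst(allele_frequencies(g), "a", "b") == pytest.approx(1.0)


def test_patterson_d_pure_abba_is_one():
    # two identical ABBA sites: freqs (0, 1, 1, 0)
    gt = np.array([[0, 0], [2, 2], [2, 2], [0, 0]], dtype=np.int8)
    g = GenotypeMatrix(gt, list("wxyz"), ["p1", "p2", "p3", "o"])
    res = patterson_d(allele_frequencies(g), ("p1", "p2", "p3", "o"), n_blocks=2)
    assert res.statistic == pytest.approx(1.0)
    assert res.se == pytest.approx(0.0)
    assert res.n_informative == 2


def test_patterson_d_antisymmetry_and_range(quartet_scenario):
    d = fixed_draw(quartet_scenario, t_s12=1_000, t_s3=4_000, t_so=15_000)
    g = simulate_dataset(quartet_scenario, d, 400, seed=3)
    freqs = allele_frequencies(g)
    d12 = patterson_d(freqs, ("p1", "p2", "p3", "o"), n_blocks=20)
    d21 = patterson_d(freqs, ("p2", "p1", "p3", "o"), n_blocks=20)
    assert d12.statistic == pytest.approx(-d21.statistic)
    assert -1.0 <= d12.statistic <= 1.0


def test_patterson_d_null_under_symmetric_quartet(quartet_scenario):
    """No gene flow, symmetric sister pair: |Z| < 3 in >= 95% of replicates."""
    d = fixed_draw(quartet_scenario, t_s12=1_000, t_s3=4_000, t_so=15_000)
    ok = 0
    reps = 100
    for seed in range(reps):
        g = simulate_dataset(quartet_scenario, d, 400, seed=seed)
        res = patterson_d(allele_frequencies(g), ("p1", "p2", "p3", "o"),
                          n_blocks=20)
        ok += abs(res.z) < 3
    assert ok >= 0.95 * reps


def test_f4_algebra():
    rng = np.random.default_rng(8)
    g = _random_matrix(rng, n_ind=24, n_loci=60, n_pops=4, missing=0.0)
    freqs = allele_frequencies(g)
    pops = freqs.populations
    a, b, c, d = pops[0], pops[1], pops[2], pops[3]
    assert f4(freqs, a, b, c, d) == pytest.approx(-f4(freqs, b, a, c, d))
    assert f4(freqs, a, b, c, d) == pytest.approx(-f4(freqs, a, b, d, c))
    assert f4(freqs, a, a, c, d) == 0.0


def test_f4_ratio_recovers_admixture_proportion(admixture_scenario):
    """95% jackknife CI covers the generator proportion in >= 90% of reps."""
    ra = 0.3
    d = fixed_draw(admixture_scenario, t_adm=200, t_sa0=900, t_sab=2_000,
                   t_so=8_000, ra_adm=ra)
    num = ("a0", "o", "x", "b")
    den = ("a0", "o", "a", "b")
    covered = 0
    reps = 50
    for seed in range(reps):
        g = simulate_dataset(admixture_scenario, d, 2_000, seed=seed)
        res = f4_ratio(allele_frequencies(g), num, den, n_blocks=20)
        lo, hi = res.statistic - 1.96 * res.se, res.statistic + 1.96 * res.se
        covered += lo <= ra <= hi
    assert covered >= 0.9 * reps


def test_f4_ratio_degenerate_unadmixed_target(admixture_scenario):
    """Pulse proportion 1.0: the target is pure source, alpha within 3 SE of 1."""
    d = fixed_draw(admixture_scenario, t_adm=200, t_sa0=900, t_sab=2_000,
                   t_so=8_000, ra_adm=1.0)
    g = simulate_dataset(admixture_scenario, d, 2_000, seed=13)
    res = f4_ratio(allele_frequencies(g), ("a0", "o", "x", "b"),
                   ("a0", "o", "a", "b"), n_blocks=20)
    assert abs(res.statistic - 1.0) < 3 * res.se


def test_block_jackknife_textbook_equivalence():
    """Equal blocks reduce the weighted formula to the classic jackknife."""
    rng = np.random.default_rng(5)
    x = rng.normal(2.0, 1.0, 200)
    n_blocks = 20
    est, se = block_jackknife(x, n_blocks)
    # brute-force unweighted delete-one jackknife of the mean
    blocks = x.reshape(n_blocks, -1)
    theta_del = np.array([np.delete(blocks, j, axis=0).mean()
                          for j in range(n_blocks)])
    theta_full = x.mean()
    pseudo = n_blocks * theta_full - (n_blocks - 1) * theta_del
    est_ref = pseudo.mean()
    se_ref = np.sqrt(((pseudo - est_ref) ** 2).sum() / (n_blocks * (n_blocks - 1)))
    assert est == pytest.approx(est_ref)
    assert se == pytest.approx(se_ref)


def test_block_jackknife_degenerate_cases():
    x = np.full(40, 3.14)
    est, se = block_jackknife(x, 8)
    assert est == pytest.approx(3.14)
    assert se == pytest.approx(0.0)
    with pytest.raises(ValueError):
        block_jackknife(np.arange(5), 10)


def test_summary_vector_invariant_to_individual_order(two_pop_scenario):
    d = fixed_draw(two_pop_scenario, t_split=3_000.0)
    g = simulate_dataset(two_pop_scenario, d, 100, seed=5)
    config = SumStatConfig.default(g.population_names)
    v1 = summary_vector(g, config)
    rng = np.random.default_rng(0)
    # shuffle individuals within populations
    order = []
    for p in g.population_names:
        idx = g.population_indices(p)
        order.extend(rng.permutation(idx).tolist())
    g2 = GenotypeMatrix(g.genotypes[order],
                        [g.individuals[i] for i in order],
                        [g.populations[i] for i in order], list(g.loci))
    v2 = summary_vector(g2, config)
    np.testing.assert_allclose(v1, v2)


@pytest.mark.parametrize("n_pops", [2, 3, 4, 5, 6])
def test_summary_vector_length_formula(n_pops):
    """Length = 3P + 2*C(P,2) + T + Q for the configured triads/quartets."""
    from math import comb

    pops = [f"p{i}" for i in range(n_pops)]
    config = SumStatConfig.default(pops)
    expected = 3 * n_pops + 2 * comb(n_pops, 2) + len(config.triads) \
        + len(config.quartets)
    assert len(config.names()) == expected
    # and the default triad/quartet counts follow the combinatorics
    assert len(config.triads) == n_pops * comb(n_pops - 1, 2)
    assert len(config.quartets) == 3 * comb(n_pops, 4)


def test_summary_vector_stable_under_duplication(two_pop_scenario):
    """Doubling every individual changes He means only via the 1/(2n) bias term."""
    d = fixed_draw(two_pop_scenario, t_split=3_000.0)
    g = simulate_dataset(two_pop_scenario, d, 100, seed=6)
    config = SumStatConfig.default(g.population_names)
    v1 = summary_vector(g, config)
    dup = np.repeat(np.arange(g.n_individuals), 2)
    g2 = GenotypeMatrix(g.genotypes[dup],
                        [f"{g.individuals[i]}_{k}" for k, i in enumerate(dup)],
                        [g.populations[i] for i in dup], list(g.loci))
    v2 = summary_vector(g2, config)
    names = config.names()
    for i, name in enumerate(names):
        if name.startswith("he_mean"):
            n = 2 * 10
            assert abs(v1[i] - v2[i]) <= 1 / (2 * n) + 1e-9


def test_f3_admixed_target_is_negative(admixture_scenario):
    """An admixed population yields negative f3 against its two sources."""
    d = fixed_draw(admixture_scenario, t_adm=200, t_sa0=900, t_sab=2_000,
                   t_so=8_000, ra_adm=0.5)
    vals = []
    for seed in range(10):
        g = simulate_dataset(admixture_scenario, d, 1_000, seed=seed)
        vals.append(f3(allele_frequencies(g), "x", "a", "b"))
    assert np.mean(vals) < 0


# -- property-based invariants ----------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402

freq_arrays = st.lists(
    st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)),
    min_size=4, max_size=40)


@settings(max_examples=100, derandomize=True)
@given(freq_arrays)
def test_patterson_d_bounded_and_antisymmetric(freq_rows):
    arr = np.array(freq_rows, dtype=float).T  # (4 pops, L loci)
    table = AlleleFrequencyTable(["p1", "p2", "p3", "o"], arr,
                                 np.full(arr.shape, 20))
    try:
        d12 = patterson_d(table, ("p1", "p2", "p3", "o"), n_blocks=2)
        d21 = patterson_d(table, ("p2", "p1", "p3", "o"), n_blocks=2)
    except ValueError:
        return  # zero ABBA+BABA denominator: D undefined by contract
    assert -1.0 - 1e-9 <= d12.statistic <= 1.0 + 1e-9
    assert d12.statistic == pytest.approx(-d21.statistic, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=200),
       st.integers(min_value=2, max_value=4))
def test_block_jackknife_of_mean_recovers_mean(values, n_blocks):
    x = np.asarray(values, dtype=float)
    if len(x) < n_blocks:
        return
    est, se = block_jackknife(x, n_blocks)
    assert est == pytest.approx(x.mean(), abs=1e-6 + 1e-9 * np.abs(x).max())
    assert se >= 0.0
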