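"""Coalescent simulator: analytic laws, degenerate events, ascertainment,
and distributional agreement with msprime as the independent oracle."""

import numpy as np
import pytest
from scipy import stats

from betulabc.coalsim import (Genealogy, StrandedLineagesError,
                              drop_snp_mutation, simulate_dataset,
                              simulate_genealogy)
from betulabc.scenarios import (DemographicEvent, ParameterDraw,
                                PopulationSpec, PriorSpec, Scenario)

from conftest import fixed_draw

NE = PriorSpec("uniform", 100, 100_000)


def _panmictic(n_diploids=1):
    return Scenario("pan", (PopulationSpec("a", True, n_diploids, NE),), ())


def test_pairwise_tmrca_matches_closed_form():
    """E[T2] = 2N generations for two lineages in a diploid population."""
    s = _panmictic(1)
    d = ParameterDraw("pan", {"ne_a": 1_000.0}, 0)
    times = np.array([simulate_genealogy(s, d, seed).tmrca
                      for seed in range(20_000)])
    expected = 2_000.0
    se = times.std() / np.sqrt(len(times))
    assert abs(times.mean() - expected) < 3 * se


def test_no_cross_population_coalescence_before_split(two_pop_scenario):
    """With enormous within-population Ne every coalescence postdates the split."""
    d = fixed_draw(two_pop_scenario, t_split=1_000.0)
    d.values["ne_a"] = d.values["ne_b"] = 1e12
    g = simulate_genealogy(two_pop_scenario, d, seed=4)
    internal = g.node_time[g.n_leaves:]
    assert (internal > 1_000.0).all()


def test_admixture_with_full_proportion_equals_divergence():
    """ra = 1 sends every lineage to source 1, matching a plain divergence."""
    pops = (PopulationSpec("x", True, 5, NE), PopulationSpec("a", True, 5, NE),
            PopulationSpec("b", True, 5, NE))
    adm = Scenario("adm", pops, (
        DemographicEvent("mix", "admixture", PriorSpec("uniform", 90, 110),
                         ("x", "a", "b"), rate_prior=PriorSpec("uniform", 0.01, 0.99)),
        DemographicEvent("dab", "divergence", PriorSpec("uniform", 900, 1_100),
                         ("b", "a"))))
    div = Scenario("div", pops, (
        DemographicEvent("mix", "divergence", PriorSpec("uniform", 90, 110),
                         ("x", "a")),
        DemographicEvent("dab", "divergence", PriorSpec("uniform", 900, 1_100),
                         ("b", "a"))))
    d_adm = ParameterDraw("adm", {"ne_x": 500.0, "ne_a": 500.0, "ne_b": 500.0,
                                  "t_mix": 100.0, "ra_mix": 1.0, "t_dab": 1_000.0}, 0)
    d_div = ParameterDraw("div", {"ne_x": 500.0, "ne_a": 500.0, "ne_b": 500.0,
                                  "t_mix": 100.0, "t_dab": 1_000.0}, 0)
    t_adm = np.array([simulate_genealogy(adm, d_adm, s).tmrca for s in range(2_000)])
    t_div = np.array([simulate_genealogy(div, d_div, s + 50_000).tmrca
                      for s in range(2_000)])
    se = np.sqrt(t_adm.var() / 2_000 + t_div.var() / 2_000)
    assert abs(t_adm.mean() - t_div.mean()) < 3 * se


def test_stranded_lineages_raise():
    s = Scenario("stuck",
                 (PopulationSpec("a", True, 2, NE), PopulationSpec("b", True, 2, NE)),
                 ())
    d = ParameterDraw("stuck", {"ne_a": 100.0, "ne_b": 100.0}, 0)
    with pytest.raises(StrandedLineagesError):
        simulate_genealogy(s, d, seed=1)


def _star(n_leaves: int) -> Genealogy:
    parent = np.array([n_leaves] * n_leaves + [-1])
    times = np.array([0.0] * n_leaves + [1.0])
    pops = np.zeros(n_leaves + 1, dtype=np.int64)
    return Genealogy(parent, times, pops, n_leaves)


def test_snp_placement_uniform_on_star_tree():
    """Equal branch lengths: each leaf derived with probability 1/n (GOF)."""
    n = 8
    star = _star(n)
    counts = np.zeros(n)
    reps = 50_000
    for seed in range(reps):
        derived = drop_snp_mutation(star, seed)
        assert len(derived) == 1  # leaf branches only on a star tree
        counts[derived[0]] += 1
    chi2 = stats.chisquare(counts)
    assert chi2.pvalue > 0.01


def test_two_leaf_genealogy_always_polymorphic():
    g = Genealogy(np.array([2, 2, -1]), np.array([0.0, 0.0, 5.0]),
                  np.zeros(3, dtype=np.int64), 2)
    for seed in range(200):
        derived = drop_snp_mutation(g, seed)
        assert len(derived) == 1


def test_zero_length_branch_never_mutated():
    # leaf 2 sits at its parent's time: zero-length branch
    parent = np.array([3, 3, 4, 4, -1])
    times = np.array([0.0, 0.0, 5.0, 2.0, 5.0])
    g = Genealogy(parent, times, np.zeros(5, dtype=np.int64), 3)
    for seed in range(500):
        derived = set(drop_snp_mutation(g, seed).tolist())
        assert derived != {2}


def test_maf_ascertainment_and_missingness(two_pop_scenario):
    d = fixed_draw(two_pop_scenario, t_split=2_000.0)
    g = simulate_dataset(two_pop_scenario, d, 150, maf=0.025,
                         missing_rate=0.2, seed=9)
    assert g.genotypes.shape == (20, 150)
    assert (g.genotypes == -1).any()  # missingness applied
    for col in g.genotypes.T:
        called = col[col >= 0]
        freq = called.sum() / (2 * len(called))
        assert 0.025 <= freq <= 0.975

    clean = simulate_dataset(two_pop_scenario, d, 50, maf=0.025,
                             missing_rate=0.0, seed=9)
    assert not (clean.genotypes == -1).any()


def test_dataset_determinism(two_pop_scenario):
    d = fixed_draw(two_pop_scenario, t_split=2_000.0)
    a = simulate_dataset(two_pop_scenario, d, 80, seed=21)
    b = simulate_dataset(two_pop_scenario, d, 80, seed=21)
    c = simulate_dataset(two_pop_scenario, d, 80, seed=22)
    assert (a.genotypes == b.genotypes).all()
    assert (a.genotypes != c.genotypes).any()


def test_deep_split_raises_fst_above_panmixia(two_pop_scenario):
    """Population structure shows up as Hudson FST >> panmictic control."""
    from betulabc.sumstats import allele_frequencies, hudson_fst

    split = fixed_draw(two_pop_scenario, t_split=20_000.0)
    pan = fixed_draw(two_pop_scenario, t_split=1.0)  # immediate merge
    fst_split, fst_pan = [], []
    for seed in range(50):
        for draw, acc in ((split, fst_split), (pan, fst_pan)):
            g = simulate_dataset(two_pop_scenario, draw, 100, seed=seed)
            acc.append(hudson_fst(allele_frequencies(g), "a", "b"))
    assert np.mean(fst_split) > np.mean(fst_pan)
    assert np.mean(fst_split) > 0.3  # deep split: strong differentiation
    assert abs(np.mean(fst_pan)) < 0.05


# ---------------------------------------------------------------------------
# msprime as the independent coalescent oracle

def _three_pop_scenario():
    return Scenario(
        "three",
        (PopulationSpec("a", True, 2, NE), PopulationSpec("b", True, 2, NE),
         PopulationSpec("c", True, 2, NE)),
        (DemographicEvent("sb", "divergence", PriorSpec("uniform", 900, 1_100),
                          ("b", "a")),
         DemographicEvent("sc", "divergence", PriorSpec("uniform", 3_900, 4_100),
                          ("c", "a"))))


def test_joint_sfs_matches_msprime_oracle():
    """Joint derived-allele-count spectrum vs msprime branch-length AFS."""
    import msprime

    s = _three_pop_scenario()
    d = ParameterDraw("three", {"ne_a": 2_000.0, "ne_b": 2_000.0,
                                "ne_c": 2_000.0, "t_sb": 1_000.0,
                                "t_sc": 4_000.0}, 0)
    n_loci = 10_000
    g = simulate_dataset(s, d, n_loci, maf=0.0, seed=33)
    pops = np.asarray(g.populations)
    counts = np.zeros((5, 5, 5))
    for col in g.genotypes.T:
        idx = tuple(int(col[pops == p].sum()) for p in ("a", "b", "c"))
        counts[idx] += 1

    demography = msprime.Demography()
    for name in ("a", "b", "c"):
        demography.add_population(name=name, initial_size=2_000)
    demography.add_population(name="anc1", initial_size=2_000)
    demography.add_population(name="anc2", initial_size=2_000)
    demography.add_population_split(time=1_000, derived=["a", "b"], ancestral="anc1")
    demography.add_population_split(time=4_000, derived=["anc1", "c"], ancestral="anc2")
    reps = msprime.sim_ancestry(
        samples={"a": 2, "b": 2, "c": 2}, demography=demography,
        num_replicates=20_000, random_seed=77)
    expected = np.zeros((5, 5, 5))
    for ts in reps:
        sets = [ts.samples(population=i) for i in range(3)]
        afs = ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=False)
        # single conditioned mutation: normalise per tree (E[L_c / L_total],
        # not E[L_c] / E[L_total]) to match the fixed-S scheme
        expected += afs / afs.sum()
    expected[0, 0, 0] = expected[4, 4, 4] = 0.0
    expected = expected / expected.sum() * n_loci

    obs = counts.ravel()
    exp = expected.ravel()
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    # pool sparse cells so the chi-square approximation holds
    order = np.argsort(exp)
    obs, exp = obs[order], exp[order]
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 10:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    pooled_obs[-1] += acc_o
    pooled_exp[-1] += acc_e
    res = stats.chisquare(pooled_obs, f_exp=np.array(pooled_exp)
                          * sum(pooled_obs) / sum(pooled_exp))
    assert res.pvalue > 0.01


def test_two_pop_fst_matches_msprime_oracle(two_pop_scenario):
    """Hudson FST under a two-island split agrees with msprime simulation."""
    import msprime

    from betulabc.sumstats import allele_frequencies, hudson_fst

    ne, t_split = 5_000.0, 20_000.0  # split at 4N
    d = fixed_draw(two_pop_scenario, t_split=t_split)
    mine = []  # per-replicate (num_sum, den_sum): ratio pooled afterwards
    for seed in range(30):
        g = simulate_dataset(two_pop_scenario, d, 200, maf=0.0, seed=seed)
        freqs = allele_frequencies(g)
        pa, na = freqs.row("a")
        pb, nb = freqs.row("b")
        num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
        den = pa * (1 - pb) + pb * (1 - pa)
        mine.append((num.sum(), den.sum()))

    demography = msprime.Demography()
    demography.add_population(name="a", initial_size=ne)
    demography.add_population(name="b", initial_size=ne)
    demography.add_population(name="anc", initial_size=ne)
    demography.add_population_split(time=t_split, derived=["a", "b"], ancestral="anc")
    theirs = []
    rng = np.random.default_rng(5)
    for rep in range(30):
        # low per-site rate: effectively infinite sites, each hit at most once
        ts = msprime.sim_ancestry(
            samples={"a": 10, "b": 10}, demography=demography,
            sequence_length=200_000, num_replicates=None,
            random_seed=int(rng.integers(1, 2**31)))
        mts = msprime.sim_mutations(ts, rate=1e-8,
                                    random_seed=int(rng.integers(1, 2**31)),
                                    model=msprime.BinaryMutationModel())
        pa, pb, na, nb = [], [], [], []
        for var in mts.variants():
            gts = var.genotypes
            if len(var.alleles) != 2:
                continue
            pa.append(gts[:20].mean())
            pb.append(gts[20:].mean())
        pa, pb = np.array(pa), np.array(pb)
        num = ((pa - pb) ** 2 - pa * (1 - pa) / 19 - pb * (1 - pb) / 19)
        den = pa * (1 - pb) + pb * (1 - pa)
        theirs.append((num.sum(), den.sum()))

    def pooled_ratio_and_jackknife_se(pairs):
        pairs = np.asarray(pairs, dtype=float)
        tot = pairs.sum(axis=0)
        full = tot[0] / tot[1]
        loo = np.array([(tot[0] - n) / (tot[1] - d) for n, d in pairs])
        g = len(pairs)
        return full, np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())

    fst_mine, se_mine = pooled_ratio_and_jackknife_se(mine)
    fst_ref, se_ref = pooled_ratio_and_jackknife_se(theirs)
    se = np.sqrt(se_mine**2 + se_ref**2)
    assert abs(fst_mine - fst_ref) < 3 * se
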