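"""Shared fixtures: small synthetic scenarios and reusable heavy artefacts."""

from __future__ import annotations

import numpy as np
import pytest

from betulabc.coalsim import GenotypeMatrix
from betulabc.scenarios import (DemographicEvent, ParameterDraw,
                                PopulationSpec, PriorSpec, Scenario)

NE_PRIOR = PriorSpec("uniform", 1_000, 20_000)
PROP_PRIOR = PriorSpec("uniform", 0.05, 0.95)


def prior(lo, hi, dist="loguniform"):
    return PriorSpec(dist, lo, hi)


def fixed_draw(scenario: Scenario, **values) -> ParameterDraw:
    """A fully specified draw; unlisted Ne parameters default to 5000."""
    out = {}
    for name in scenario.parameter_names:
        if name in values:
            out[name] = float(values[name])
        elif name.startswith("ne_"):
            out[name] = 5_000.0
        else:
            raise KeyError(f"value required for {name}")
    return ParameterDraw(scenario.scenario_id, out, seed=0)


@pytest.fixture(scope="session")
def two_pop_scenario() -> Scenario:
    return Scenario(
        "two_pop",
        (PopulationSpec("a", True, 10, NE_PRIOR),
         PopulationSpec("b", True, 10, NE_PRIOR)),
        (DemographicEvent("split", "divergence", prior(500, 20_000), ("b", "a")),),
    )


@pytest.fixture(scope="session")
def quartet_scenario() -> Scenario:
    """Symmetric (p1, p2) quartet with outgroup and no gene flow: D is null."""
    return Scenario(
        "quartet_null",
        tuple(PopulationSpec(n, True, 10, NE_PRIOR)
              for n in ("p1", "p2", "p3", "o")),
        (DemographicEvent("s12", "divergence", prior(500, 1_500), ("p2", "p1")),
         DemographicEvent("s3", "divergence", prior(3_000, 6_000), ("p3", "p1")),
         DemographicEvent("so", "divergence", prior(10_000, 20_000), ("o", "p1"))),
        (("t_s3", "t_s12"), ("t_so", "t_s3")),
    )


@pytest.fixture(scope="session")
def admixture_scenario() -> Scenario:
    """x admixed from a (proportion ra) and b; a0 is a's unadmixed sister.

    alpha = f4(a0, o; x, b) / f4(a0, o; a, b) recovers ra.
    """
    return Scenario(
        "admix",
        tuple(PopulationSpec(n, True, 10, NE_PRIOR)
              for n in ("a0", "a", "b", "x", "o")),
        (DemographicEvent("adm", "admixture", prior(100, 400), ("x", "a", "b"),
                          rate_prior=PROP_PRIOR),
         DemographicEvent("sa0", "divergence", prior(600, 1_200), ("a0", "a")),
         DemographicEvent("sab", "divergence", prior(1_500, 3_000), ("a", "b")),
         DemographicEvent("so", "divergence", prior(5_000, 10_000), ("o", "b"))),
        (("t_sa0", "t_adm"), ("t_sab", "t_sa0"), ("t_so", "t_sab")),
    )


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    gt = np.array([
        [0, 1, 2, 0, -1],
        [1, 1, 0, 2, 0],
        [2, 0, 0, 1, 1],
        [0, 2, 1, -1, 2],
    ], dtype=np.int8)
    return GenotypeMatrix(gt, ["i0", "i1", "i2", "i3"],
                          ["pa", "pa", "pb", "pb"])


# ---------------------------------------------------------------------------
# heavy shared artefacts for the acceptance-style end-to-end checks

@pytest.fixture(scope="session")
def global_catalogue():
    from betulabc.scenarios import build_global_catalogue
    return build_global_catalogue()


@pytest.fixture(scope="session")
def desk_scale_run(global_catalogue):
    """Desk-scale self-consistency run shared across acceptance tests.

    Reference table of 2000 simulations per scenario (200 loci, 20 diploids
    per sampled population, MAF 0.025, seed 1); 10 pseudo-observed datasets
    under scenario 1 at mid-prior parameters (seeds 101-110); LDA-augmented
    500-tree model choice.
    """
    from betulabc.abcrf import (ScenarioChoice, append_lda_features,
                                build_reference_table)
    from betulabc.coalsim import simulate_dataset
    from betulabc.scenarios import midprior_draw
    from betulabc.sumstats import SumStatConfig, summary_vector

    cat = global_catalogue
    config = SumStatConfig.default([p.name for p in cat[0].sampled_populations])
    rt = build_reference_table(cat, 2_000, 200, maf=0.025, seed=1, config=config)
    draw = midprior_draw(cat[0])
    observed = np.stack([
        summary_vector(simulate_dataset(cat[0], draw, 200, maf=0.025, seed=s),
                       config)
        for s in range(101, 111)])
    rt_lda, obs_lda, _ = append_lda_features(rt, observed)
    first = ScenarioChoice(rt_lda, obs_lda[0], n_trees=500, seed=7).fit()
    results = [first] + [first.classify(o) for o in obs_lda[1:]]
    return {
        "catalogue": cat,
        "config": config,
        "table": rt,
        "draw": draw,
        "observed": observed,
        "choice_results": results,
    }
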