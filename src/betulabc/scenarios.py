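"""Demographic scenarios: populations, timed events, priors and constraints.

A :class:`Scenario` is a demographic model in the coalescent convention —
time runs backward from the present in generations.  Populations carry a
prior on their diploid effective size ``Ne``; events (divergence, admixture,
introgression, bottleneck, step Ne change) carry a prior on their time and,
where applicable, on a pulse/mixing proportion.  Order relations between
time parameters ("the ancestral split predates the derived split") are
enforced by rejection sampling.

Scenarios round-trip losslessly through YAML config files; the packaged
global catalogue for the six-population dwarf-birch system ships as four
such files under ``betulabc/data/scenarios``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "PriorSpec",
    "PopulationSpec",
    "DemographicEvent",
    "Scenario",
    "ParameterDraw",
    "ValidationReport",
    "validate_scenario",
    "sample_parameters",
    "build_global_catalogue",
    "read_scenario",
    "write_scenario",
]

EVENT_KINDS = ("divergence", "admixture", "introgression", "bottleneck", "ne_change")


@dataclass(frozen=True)
class PriorSpec:
    """A one-dimensional prior: ``uniform`` or ``loguniform`` on [lower, upper]."""

    distribution: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior distribution {self.distribution!r}")
        if not self.lower < self.upper:
            raise ValueError(f"prior requires lower < upper, got [{self.lower}, {self.upper}]")
        if self.distribution == "loguniform" and self.lower <= 0:
            raise ValueError("log-uniform prior requires lower > 0")

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.distribution == "uniform":
            return rng.uniform(self.lower, self.upper, size)
        lo, hi = math.log(self.lower), math.log(self.upper)
        return np.exp(rng.uniform(lo, hi, size))

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def midpoint(self) -> float:
        """Mid-prior value (geometric mid for log-uniform)."""
        if self.distribution == "uniform":
            return 0.5 * (self.lower + self.upper)
        return math.sqrt(self.lower * self.upper)

    def to_dict(self) -> dict:
        return {"dist": self.distribution, "lower": self.lower, "upper": self.upper}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(d["dist"], float(d["lower"]), float(d["upper"]))


@dataclass(frozen=True)
class PopulationSpec:
    """A (possibly unsampled "ghost") population with an Ne prior.

    ``n_diploids`` is the number of sampled diploid individuals; ghosts have 0.
    """

    name: str
    sampled: bool
    n_diploids: int
    ne_prior: PriorSpec

    def __post_init__(self) -> None:
        if self.n_diploids < 0:
            raise ValueError("n_diploids must be >= 0")
        if self.sampled and self.n_diploids < 1:
            raise ValueError(f"sampled population {self.name!r} needs n_diploids >= 1")
        if not self.sampled and self.n_diploids != 0:
            raise ValueError(f"ghost population {self.name!r} must have n_diploids = 0")


@dataclass(frozen=True)
class DemographicEvent:
    """One timed event, backward-time semantics.

    divergence     derived -> ancestor (all derived lineages move)
    admixture      admixed population's lineages move to source1 with
                   probability ``rate`` else source2 (forward: source1 and
                   source2 mix to found the admixed population)
    introgression  recipient lineages move to the donor with probability
                   ``rate`` (forward: a pulse of gene flow donor -> recipient)
    bottleneck     population's Ne is reduced to ``ne_prior`` draw on the
                   interval [time, time + duration]
    ne_change      population's Ne set to the ``ne_prior`` draw at ``time``
                   (further into the past)
    """

    event_id: str
    kind: str
    time_prior: PriorSpec
    participants: tuple[str, ...]
    rate_prior: PriorSpec | None = None
    duration_prior: PriorSpec | None = None
    ne_prior: PriorSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        n_expected = {"divergence": 2, "admixture": 3, "introgression": 2,
                      "bottleneck": 1, "ne_change": 1}[self.kind]
        if len(self.participants) != n_expected:
            raise ValueError(
                f"event {self.event_id!r} ({self.kind}) expects "
                f"{n_expected} participants, got {len(self.participants)}")
        if self.kind in ("admixture", "introgression") and self.rate_prior is None:
            raise ValueError(f"event {self.event_id!r} ({self.kind}) needs a rate prior")
        if self.kind == "bottleneck" and (self.duration_prior is None or self.ne_prior is None):
            raise ValueError(f"bottleneck {self.event_id!r} needs duration and Ne priors")
        if self.kind == "ne_change" and self.ne_prior is None:
            raise ValueError(f"ne_change {self.event_id!r} needs an Ne prior")

    @property
    def time_param(self) -> str:
        return f"t_{self.event_id}"

    def parameter_priors(self) -> dict[str, PriorSpec]:
        priors = {self.time_param: self.time_prior}
        if self.kind == "admixture":
            priors[f"ra_{self.event_id}"] = self.rate_prior
        elif self.kind == "introgression":
            priors[f"ri_{self.event_id}"] = self.rate_prior
        elif self.kind == "bottleneck":
            priors[f"d_{self.event_id}"] = self.duration_prior
            priors[f"ne_{self.event_id}"] = self.ne_prior
        elif self.kind == "ne_change":
            priors[f"ne_{self.event_id}"] = self.ne_prior
        return priors


@dataclass(frozen=True)
class Scenario:
    """A demographic model: populations, ordered events, order constraints.

    ``constraints`` is a list of ``(a, b)`` parameter-name pairs meaning
    ``a > b`` must hold in every accepted draw.
    """

    scenario_id: str
    populations: tuple[PopulationSpec, ...]
    events: tuple[DemographicEvent, ...]
    constraints: tuple[tuple[str, str], ...] = ()

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def population_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)

    @property
    def sampled_populations(self) -> tuple[PopulationSpec, ...]:
        return tuple(p for p in self.populations if p.sampled)

    @property
    def ghost_populations(self) -> tuple[PopulationSpec, ...]:
        return tuple(p for p in self.populations if not p.sampled)

    def parameter_priors(self) -> dict[str, PriorSpec]:
        """All free parameters, in deterministic order: Ne's then event params."""
        priors: dict[str, PriorSpec] = {}
        for p in self.populations:
            priors[f"ne_{p.name}"] = p.ne_prior
        for e in self.events:
            for name, prior in e.parameter_priors().items():
                if name in priors:
                    raise ValueError(f"duplicate parameter name {name!r}")
                priors[name] = prior
        return priors

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.parameter_priors())


@dataclass(frozen=True)
class ParameterDraw:
    """One accepted draw from a scenario's joint prior."""

    scenario_id: str
    values: dict[str, float]
    seed: int

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class ValidationReport:
    scenario_id: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


# ---------------------------------------------------------------------------
# validation

def _feasible_times(scenario: Scenario) -> dict[str, float] | None:
    """One constraint-satisfying assignment of time parameters, or None."""
    priors = {e.time_param: e.time_prior for e in scenario.events}
    rng = np.random.default_rng(0)
    for _ in range(5000):
        draw = {name: float(p.sample(rng)) for name, p in priors.items()}
        if all(draw.get(a, 0.0) > draw.get(b, 0.0)
               for a, b in scenario.constraints
               if a in draw and b in draw):
            return draw
    return None


def _constraint_graph_cyclic(constraints) -> bool:
    graph: dict[str, set[str]] = {}
    for a, b in constraints:
        graph.setdefault(a, set()).add(b)  # a > b: edge a -> b
        graph.setdefault(b, set())
    seen: dict[str, int] = {}

    def visit(node: str) -> bool:
        state = seen.get(node, 0)
        if state == 1:
            return True
        if state == 2:
            return False
        seen[node] = 1
        cyclic = any(visit(m) for m in graph[node])
        seen[node] = 2
        return cyclic

    return any(visit(n) for n in graph)


def validate_scenario(scenario: Scenario) -> ValidationReport:
    """Structural validation: proportion priors in (0,1), acyclic constraints,
    every sampled population reaching a single ancestral pool, ghosts merged.

    Report-based — never raises for model defects.
    """
    report = ValidationReport(scenario.scenario_id)
    names = set(scenario.population_names)
    if len(names) != len(scenario.populations):
        report.violations.append("duplicate population names")

    for e in scenario.events:
        for p in e.participants:
            if p not in names:
                report.violations.append(
                    f"event {e.event_id!r} references unknown population {p!r}")
        if e.rate_prior is not None and not (
                0.0 < e.rate_prior.lower and e.rate_prior.upper < 1.0):
            report.violations.append(
                f"event {e.event_id!r}: proportion prior "
                f"[{e.rate_prior.lower}, {e.rate_prior.upper}] out of range (0,1)")

    if _constraint_graph_cyclic(scenario.constraints):
        report.violations.append("cyclic order constraints")
        return report
    param_names = set()
    for e in scenario.events:
        param_names.update(e.parameter_priors())
    for a, b in scenario.constraints:
        for side in (a, b):
            if side not in param_names:
                report.violations.append(f"constraint references unknown parameter {side!r}")
    if report.violations:
        return report

    times = _feasible_times(scenario)
    if times is None:
        report.violations.append("no feasible time assignment satisfies the constraints")
        return report

    # trace population survival backward through the event sequence
    order = sorted(range(len(scenario.events)),
                   key=lambda i: (times[scenario.events[i].time_param], i))
    alive = dict.fromkeys(scenario.population_names, True)
    # merged[p] = pool label; union-find over the event graph
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in order:
        e = scenario.events[i]
        if e.kind == "divergence":
            derived, ancestor = e.participants
            if not alive.get(derived, False):
                report.violations.append(
                    f"event {e.event_id!r}: population {derived!r} already removed")
            alive[derived] = False
            union(derived, ancestor)
        elif e.kind == "admixture":
            admixed, s1, s2 = e.participants
            if not alive.get(admixed, False):
                report.violations.append(
                    f"event {e.event_id!r}: population {admixed!r} already removed")
            alive[admixed] = False
            union(admixed, s1)
            union(admixed, s2)
        elif e.kind == "introgression":
            recipient, donor = e.participants
            union(recipient, donor)

    pools = {find(n) for n in names}
    if len(pools) > 1:
        stranded = sorted(n for n in names if sum(find(m) == find(n) for m in names) < len(names))
        for p in scenario.sampled_populations:
            if any(find(p.name) != find(q) for q in names):
                report.violations.append(
                    f"unreachable: sampled population {p.name!r} never joins the root pool "
                    f"(pools: {sorted(pools)})")
                break
        else:
            report.violations.append(f"event graph leaves {len(pools)} disconnected pools")
        del stranded
    for g in scenario.ghost_populations:
        takes_part = any(g.name in e.participants for e in scenario.events)
        if not takes_part:
            report.violations.append(f"ghost population {g.name!r} never merged by any event")
    return report


# ---------------------------------------------------------------------------
# prior sampling

def sample_parameters(scenario: Scenario, n: int, seed: int) -> list[ParameterDraw]:
    """Draw ``n`` joint-prior samples satisfying all order constraints.

    Rejection sampling; a pure function of (scenario, n, seed).  Aborts if the
    acceptance rate over a probe batch falls below 0.1% (inconsistent
    constraints).
    """
    report = validate_scenario(scenario)
    if not report.ok:
        raise ValueError(f"invalid scenario {scenario.scenario_id!r}: {report.violations}")
    priors = scenario.parameter_priors()
    names = list(priors)
    rng = np.random.default_rng(seed)
    draws: list[ParameterDraw] = []
    attempts = 0
    while len(draws) < n:
        batch = max(256, 2 * (n - len(draws)))
        cols = {name: np.asarray(priors[name].sample(rng, batch)) for name in names}
        keep = np.ones(batch, dtype=bool)
        for a, b in scenario.constraints:
            keep &= cols[a] > cols[b]
        attempts += batch
        for i in np.flatnonzero(keep):
            if len(draws) >= n:
                break
            draws.append(ParameterDraw(
                scenario.scenario_id,
                {name: float(cols[name][i]) for name in names},
                seed))
        if attempts >= 100_000 and len(draws) < max(1, attempts // 1000):
            raise RuntimeError(
                f"rejection acceptance below 0.1% for scenario "
                f"{scenario.scenario_id!r}; constraints likely inconsistent")
    return draws


def midprior_draw(scenario: Scenario, seed: int = 0) -> ParameterDraw:
    """Deterministic draw at each prior's midpoint (geometric for log-uniform).

    If midpoints violate an order constraint the draw falls back to the first
    accepted rejection sample at the given seed.
    """
    values = {name: p.midpoint() for name, p in scenario.parameter_priors().items()}
    if all(values[a] > values[b] for a, b in scenario.constraints):
        return ParameterDraw(scenario.scenario_id, values, seed)
    return sample_parameters(scenario, 1, seed)[0]


# ---------------------------------------------------------------------------
# YAML config round-trip

def _event_to_dict(e: DemographicEvent) -> dict:
    d: dict = {"id": e.event_id, "kind": e.kind, "time": e.time_prior.to_dict()}
    if e.kind == "divergence":
        d["derived"], d["ancestor"] = e.participants
    elif e.kind == "admixture":
        d["admixed"], d["source1"], d["source2"] = e.participants
        d["rate"] = e.rate_prior.to_dict()
    elif e.kind == "introgression":
        d["recipient"], d["donor"] = e.participants
        d["rate"] = e.rate_prior.to_dict()
    elif e.kind == "bottleneck":
        (d["population"],) = e.participants
        d["duration"] = e.duration_prior.to_dict()
        d["ne"] = e.ne_prior.to_dict()
    elif e.kind == "ne_change":
        (d["population"],) = e.participants
        d["ne"] = e.ne_prior.to_dict()
    return d


def _event_from_dict(d: dict) -> DemographicEvent:
    kind = d["kind"]
    if kind == "divergence":
        participants = (d["derived"], d["ancestor"])
    elif kind == "admixture":
        participants = (d["admixed"], d["source1"], d["source2"])
    elif kind == "introgression":
        participants = (d["recipient"], d["donor"])
    else:
        participants = (d["population"],)
    return DemographicEvent(
        event_id=d["id"],
        kind=kind,
        time_prior=PriorSpec.from_dict(d["time"]),
        participants=participants,
        rate_prior=PriorSpec.from_dict(d["rate"]) if "rate" in d else None,
        duration_prior=PriorSpec.from_dict(d["duration"]) if "duration" in d else None,
        ne_prior=PriorSpec.from_dict(d["ne"]) if "ne" in d else None,
    )


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "scenario_id": s.scenario_id,
        "populations": [
            {"name": p.name, "sampled": p.sampled, "n_diploids": p.n_diploids,
             "ne": p.ne_prior.to_dict()}
            for p in s.populations],
        "events": [_event_to_dict(e) for e in s.events],
        "constraints": [f"{a} > {b}" for a, b in s.constraints],
    }


def scenario_from_dict(d: dict) -> Scenario:
    pops = tuple(
        PopulationSpec(p["name"], bool(p["sampled"]), int(p["n_diploids"]),
                       PriorSpec.from_dict(p["ne"]))
        for p in d["populations"])
    events = tuple(_event_from_dict(e) for e in d["events"])
    constraints = []
    for c in d.get("constraints", []):
        a, op, b = c.split()
        if op != ">":
            raise ValueError(f"unsupported constraint operator in {c!r}")
        constraints.append((a, b))
    return Scenario(d["scenario_id"], pops, events, tuple(constraints))


def write_scenario(s: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(s), fh, sort_keys=False)


def read_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# packaged global catalogue

def _iter_packaged_configs() -> Iterator:
    base = resources.files("betulabc").joinpath("data/scenarios")
    for name in sorted(p.name for p in base.iterdir() if p.name.endswith(".yaml")):
        yield base.joinpath(name)


def build_global_catalogue() -> list[Scenario]:
    """The four competing global models for the six-population birch system.

    Sampled populations: Nana, Svalbard, Exilis, Admixed (Glandulosa-west x
    Exilis), Glandulosa west, Glandulosa east; plus the unsampled ghost
    Tundrarum where the model includes it.  Scenario 1 (the best-supported
    topology) carries the full set of secondary-contact events; scenario 2
    has divergences only; scenario 3 restricts gene flow to North America;
    scenario 4 drops the Exilis-Glandulosa admixture.
    """
    catalogue = []
    for cfg in _iter_packaged_configs():
        with cfg.open() as fh:
            catalogue.append(scenario_from_dict(yaml.safe_load(fh)))
    return catalogue
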