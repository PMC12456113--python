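"""Structured-coalescent simulator for unlinked biallelic SNP loci.

Each locus is an independent genealogy of the pooled sample drawn under a
:class:`~betulabc.scenarios.Scenario` and one accepted parameter draw.
Within a population holding ``k`` lineages of diploid size ``Ne``,
coalescence occurs at rate ``k(k-1)/(4Ne)`` per generation (continuous-time
approximation); demographic events are exact cut points.  A single mutation
is then placed on a branch chosen proportional to branch length — the
fixed-S scheme that conditions every locus on being a SNP, so no mutation
rate is ever parameterised.  RAD-style ascertainment follows: per-genotype
missingness, then a pooled-sample minor-allele-frequency filter with failed
loci redrawn from scratch.

The hot loops are numba-compiled (see ``_kernels``); this module provides
the object API and the Scenario -> event-array compiler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .scenarios import ParameterDraw, Scenario

__all__ = [
    "Genealogy",
    "GenotypeMatrix",
    "StrandedLineagesError",
    "simulate_genealogy",
    "drop_snp_mutation",
    "simulate_dataset",
]

MISSING = -1


class StrandedLineagesError(RuntimeError):
    """Raised when the event schedule leaves lineages with no common ancestor."""


@dataclass
class Genealogy:
    """A coalescent tree: parent links, node times (generations), leaf map.

    Leaves are nodes ``0..n_leaves-1``; leaf ``2i`` and ``2i+1`` are the two
    allele copies of diploid individual ``i``.  Parent ids always exceed
    child ids; the root has parent ``-1``.
    """

    parent: np.ndarray
    node_time: np.ndarray
    node_pop: np.ndarray
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    @property
    def total_branch_length(self) -> float:
        p = self.parent
        has_parent = p >= 0
        return float(np.sum(self.node_time[p[has_parent]] - self.node_time[has_parent]))

    def branch_lengths(self) -> np.ndarray:
        """Branch length above each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = self.node_time[self.parent[has_parent]] - self.node_time[has_parent]
        return out

    def leaves_below(self, node: int) -> np.ndarray:
        state = np.zeros(self.n_nodes, dtype=bool)
        state[node] = True
        for i in range(self.n_nodes - 1, -1, -1):
            if self.parent[i] >= 0 and state[self.parent[i]]:
                state[i] = True
        return np.flatnonzero(state[: self.n_leaves])


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes: individuals x loci, values {0,1,2,-1}.

    Values count derived (ALT) alleles; ``-1`` marks a missing call.
    """

    genotypes: np.ndarray
    individuals: list[str]
    populations: list[str]
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be individuals x loci")
        n_ind, n_loci = self.genotypes.shape
        if len(self.individuals) != n_ind or len(self.populations) != n_ind:
            raise ValueError("individual/population labels must match row count")
        if not self.loci:
            self.loci = [f"locus_{i}" for i in range(n_loci)]
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be 0/1/2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.populations) == name)

    def subset_populations(self, names) -> "GenotypeMatrix":
        mask = np.isin(np.asarray(self.populations), list(names))
        return GenotypeMatrix(
            self.genotypes[mask],
            [i for i, m in zip(self.individuals, mask) if m],
            [p for p, m in zip(self.populations, mask) if m],
            list(self.loci),
        )


# ---------------------------------------------------------------------------
# Scenario -> kernel arrays

def compile_draw(scenario: Scenario, draw: ParameterDraw):
    """Flatten a (scenario, draw) pair into the kernel's event arrays.

    Returns (lineage_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_c,
    ev_param, pop_index, sample_layout) where sample_layout lists
    (population name, n_diploids) in individual order.
    """
    if draw.scenario_id != scenario.scenario_id:
        raise ValueError(
            f"draw for {draw.scenario_id!r} used with scenario {scenario.scenario_id!r}")
    pop_index = {p.name: i for i, p in enumerate(scenario.populations)}
    ne0 = np.array([draw[f"ne_{p.name}"] for p in scenario.populations], dtype=np.float64)

    rows: list[tuple[float, int, int, int, int, float]] = []
    for e in scenario.events:
        t = draw[e.time_param]
        if e.kind == "divergence":
            a, b = (pop_index[x] for x in e.participants)
            rows.append((t, 0, a, b, -1, 0.0))
        elif e.kind == "introgression":
            recipient, donor = (pop_index[x] for x in e.participants)
            rows.append((t, 1, recipient, donor, -1, draw[f"ri_{e.event_id}"]))
        elif e.kind == "admixture":
            admixed, s1, s2 = (pop_index[x] for x in e.participants)
            rows.append((t, 2, admixed, s1, s2, draw[f"ra_{e.event_id}"]))
        elif e.kind == "bottleneck":
            (p,) = (pop_index[x] for x in e.participants)
            rows.append((t, 3, p, -1, -1, draw[f"ne_{e.event_id}"]))
            rows.append((t + draw[f"d_{e.event_id}"], 3, p, -1, -1,
                         draw[f"ne_{e.participants[0]}"]))
        elif e.kind == "ne_change":
            (p,) = (pop_index[x] for x in e.participants)
            rows.append((t, 3, p, -1, -1, draw[f"ne_{e.event_id}"]))
    # ties broken by event-list position (stable sort on time only)
    order = sorted(range(len(rows)), key=lambda i: rows[i][0])
    rows = [rows[i] for i in order]

    ev_time = np.array([r[0] for r in rows], dtype=np.float64)
    ev_kind = np.array([r[1] for r in rows], dtype=np.int64)
    ev_a = np.array([r[2] for r in rows], dtype=np.int64)
    ev_b = np.array([r[3] for r in rows], dtype=np.int64)
    ev_c = np.array([r[4] for r in rows], dtype=np.int64)
    ev_param = np.array([r[5] for r in rows], dtype=np.float64)

    layout = [(p.name, p.n_diploids) for p in scenario.populations if p.sampled]
    lineage_pop0 = np.concatenate([
        np.full(2 * n, pop_index[name], dtype=np.int64) for name, n in layout
    ]) if layout else np.empty(0, dtype=np.int64)
    return (lineage_pop0, len(scenario.populations), ne0,
            ev_time, ev_kind, ev_a, ev_b, ev_c, ev_param, pop_index, layout)


def _raise_for_status(status: int, scenario: Scenario) -> None:
    if status == _kernels.STATUS_STRANDED:
        raise StrandedLineagesError(
            f"scenario {scenario.scenario_id!r}: lineages never reach a common "
            f"ancestor (check divergence/admixture events for populations "
            f"{[p.name for p in scenario.populations]})")
    if status == _kernels.STATUS_ZERO_LENGTH:
        raise RuntimeError("zero total branch length; cannot place a mutation")
    if status == _kernels.STATUS_MAF_EXHAUSTED:
        raise RuntimeError(
            "more than 10000 consecutive loci rejected by the MAF filter; "
            "parameters incompatible with the ascertainment threshold")


# ---------------------------------------------------------------------------
# public simulation API

def simulate_genealogy(scenario: Scenario, draw: ParameterDraw, seed: int) -> Genealogy:
    """One coalescent genealogy of the full pooled sample."""
    (lineage_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_param,
     _, _) = compile_draw(scenario, draw)
    n = len(lineage_pop0)
    if n < 2:
        raise ValueError("need at least two sampled lineages")
    parent = np.empty(2 * n - 1, dtype=np.int64)
    node_time = np.empty(2 * n - 1, dtype=np.float64)
    node_pop = np.empty(2 * n - 1, dtype=np.int64)
    _kernels._seed_rng(seed)
    status, n_nodes = _kernels._simulate_tree(
        lineage_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_param,
        parent, node_time, node_pop)
    _raise_for_status(status, scenario)
    return Genealogy(parent[:n_nodes], node_time[:n_nodes], node_pop[:n_nodes], n)


def drop_snp_mutation(genealogy: Genealogy, seed: int) -> np.ndarray:
    """Place one mutation, branch chosen proportional to length.

    Returns the sorted leaf ids carrying the derived allele (a proper,
    non-empty subset of the leaves).
    """
    if genealogy.n_leaves < 2:
        raise ValueError("genealogy needs at least two leaves")
    derived = np.zeros(genealogy.n_leaves, dtype=np.bool_)
    _kernels._seed_rng(seed)
    status = _kernels._drop_mutation(
        genealogy.parent, genealogy.node_time, genealogy.n_leaves,
        genealogy.n_nodes, derived)
    if status == _kernels.STATUS_ZERO_LENGTH:
        raise RuntimeError("zero total branch length; cannot place a mutation")
    return np.flatnonzero(derived)


def simulate_dataset(scenario: Scenario, draw: ParameterDraw, n_loci: int,
                     maf: float = 0.025, missing_rate: float = 0.0,
                     seed: int = 0) -> GenotypeMatrix:
    """Simulate a full SNP dataset with MAF ascertainment and missingness.

    Exactly ``n_loci`` loci are returned, each passing the pooled-sample
    minor-allele-frequency filter computed on non-missing genotypes; failing
    loci are redrawn (genealogy and mutation) so the ascertainment is by
    rejection.  Fully deterministic in (scenario, draw, n_loci, seed).
    """
    if not 0.0 <= maf < 0.5:
        raise ValueError("maf must be in [0, 0.5)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    (lineage_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_param,
     _, layout) = compile_draw(scenario, draw)
    n_ind = len(lineage_pop0) // 2
    genotypes = np.empty((n_ind, n_loci), dtype=np.int64)
    status = _kernels._simulate_dataset(
        lineage_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_param,
        n_loci, maf, missing_rate, int(seed), genotypes)
    _raise_for_status(status, scenario)
    individuals, populations = [], []
    for name, n in layout:
        for i in range(n):
            individuals.append(f"{name}_{i}")
            populations.append(name)
    return GenotypeMatrix(genotypes.astype(np.int8), individuals, populations)
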