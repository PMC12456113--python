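"""Summary statistics for ABC and stand-alone admixture tests.

Provides the fixed-order summary vector consumed by the random forest
(per-population gene diversity, monomorphy, pairwise Hudson FST and Nei
distance, f3/f4 for configured triads and quartets) and the stand-alone
Patterson's D and f4-ratio with weighted block-jackknife standard errors.

All statistics are deterministic functions of their inputs; no RNG here.
Frequencies are of the derived (ALT) allele.  For unpolarised data D is
sensitive to polarisation, while the frequency-difference forms of f3/f4
are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .coalsim import MISSING, GenotypeMatrix

__all__ = [
    "AlleleFrequencyTable",
    "FStatResult",
    "SumStatConfig",
    "allele_frequencies",
    "expected_heterozygosity",
    "hudson_fst",
    "nei_distance",
    "f3",
    "f4",
    "patterson_d",
    "f4_ratio",
    "block_jackknife",
    "summary_vector",
]


@dataclass
class AlleleFrequencyTable:
    """Per population x locus derived-allele frequencies and allele counts.

    ``freq`` is NaN where a population has no non-missing call at a locus
    (the "absent" flag); ``n_alleles`` is the non-missing allele count.
    """

    populations: list[str]
    freq: np.ndarray       # (P, L) float, NaN = absent
    n_alleles: np.ndarray  # (P, L) int

    def index(self, name: str) -> int:
        return self.populations.index(name)

    def row(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.index(name)
        return self.freq[i], self.n_alleles[i]


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyTable:
    pops = g.population_names
    gt = g.genotypes
    called = gt != MISSING
    freq = np.full((len(pops), g.n_loci), np.nan)
    n_alleles = np.zeros((len(pops), g.n_loci), dtype=np.int64)
    for i, p in enumerate(pops):
        rows = g.population_indices(p)
        sub = gt[rows]
        ok = called[rows]
        n = 2 * ok.sum(axis=0)
        derived = np.where(ok, sub, 0).sum(axis=0)
        n_alleles[i] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[i] = np.where(n > 0, derived / np.maximum(n, 1), np.nan)
    return AlleleFrequencyTable(pops, freq, n_alleles)


def expected_heterozygosity(freqs: AlleleFrequencyTable,
                            population: str) -> tuple[float, float, np.ndarray]:
    """Unbiased gene diversity He = n/(n-1) * (1 - p^2 - q^2), per locus.

    Returns (mean, variance, per-locus values) across loci where the
    population is present with at least two alleles.
    """
    p, n = freqs.row(population)
    ok = np.isfinite(p) & (n >= 2)
    if not ok.any():
        raise ValueError(f"population {population!r} absent at all loci")
    pp, nn = p[ok], n[ok]
    he = nn / (nn - 1) * (1.0 - pp**2 - (1.0 - pp) ** 2)
    return float(he.mean()), float(he.var()), he


def _pair_mask(freqs: AlleleFrequencyTable, a: str, b: str):
    pa, na = freqs.row(a)
    pb, nb = freqs.row(b)
    ok = np.isfinite(pa) & np.isfinite(pb)
    return pa[ok], na[ok], pb[ok], nb[ok]


def hudson_fst(freqs: AlleleFrequencyTable, pop_a: str, pop_b: str) -> float:
    """Hudson's FST as a ratio of locus-summed numerators and denominators.

    N_l = (pA-pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    D_l = pA(1-pB) + pB(1-pA)
    Requires >= 2 alleles per population per locus; undefined (NaN) when the
    summed denominator is zero.
    """
    pa, na, pb, nb = _pair_mask(freqs, pop_a, pop_b)
    ok = (na >= 2) & (nb >= 2)
    pa, na, pb, nb = pa[ok], na[ok], pb[ok], nb[ok]
    if pa.size == 0:
        return float("nan")
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    total = den.sum()
    if total == 0:
        return float("nan")
    return float(num.sum() / total)


def nei_distance(freqs: AlleleFrequencyTable, pop_a: str, pop_b: str) -> float:
    """Nei's (1972) standard genetic distance for biallelic loci."""
    pa, _, pb, _ = _pair_mask(freqs, pop_a, pop_b)
    if pa.size == 0:
        return float("nan")
    jab = np.mean(pa * pb + (1 - pa) * (1 - pb))
    ja = np.mean(pa**2 + (1 - pa) ** 2)
    jb = np.mean(pb**2 + (1 - pb) ** 2)
    if jab <= 0:
        return float("inf")
    return float(-np.log(jab / np.sqrt(ja * jb)))


def f3(freqs: AlleleFrequencyTable, target: str, a: str, b: str) -> float:
    """f3(target; A, B) = mean over loci of (pT - pA)(pT - pB), uncorrected."""
    pt, _ = freqs.row(target)
    pa, _ = freqs.row(a)
    pb, _ = freqs.row(b)
    ok = np.isfinite(pt) & np.isfinite(pa) & np.isfinite(pb)
    if not ok.any():
        return float("nan")
    return float(np.mean((pt[ok] - pa[ok]) * (pt[ok] - pb[ok])))


def f4(freqs: AlleleFrequencyTable, a: str, b: str, c: str, d: str) -> float:
    """f4(A,B; C,D) = mean over loci of (pA - pB)(pC - pD)."""
    rows = [freqs.row(x)[0] for x in (a, b, c, d)]
    ok = np.all(np.isfinite(rows), axis=0)
    if not ok.any():
        return float("nan")
    pa, pb, pc, pd = (r[ok] for r in rows)
    return float(np.mean((pa - pb) * (pc - pd)))


# ---------------------------------------------------------------------------
# block jackknife

def block_jackknife(contributions: np.ndarray, n_blocks: int,
                    statistic=None) -> tuple[float, float]:
    """Weighted delete-one block jackknife over contiguous locus blocks.

    ``contributions`` is (L,) or (L, k); ``statistic`` maps the column sums of
    the included loci to a scalar (default: mean of a single column, i.e.
    ``sum / count``, with the count passed implicitly by appending a column
    of ones).  Weights are block sizes (Busing et al. 1999), reducing to the
    textbook unweighted delete-one formula for equal blocks.
    Returns (jackknife estimate, standard error).
    """
    x = np.atleast_2d(np.asarray(contributions, dtype=float).T).T
    n = x.shape[0]
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if n < n_blocks:
        raise ValueError(f"fewer loci ({n}) than blocks ({n_blocks})")
    if statistic is None:
        if x.shape[1] != 1:
            raise ValueError("default statistic requires 1-D contributions")
        x = np.column_stack([x[:, 0], np.ones(n)])
        statistic = lambda s: s[0] / s[1]  # noqa: E731

    edges = np.linspace(0, n, n_blocks + 1).round().astype(int)
    sizes = np.diff(edges)
    total = x.sum(axis=0)
    # a deleted block may leave a degenerate statistic (0/0): the SE is then
    # honestly NaN rather than a warning-laden guess
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_full = float(statistic(total))
        theta_del = np.empty(n_blocks)
        for j in range(n_blocks):
            block_sum = x[edges[j]:edges[j + 1]].sum(axis=0)
            theta_del[j] = statistic(total - block_sum)

    g = n_blocks
    w = sizes / n
    theta_j = g * theta_full - np.sum((1 - w) * theta_del)
    tau = (theta_full - (1 - w) * theta_del) / w
    var = np.sum((tau - theta_j) ** 2 / (n / sizes - 1)) / g
    return float(theta_j), float(np.sqrt(max(var, 0.0)))


@dataclass
class FStatResult:
    """An f-statistic with its block-jackknife uncertainty."""

    statistic: float
    se: float
    n_blocks: int
    n_informative: int

    @property
    def z(self) -> float:
        if self.se > 0:
            return self.statistic / self.se
        return float("nan")


def patterson_d(freqs: AlleleFrequencyTable, quartet: tuple[str, str, str, str],
                n_blocks: int = 20) -> FStatResult:
    """Patterson's D over a (P1, P2, P3, O) quartet, ABBA/BABA form.

    D = sum[(1-p1)p2p3(1-p4) - p1(1-p2)p3(1-p4)] / sum[... + ...].
    A site is informative when its denominator contribution is positive.
    SE by weighted delete-one block jackknife over contiguous locus blocks.
    """
    rows = [freqs.row(x)[0] for x in quartet]
    ok = np.all(np.isfinite(rows), axis=0)
    p1, p2, p3, p4 = (r[ok] for r in rows)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    num = abba - baba
    den = abba + baba
    if den.sum() == 0:
        raise ValueError("D undefined: zero ABBA+BABA denominator")
    # report the full-data ratio; the jackknife supplies only the SE
    # (the bias-corrected jackknife mean can leave [-1, 1])
    _, se = block_jackknife(
        np.column_stack([num, den]), n_blocks, statistic=lambda s: s[0] / s[1])
    return FStatResult(float(num.sum() / den.sum()), se, n_blocks,
                       int(np.count_nonzero(den > 0)))


def f4_ratio(freqs: AlleleFrequencyTable,
             numerator: tuple[str, str, str, str],
             denominator: tuple[str, str, str, str],
             n_blocks: int = 20) -> FStatResult:
    """Admixture proportion alpha = f4(numerator) / f4(denominator).

    Both f4's use the same locus mask (all eight population slots present);
    the jackknife deletes blocks from numerator and denominator jointly and
    recomputes the ratio per block.
    """
    names = list(dict.fromkeys(numerator + denominator))
    rows = {x: freqs.row(x)[0] for x in names}
    ok = np.all([np.isfinite(rows[x]) for x in names], axis=0)

    def contrib(q):
        pa, pb, pc, pd = (rows[x][ok] for x in q)
        return (pa - pb) * (pc - pd)

    num = contrib(numerator)
    den = contrib(denominator)
    if abs(den.sum()) < 1e-12 * max(1, den.size):
        raise ValueError("f4-ratio undefined: denominator f4 is ~0")
    # full-data ratio as the point estimate, jackknife for the SE
    _, se = block_jackknife(
        np.column_stack([num, den]), n_blocks, statistic=lambda s: s[0] / s[1])
    informative = int(np.count_nonzero(den != 0))
    return FStatResult(float(num.sum() / den.sum()), se, n_blocks, informative)


# ---------------------------------------------------------------------------
# summary vector

@dataclass(frozen=True)
class SumStatConfig:
    """Which populations, triads and quartets enter the summary vector."""

    populations: tuple[str, ...]
    triads: tuple[tuple[str, str, str], ...]
    quartets: tuple[tuple[str, str, str, str], ...]

    @classmethod
    def default(cls, populations) -> "SumStatConfig":
        """All f3 triads (target; A, B) and all three pairings per 4-subset."""
        pops = tuple(populations)
        triads = tuple(
            (t, a, b)
            for t in pops
            for a, b in combinations([p for p in pops if p != t], 2))
        quartets = []
        for a, b, c, d in combinations(pops, 4):
            quartets += [(a, b, c, d), (a, c, b, d), (a, d, b, c)]
        return cls(pops, triads, tuple(quartets))

    def names(self) -> list[str]:
        """Deterministic statistic names, fixed order."""
        out = []
        for p in self.populations:
            out += [f"he_mean_{p}", f"he_var_{p}", f"mono_{p}"]
        for a, b in combinations(self.populations, 2):
            out.append(f"fst_{a}_{b}")
        for a, b in combinations(self.populations, 2):
            out.append(f"nei_{a}_{b}")
        for t, a, b in self.triads:
            out.append(f"f3_{t}_{a}_{b}")
        for a, b, c, d in self.quartets:
            out.append(f"f4_{a}_{b}_{c}_{d}")
        return out


def summary_vector(g: GenotypeMatrix, config: SumStatConfig | None = None) -> np.ndarray:
    """The fixed-order summary vector for one dataset.

    Length 3P + 2*C(P,2) + T + Q; invariant to individual ordering within
    populations.  Entries that cannot be computed (population absent,
    undefined ratio) come back non-finite and are imputed at reference-table
    assembly, not here.
    """
    if config is None:
        config = SumStatConfig.default(g.population_names)
    freqs = allele_frequencies(g)
    out: list[float] = []
    for p in config.populations:
        try:
            mean, var, he = expected_heterozygosity(freqs, p)
        except ValueError:
            mean = var = float("nan")
            he = np.array([])
        pp, nn = freqs.row(p)
        present = np.isfinite(pp)
        mono = float(np.mean((pp[present] == 0) | (pp[present] == 1))) \
            if present.any() else float("nan")
        out += [mean, var, mono]
    for a, b in combinations(config.populations, 2):
        out.append(hudson_fst(freqs, a, b))
    for a, b in combinations(config.populations, 2):
        out.append(nei_distance(freqs, a, b))
    for t, a, b in config.triads:
        out.append(f3(freqs, t, a, b))
    for a, b, c, d in config.quartets:
        out.append(f4(freqs, a, b, c, d))
    return np.asarray(out, dtype=float)
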