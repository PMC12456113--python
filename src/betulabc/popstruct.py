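"""Individual-based population-structure diagnostics.

Hamming genetic distances between diploid genotype vectors, great-circle
geographic distances, Mantel and partial Mantel permutation tests
(isolation by distance), non-metric multidimensional scaling with Kruskal
stress-1, and sample-size-corrected (rarefied) allelic richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .coalsim import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "NMDSResult",
    "hamming_distance",
    "haversine_matrix",
    "mantel",
    "partial_mantel",
    "nmds",
    "rarefied_allelic_richness",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Square symmetric non-negative matrix with zero diagonal."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count mismatch")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("distance matrix must be symmetric")
        if np.nanmin(v) < 0:
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def hamming_distance(g: GenotypeMatrix, scale_missing: bool = True) -> DistanceMatrix:
    """Pairwise allelic differences: d(i,j) = sum over loci of |g_i - g_j|.

    Loci with a missing call in either individual are skipped; with
    ``scale_missing`` the partial sum is rescaled by
    total loci / compared loci so distances stay comparable under uneven
    missingness.  Pairs with zero comparable loci get NaN.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    gt = g.genotypes.astype(float)
    called = gt != MISSING
    gt0 = np.where(called, gt, 0.0)
    n, L = gt.shape
    d = np.zeros((n, n))
    compared = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called
        diff = np.abs(gt0[i] - gt0) * both
        d[i] = diff.sum(axis=1)
        compared[i] = both.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if scale_missing:
            d = np.where(compared > 0, d * L / np.maximum(compared, 1), np.nan)
        else:
            d = np.where(compared > 0, d, np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(g.individuals))


def haversine_matrix(coords: np.ndarray, labels: list[str] | None = None,
                     radius_km: float = EARTH_RADIUS_KM) -> DistanceMatrix:
    """Great-circle distances (km) from (lat, lon) decimal degrees."""
    coords = np.asarray(coords, dtype=float)
    lat, lon = coords[:, 0], coords[:, 1]
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("latitude in [-90, 90], longitude in [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] \
        * np.sin(dlam / 2) ** 2
    d = 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    if labels is None:
        labels = [f"site_{i}" for i in range(len(lat))]
    return DistanceMatrix(d, labels)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def _check_aligned(*mats: DistanceMatrix) -> None:
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            raise ValueError("distance matrices must share labels and order")


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, tail: str = "greater") -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the lower triangles; the null permutes
    rows and columns of the second matrix simultaneously;
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) for the one-sided
    greater tail (default), mirrored for "less", doubled-tail for
    "two-sided".
    """
    _check_aligned(d1, d2)
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    x = d1.condensed()
    n = d1.n
    iu = np.triu_indices(n, k=1)
    y = d2.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Mantel r undefined for a constant matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][iu]
        r_p = np.corrcoef(x, yp)[0, 1]
        if tail == "greater":
            count += r_p >= r_obs
        elif tail == "less":
            count += r_p <= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm)


def partial_mantel(d1: DistanceMatrix, d2: DistanceMatrix, d3: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0,
                   tail: str = "greater") -> MantelResult:
    """Partial Mantel: correlation of d1 and d2 controlling for d3.

    Residualises the lower triangles of d1 and d2 on d3; the permutation
    null permutes the residualised second matrix (rows/columns jointly).
    """
    _check_aligned(d1, d2, d3)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    x, y, z = d1.values[iu], d2.values[iu], d3.values[iu]
    for name, v in (("d1", x), ("d2", y), ("d3", z)):
        if np.std(v) == 0:
            raise ValueError(f"constant matrix {name}")
    # a covariate collinear with the response makes the partial test
    # meaningless; a covariate equal to d2 just leaves zero residual (r = 0)
    if abs(np.corrcoef(x, z)[0, 1]) > 0.9999:
        raise ValueError("d1 collinear with the covariate")

    def residual(v):
        beta = np.polyfit(z, v, 1)
        return v - np.polyval(beta, z)

    rx = residual(x)
    # residualise d2 as a full matrix so permutation keeps structure
    ry_mat = np.zeros((n, n))
    beta_y = np.polyfit(z, y, 1)
    ry_mat[iu] = y - np.polyval(beta_y, z)
    ry_mat += ry_mat.T

    # perfectly explained matrices leave (numerically) zero residual:
    # the partial correlation is 0 by convention, not noise
    tol_x = 1e-10 * np.std(x)
    tol_y = 1e-10 * np.std(y)

    def safe_corr(a, b):
        if np.std(a) <= tol_x or np.std(b) <= tol_y:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = safe_corr(rx, ry_mat[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = ry_mat[np.ix_(perm, perm)][iu]
        r_p = safe_corr(rx, yp)
        if tail == "greater":
            count += r_p >= r_obs
        elif tail == "less":
            count += r_p <= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm)


# ---------------------------------------------------------------------------
# NMDS

@dataclass
class NMDSResult:
    configuration: np.ndarray
    stress: float
    n_restarts: int
    converged: bool


def _kruskal_stress(dhat: np.ndarray, dstar: np.ndarray) -> float:
    denom = np.sum(dhat**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - dstar) ** 2) / denom))


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(d: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         max_iter: int = 500, tol: float = 1e-7, seed: int = 0) -> NMDSResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Alternates isotonic regression of configuration distances on the rank
    order of the input dissimilarities with Guttman configuration updates.
    The first start is the classical (metric) scaling solution; further
    starts are random.  Returns the best configuration over restarts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.n
    iu = np.triu_indices(n, k=1)
    delta = d.values[iu]
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression()
    rng = np.random.default_rng(seed)

    best: NMDSResult | None = None
    for restart in range(n_restarts):
        if restart == 0:
            X = _classical_mds(d.values, k)
        else:
            X = rng.normal(size=(n, k)) * np.mean(delta)
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            diff = X[:, None, :] - X[None, :, :]
            dist = np.sqrt((diff**2).sum(axis=-1))
            dhat = dist[iu]
            # monotone regression on dissimilarity ranks
            fitted = iso.fit_transform(np.arange(len(order)), dhat[order])
            dstar = np.empty_like(dhat)
            dstar[order] = fitted
            stress = _kruskal_stress(dhat, dstar)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform toward the fitted disparities
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio_c = np.where(dhat > 0, dstar / dhat, 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio_c
            B += B.T
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
        if best is None or stress < best.stress:
            best = NMDSResult(X, stress, n_restarts, converged)
    return best


# ---------------------------------------------------------------------------
# rarefied allelic richness

def rarefied_allelic_richness(g: GenotypeMatrix, rarefaction_n: int):
    """Expected allele count in subsamples of ``rarefaction_n`` gene copies.

    Per population and locus: A_r = sum over alleles of
    1 - C(N - N_a, n) / C(N, n), the hypergeometric chance that allele ``a``
    appears at least once among ``n`` of the ``N`` sampled copies.  Returns
    (per-population mean over loci, per-population-per-locus matrix).
    """
    from scipy.special import gammaln

    if rarefaction_n < 2:
        raise ValueError("rarefaction_n must be >= 2")
    from .sumstats import allele_frequencies

    freqs = allele_frequencies(g)
    pops = freqs.populations
    P, L = freqs.freq.shape
    richness = np.full((P, L), np.nan)

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    for i in range(P):
        for l in range(L):
            N = freqs.n_alleles[i, l]
            if N < rarefaction_n:
                continue
            p = freqs.freq[i, l]
            counts = np.array([round(p * N), N - round(p * N)])
            a_r = 0.0
            for Na in counts:
                if Na == 0:
                    continue
                if N - Na < rarefaction_n:
                    a_r += 1.0
                else:
                    a_r += 1.0 - np.exp(log_comb(N - Na, rarefaction_n)
                                        - log_comb(N, rarefaction_n))
            richness[i, l] = a_r
    means = {}
    for i, p in enumerate(pops):
        row = richness[i]
        ok = np.isfinite(row)
        if not ok.any():
            raise ValueError(
                f"population {p!r}: no locus reaches {rarefaction_n} allele copies")
        means[p] = float(row[ok].mean())
    return means, richness
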