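"""Population-level statistics.

Implements the allele-count-based Reich-Patterson F_ST estimator with a
locus bootstrap, PCA of the individual x individual genotype covariance
matrix, per-site diversity metrics (Watterson's theta, pi, observed
heterozygosity), along-network river distances, and isolation-by-distance
via Mantel tests on linearised F_ST.

The Reich-Patterson estimator uses, per locus, with a alternate-allele
counts out of n called chromosomes in each population and
h = a(n - a) / (n(n - 1)):

    N_hat = (a1/n1 - a2/n2)^2 - h1/n1 - h2/n2
    D_hat = N_hat + h1 + h2

combined across loci as a ratio of sums F_ST = sum(N_hat) / sum(D_hat),
which keeps the estimator unbiased for small and unequal sample sizes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .vcfio import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Reich-Patterson F_ST
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_loci: int = 0
    significant_nonzero: bool | None = None


def _rp_terms(a1, n1, a2, n2):
    a1, n1, a2, n2 = (np.asarray(x, dtype=float) for x in (a1, n1, a2, n2))
    use = (n1 >= 2) & (n2 >= 2)
    a1, n1, a2, n2 = a1[use], n1[use], a2[use], n2[use]
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1))
    N = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    D = N + h1 + h2
    return N, D


def reich_patterson_fst(a1, n1, a2, n2) -> FstResult:
    """Reich-Patterson F_ST from per-locus allele counts (ratio of sums).

    Loci with fewer than 2 called chromosomes in either population are
    skipped.  If every usable locus is monomorphic in both populations the
    denominator is zero and a flagged NaN is returned.
    """
    N, D = _rp_terms(a1, n1, a2, n2)
    if len(D) == 0 or D.sum() == 0:
        logger.warning("reich_patterson_fst: undefined (denominator zero)")
        return FstResult(estimate=float("nan"), n_loci=len(D))
    return FstResult(estimate=float(N.sum() / D.sum()), n_loci=len(N))


def population_counts(gm: GenotypeMatrix, pops: np.ndarray, label) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (alt count, called chromosomes) for one population label."""
    sub = gm.take_samples(np.asarray(pops) == label)
    return sub.alt_counts()


def fst_bootstrap(
    gm: GenotypeMatrix,
    pops: np.ndarray | list,
    pop1,
    pop2,
    B: int = 1000,
    seed: int | None = None,
) -> FstResult:
    """F_ST between two labelled populations with a percentile locus bootstrap.

    Loci are resampled with replacement B times (B >= 100); the 95%
    percentile interval is reported and ``significant_nonzero`` is True when
    it excludes zero.
    """
    if B < 100:
        raise ValueError("bootstrap requires B >= 100")
    a1, n1 = population_counts(gm, pops, pop1)
    a2, n2 = population_counts(gm, pops, pop2)
    N, D = _rp_terms(a1, n1, a2, n2)
    if len(D) == 0 or D.sum() == 0:
        return FstResult(estimate=float("nan"), n_loci=len(D))
    est = float(N.sum() / D.sum())
    rng = np.random.default_rng(seed)
    L = len(N)
    idx = rng.integers(0, L, size=(B, L))
    Ns = N[idx].sum(axis=1)
    Ds = D[idx].sum(axis=1)
    reps = np.where(Ds != 0, Ns / np.where(Ds == 0, 1, Ds), np.nan)
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return FstResult(
        estimate=est,
        ci_low=float(lo),
        ci_high=float(hi),
        n_loci=L,
        significant_nonzero=bool(lo > 0 or hi < 0),
    )


def pairwise_fst(
    gm: GenotypeMatrix, pops: np.ndarray | list, B: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Matrix of pairwise Reich-Patterson F_ST point estimates."""
    pops = np.asarray(pops)
    labels = list(pd.unique(pops))
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for x, y in itertools.combinations(labels, 2):
        a1, n1 = population_counts(gm, pops, x)
        a2, n2 = population_counts(gm, pops, y)
        f = reich_patterson_fst(a1, n1, a2, n2).estimate
        mat.loc[x, y] = mat.loc[y, x] = f
    return mat


# ---------------------------------------------------------------------------
# PCA of the genotype covariance matrix
# ---------------------------------------------------------------------------


def pca_genotypes(gm: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA via eigendecomposition of the individual x individual covariance.

    Missing genotypes are mean-imputed per locus; loci are centred.  Returns
    ``(scores, varfrac)`` with PCs ordered by decreasing variance; scores are
    eigenvector coordinates scaled by the square root of the eigenvalues.
    """
    X = gm.imputed() if isinstance(gm, GenotypeMatrix) else np.asarray(gm, float)
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 individuals")
    Xc = X - X.mean(axis=0)
    C = Xc @ Xc.T / max(X.shape[1] - 1, 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0, None)
    total = vals.sum()
    if total == 0:
        logger.warning("pca_genotypes: constant matrix, all eigenvalues zero")
        return np.zeros_like(vecs), np.zeros_like(vals)
    return vecs * np.sqrt(vals), vals / total


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityReport:
    theta_w: float              # Watterson's estimator, per site
    pi: float                   # nucleotide diversity, per site
    het_obs: float              # mean observed heterozygosity per individual
    het_exp: float              # mean expected heterozygosity over variant loci
    n_segregating: int
    n_chromosomes: int


def diversity_metrics(
    gm: GenotypeMatrix, total_sites: int
) -> DiversityReport:
    """Per-site diversity from genotypes plus an invariant-site denominator.

    ``total_sites`` is the total number of surveyed sites (variant and
    invariant); it must be at least the number of variant loci.  theta_W is
    S over the harmonic number of (n - 1) with n the rounded mean number of
    called chromosomes; pi sums per-site heterozygosity 2p(1-p) * n/(n-1).
    """
    if total_sites < gm.n_loci:
        raise ValueError("total_sites must be >= number of variant loci")
    alt, n = gm.alt_counts()
    use = n >= 2
    if not use.any():
        logger.warning("diversity_metrics: no loci with >= 2 called chromosomes")
        return DiversityReport(np.nan, np.nan, np.nan, np.nan, 0, 0)
    alt, n = alt[use], n[use]
    p = alt / n
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    n_mean = int(round(n.mean()))
    harm = np.sum(1.0 / np.arange(1, n_mean)) if n_mean >= 2 else np.nan
    theta_w = (S / harm) / total_sites
    pi = float(np.sum(2 * p * (1 - p) * n / (n - 1)) / total_sites)
    het = (gm.gt == 1).sum(axis=1)
    called = gm.called().sum(axis=1)
    ok = called > 0
    het_obs = float(np.mean(het[ok] / called[ok])) if ok.any() else np.nan
    het_exp = float(np.mean(2 * p[seg] * (1 - p[seg]))) if S else 0.0
    return DiversityReport(
        theta_w=float(theta_w),
        pi=pi,
        het_obs=het_obs,
        het_exp=het_exp,
        n_segregating=S,
        n_chromosomes=n_mean,
    )


# ---------------------------------------------------------------------------
# River network distances
# ---------------------------------------------------------------------------


@dataclass
class RiverNetwork:
    """River network as an edge list with lengths (km) plus site positions.

    ``edges``: list of (edge_id, node_from, node_to, length_km).
    ``sites``: mapping site id -> (edge_id, offset_km from node_from).
    """

    edges: list[tuple[str, str, str, float]]
    sites: dict[str, tuple[str, float]]

    @classmethod
    def from_tsv(cls, edges_path, sites_path) -> "RiverNetwork":
        e = pd.read_csv(edges_path, sep="\t")
        s = pd.read_csv(sites_path, sep="\t")
        edges = [
            (str(r.edge_id), str(r.node_from), str(r.node_to), float(r.length_km))
            for r in e.itertuples()
        ]
        sites = {
            str(r.site_id): (str(r.edge_id), float(r.offset_km)) for r in s.itertuples()
        }
        return cls(edges=edges, sites=sites)


def river_distance(network: RiverNetwork, site_ids: list[str] | None = None) -> pd.DataFrame:
    """Along-network shortest-path distances (km) between sites.

    Sites are attached to their edge at the given offset; the result is a
    symmetric zero-diagonal DataFrame indexed by site id.
    """
    if site_ids is None:
        site_ids = list(network.sites)
    G = nx.Graph()
    edge_info = {}
    for eid, u, v, length in network.edges:
        if length < 0:
            raise ValueError(f"edge {eid} has negative length")
        edge_info[eid] = (u, v, length)
    # split each edge at the site offsets located on it
    on_edge: dict[str, list[tuple[float, str]]] = {eid: [] for eid in edge_info}
    for sid in site_ids:
        if sid not in network.sites:
            raise ValueError(f"site {sid!r} not on the network")
        eid, off = network.sites[sid]
        if eid not in edge_info:
            raise ValueError(f"site {sid!r} references unknown edge {eid!r}")
        u, v, length = edge_info[eid]
        if not 0 <= off <= length:
            raise ValueError(f"site {sid!r} offset {off} outside edge length {length}")
        on_edge[eid].append((off, f"site::{sid}"))
    for eid, (u, v, length) in edge_info.items():
        stops = sorted(on_edge[eid])
        chain = [(0.0, u)] + stops + [(length, v)]
        for (o1, n1), (o2, n2) in zip(chain, chain[1:]):
            w = o2 - o1
            if G.has_edge(n1, n2):
                w = min(w, G[n1][n2]["weight"])
            G.add_edge(n1, n2, weight=w)
    nodes = [f"site::{s}" for s in site_ids]
    mat = np.zeros((len(nodes), len(nodes)))
    for i, a in enumerate(nodes):
        lengths = nx.single_source_dijkstra_path_length(G, a, weight="weight")
        for j, b in enumerate(nodes):
            if b not in lengths:
                raise ValueError(f"site {site_ids[j]!r} disconnected from {site_ids[i]!r}")
            mat[i, j] = lengths[b]
    return pd.DataFrame(mat, index=site_ids, columns=site_ids)


# ---------------------------------------------------------------------------
# Isolation by distance (Mantel)
# ---------------------------------------------------------------------------


@dataclass
class IbdResult:
    slope: float
    mantel_r: float
    p_value: float
    n_pairs: int


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def ibd_test(
    fst: np.ndarray | pd.DataFrame,
    distance: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> IbdResult:
    """Isolation-by-distance Mantel test on linearised F_ST.

    The response is F_ST / (1 - F_ST) pairwise (entries with F_ST = 1 are
    excluded with a warning); the Mantel statistic is the Pearson
    correlation of the off-diagonal vectors and the one-sided p-value comes
    from joint row/column permutations of the genetic matrix:
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).  With ``exact=True`` all
    n! permutations are enumerated and p = #{r_perm >= r_obs} / n!
    (the identity permutation counts, so p >= 1/n!).
    """
    F = np.asarray(fst, dtype=float)
    D = np.asarray(distance, dtype=float)
    if F.shape != D.shape or F.shape[0] != F.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(F, F.T, equal_nan=True) and np.allclose(D, D.T)):
        raise ValueError("matrices must be symmetric")
    G = F.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        G = G / (1 - G)
    if np.isinf(G).any():
        logger.warning("ibd_test: F_ST = 1 entries excluded from the Mantel vectors")
        G[np.isinf(G)] = np.nan
    g, d = _offdiag(G), _offdiag(D)
    r_obs = _pearson(g, d)
    ok = np.isfinite(g) & np.isfinite(d)
    slope = float(np.polyfit(d[ok], g[ok], 1)[0])
    n = F.shape[0]
    if exact:
        perms = itertools.permutations(range(n))
        count = total = 0
        for p in perms:
            rp = _pearson(_offdiag(G[np.ix_(p, p)]), d)
            count += rp >= r_obs - 1e-12
            total += 1
        pval = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            rp = _pearson(_offdiag(G[np.ix_(p, p)]), d)
            count += rp >= r_obs - 1e-12
        pval = (count + 1) / (n_perm + 1)
        n_used = n_perm
    return IbdResult(slope=slope, mantel_r=r_obs, p_value=float(pval), n_pairs=int(ok.sum()))
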