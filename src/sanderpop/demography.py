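"""Joint-SFS construction and two-population divergence-time inference.

The observed joint site-frequency spectrum (SFS) of two populations is
summarised on a grid of alternate-allele counts ``(i, j)`` out of
``(n1, n2)`` sampled chromosomes.  Two demographic models are fitted by
Poisson composite likelihood over the SFS cells:

``split_nomig``
    An ancestral population at neutral equilibrium splits into two
    populations of relative sizes nu1 and nu2 (nu1 + nu2 <= 1) that then
    drift independently for time T (in units of 2 N_ref generations).

``split_mig``
    As above, with asymmetric bidirectional migration after the split
    (scaled rates M12, M21 = 2 N_ref m, dadi convention).

Expected spectra are computed on a discrete Wright-Fisher frequency grid:
ancestral standing variation is initialised from the diffusion equilibrium
density (theta / x per unit frequency, i.e. weight 1/a on count a), each
daughter population's allele-frequency distribution evolves by exact
binomial WF transitions of a grid population rescaled by nu, new mutations
are injected at count one each generation, and sampling to (n1, n2) uses
binomial draws from the grid frequencies.  Non-integer generation counts
are handled by linear interpolation between the bracketing integers.  For
``split_mig`` the full joint frequency grid is propagated with migration
mixing each generation (coarse grid; documented as approximate).  A
stochastic msprime (discrete-time WF) backend provides an independent
oracle for the matrix computation.

The composite-likelihood scale theta is profiled analytically
(theta_hat = sum(obs) / sum(model)); real-time scaling uses
N_ref = theta_hat / (4 mu L) and T_years = T * 2 N_ref * generation_time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .vcfio import GenotypeMatrix

logger = logging.getLogger(__name__)

MODELS = ("split_nomig", "split_mig")

#: Mutation rates (per site per generation) used for real-time scaling.
DEFAULT_MUTATION_RATES = {
    "human": 2.5e-8,
    "cichlid": 3.5e-9,
    "herring": 2e-9,
    "fish_average": 5.97e-9,
}

DEFAULT_GENERATION_TIME = 3.0  # years


# ---------------------------------------------------------------------------
# JointSFS container
# ---------------------------------------------------------------------------


@dataclass
class JointSFS:
    """Two-population SFS: entry (i, j) = (expected) count of sites with
    alternate-allele counts i of n1 and j of n2.

    The fixed corners (0, 0) and (n1, n2) are always masked; a folded
    spectrum additionally masks the major-allele half (total count above
    (n1 + n2) / 2).
    """

    data: np.ndarray
    folded: bool = False
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("joint SFS must be 2-dimensional")
        if np.any(self.data < -1e-9):
            raise ValueError("SFS entries must be non-negative")
        if self.mask is None:
            self.mask = default_mask(self.n1, self.n2, self.folded)

    @property
    def n1(self) -> int:
        return self.data.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.data.shape[1] - 1

    def unmasked(self) -> np.ndarray:
        return self.data[~self.mask]

    def total(self) -> float:
        return float(self.unmasked().sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.data.copy(), self.folded, self.mask.copy())


def default_mask(n1: int, n2: int, folded: bool) -> np.ndarray:
    mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    mask[0, 0] = mask[n1, n2] = True
    if folded:
        i = np.arange(n1 + 1)[:, None] + np.arange(n2 + 1)[None, :]
        mask |= i > (n1 + n2) / 2
    return mask


def fold_sfs(sfs: JointSFS) -> JointSFS:
    """Fold to minor-allele orientation: add each cell to its complement,
    halving cells on the ambiguous diagonal (total count = (n1+n2)/2)."""
    if sfs.folded:
        return sfs.copy()
    d = sfs.data
    rev = d[::-1, ::-1]
    tot = np.arange(sfs.n1 + 1)[:, None] + np.arange(sfs.n2 + 1)[None, :]
    half = (sfs.n1 + sfs.n2) / 2
    out = np.where(tot < half, d + rev, np.where(tot == half, (d + rev) / 2, 0.0))
    return JointSFS(out, folded=True)


def joint_sfs(
    gm: GenotypeMatrix,
    pops: np.ndarray | list,
    pop1,
    pop2,
    fold: bool = True,
    project: tuple[int, int] | None = None,
) -> JointSFS:
    """Tabulate the joint SFS of two labelled populations.

    Without ``project``, only sites fully called in both populations are
    counted at the full sample sizes.  With ``project=(n1', n2')`` every
    site with at least that many called chromosomes per population
    contributes its hypergeometric projection (mean over down-samplings),
    which is how missing data is usually absorbed.
    """
    pops = np.asarray(pops)
    g1 = gm.take_samples(pops == pop1)
    g2 = gm.take_samples(pops == pop2)
    a1, m1 = g1.alt_counts()
    a2, m2 = g2.alt_counts()
    if project is None:
        n1, n2 = 2 * g1.n_samples, 2 * g2.n_samples
        use = (m1 == n1) & (m2 == n2)
        data = np.zeros((n1 + 1, n2 + 1))
        np.add.at(data, (a1[use], a2[use]), 1.0)
    else:
        n1, n2 = project
        data = np.zeros((n1 + 1, n2 + 1))
        use = np.flatnonzero((m1 >= n1) & (m2 >= n2))
        for s in use:
            p1 = _hypergeom_row(a1[s], m1[s], n1)
            p2 = _hypergeom_row(a2[s], m2[s], n2)
            data += np.outer(p1, p2)
    out = JointSFS(data, folded=False)
    return fold_sfs(out) if fold else out


def _hypergeom_row(a: int, m: int, n: int) -> np.ndarray:
    """P(k alt of n drawn | a alt of m chromosomes), k = 0..n."""
    k = np.arange(n + 1)
    return stats.hypergeom.pmf(k, m, a, n)


def project_sfs(sfs: JointSFS, sizes: tuple[int, int]) -> JointSFS:
    """Hypergeometric down-projection of both axes to ``sizes``.

    Mass is preserved up to what moves into the masked corners.  A folded
    input is projected on its stored grid and re-folded.
    """
    n1p, n2p = sizes
    if n1p > sfs.n1 or n2p > sfs.n2:
        raise ValueError("can only project downward")
    P1 = np.stack([_hypergeom_row(i, sfs.n1, n1p) for i in range(sfs.n1 + 1)])
    P2 = np.stack([_hypergeom_row(j, sfs.n2, n2p) for j in range(sfs.n2 + 1)])
    d = np.where(sfs.mask, 0.0, sfs.data)
    out = P1.T @ d @ P2
    res = JointSFS(out, folded=False)
    return fold_sfs(res) if sfs.folded else res


# -- dadi-compatible flat text serialization --------------------------------


def write_sfs(sfs: JointSFS, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{sfs.n1 + 1} {sfs.n2 + 1} {'folded' if sfs.folded else 'unfolded'}\n")
        fh.write(" ".join(f"{x:.8g}" for x in sfs.data.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in sfs.mask.ravel()) + "\n")


def read_sfs(path: str | Path) -> JointSFS:
    with open(path) as fh:
        header = fh.readline().split()
        d1, d2, foldtag = int(header[0]), int(header[1]), header[2]
        data = np.array(fh.readline().split(), dtype=float).reshape(d1, d2)
        mask = np.array(fh.readline().split(), dtype=int).astype(bool).reshape(d1, d2)
    return JointSFS(data, folded=foldtag == "folded", mask=mask)


# ---------------------------------------------------------------------------
# Expected SFS: discrete Wright-Fisher matrix backend
# ---------------------------------------------------------------------------


def _wf_matrix(two_n: int) -> np.ndarray:
    """Binomial WF transition matrix; rows = current count, cols = next."""
    k = np.arange(two_n + 1)
    return stats.binom.pmf(k[None, :], two_n, (k / two_n)[:, None])


def _hyper_sample(two_n: int, n: int) -> np.ndarray:
    """(two_n+1, n+1) matrix: sample n of two_n chromosomes without
    replacement given the population count (exact for equilibrium spectra)."""
    k = np.arange(two_n + 1)
    s = np.arange(n + 1)
    return stats.hypergeom.pmf(s[None, :], two_n, k[:, None], n)


def _check_stochastic(M: np.ndarray, what: str) -> None:
    leak = np.abs(M.sum(axis=1) - 1).max()
    if leak > 1e-6:
        raise FloatingPointError(f"{what}: probability mass leak {leak:.2e}")


def _daughter_size(nu: float, two_n_anc: int) -> int:
    return max(2, int(round(nu * two_n_anc)))


def _nomig_expected(
    nu1: float, nu2: float, T: float, n1: int, n2: int, grid_diploids: int
) -> np.ndarray:
    """Unfolded expected joint SFS per unit theta for the isolation model."""
    two_n = 2 * grid_diploids
    a = np.arange(1, two_n)
    w = 1.0 / a  # diffusion equilibrium standing variation per unit theta
    g_real = T * two_n
    g0 = int(np.floor(g_real))
    frac = g_real - g0

    # Per-daughter conditional sample distributions given the ancestral
    # count, at g0 and g0 + 1 post-split generations, plus the new-mutation
    # marginals.  Generation 1 is the founding draw from the ancestral
    # frequency at the daughter size (matching discrete-time WF splits);
    # g = 0 samples straight from the ancestral population.  Fractional
    # daughter sizes nu * 2N are handled by linear interpolation between
    # the bracketing integer sizes (in the sample domain), which keeps the
    # likelihood surface smooth in nu.
    def _at_size(two_nj: int, nu: float, n: int):
        M = _wf_matrix(two_nj)
        _check_stochastic(M, "WF transition")
        B = stats.binom.pmf(
            np.arange(two_nj + 1)[None, :], two_nj, (a / two_n)[:, None]
        )  # founding draw: (two_n-1, two_nj+1)
        S = _hyper_sample(two_nj, n)
        if g0 == 0:
            c0 = stats.hypergeom.pmf(np.arange(n + 1)[None, :], two_n, a[:, None], n)
        else:
            c0 = B @ np.linalg.matrix_power(M, g0 - 1) @ S
        c1 = B @ np.linalg.matrix_power(M, g0) @ S
        # mutations enter at count 1 (rate nu/2 per unit theta per
        # generation) in each post-split generation, then drift
        v = np.zeros(two_nj + 1)
        for _ in range(g0):
            v = v @ M
            v[1] += nu / 2
        n0 = v @ S
        n1 = ((v @ M) + np.eye(two_nj + 1)[1] * (nu / 2)) @ S
        return (c0, c1), (n0, n1)

    conds, news = [], []
    for nu, n in ((nu1, n1), (nu2, n2)):
        size = nu * two_n
        s0 = int(np.floor(size))
        sw = size - s0
        if s0 < max(n, 2):
            raise ValueError(
                f"grid population ({size:.1f} chromosomes) smaller than sample "
                f"size {n}; increase grid_diploids"
            )
        (c0a, c1a), (n0a, n1a) = _at_size(s0, nu, n)
        if sw == 0:
            conds.append((c0a, c1a))
            news.append((n0a, n1a))
        else:
            (c0b, c1b), (n0b, n1b) = _at_size(s0 + 1, nu, n)
            conds.append(
                ((1 - sw) * c0a + sw * c0b, (1 - sw) * c1a + sw * c1b)
            )
            news.append(((1 - sw) * n0a + sw * n0b, (1 - sw) * n1a + sw * n1b))

    def assemble(k: int) -> np.ndarray:
        c1, c2 = conds[0][k], conds[1][k]
        E = c1.T @ (w[:, None] * c2)
        E[:, 0] += news[0][k]
        E[0, :] += news[1][k]
        return E

    E0 = assemble(0)
    if frac == 0:
        return E0
    return (1 - frac) * E0 + frac * assemble(1)


def _mig_expected(
    nu1: float,
    nu2: float,
    T: float,
    M12: float,
    M21: float,
    n1: int,
    n2: int,
    grid_diploids: int,
) -> np.ndarray:
    """Unfolded expected joint SFS per unit theta, isolation-with-migration.

    Propagates the full joint allele-frequency distribution on a coarse
    grid; migration deterministically mixes expected frequencies each
    generation (fraction m12 = M12 / (2 N_ref) of population 1's gene pool
    drawn from population 2, and vice versa), then binomial drift acts in
    each population.
    """
    two_n = 2 * grid_diploids
    a = np.arange(1, two_n)
    w = 1.0 / a
    tn1 = _daughter_size(nu1, two_n)
    tn2 = _daughter_size(nu2, two_n)
    if tn1 < n1 or tn2 < n2:
        raise ValueError("grid population smaller than sample size; increase grid_diploids")
    m12, m21 = M12 / two_n, M21 / two_n
    if not (0 <= m12 <= 1 and 0 <= m21 <= 1):
        raise ValueError("per-generation migration fraction outside [0, 1]")

    B1 = stats.binom.pmf(np.arange(tn1 + 1)[None, :], tn1, (a / two_n)[:, None])
    B2 = stats.binom.pmf(np.arange(tn2 + 1)[None, :], tn2, (a / two_n)[:, None])

    x1 = (np.arange(tn1 + 1) / tn1)[:, None]
    x2 = (np.arange(tn2 + 1) / tn2)[None, :]
    f1 = (1 - m12) * x1 + m12 * x2  # (tn1+1, tn2+1) expected freq after migration
    f2 = (1 - m21) * x2 + m21 * x1
    T1 = stats.binom.pmf(
        np.arange(tn1 + 1)[None, None, :], tn1, f1[:, :, None]
    )  # (i, j, k)
    T2 = stats.binom.pmf(np.arange(tn2 + 1)[None, None, :], tn2, f2[:, :, None])

    inj = np.zeros((tn1 + 1, tn2 + 1))
    inj[1, 0] += nu1 / 2
    inj[0, 1] += nu2 / 2

    g_real = T * two_n
    g0 = int(np.floor(g_real))
    frac = g_real - g0

    S1 = _hyper_sample(tn1, n1)
    S2 = _hyper_sample(tn2, n2)
    SA1 = stats.hypergeom.pmf(np.arange(n1 + 1)[None, :], two_n, a[:, None], n1)
    SA2 = stats.hypergeom.pmf(np.arange(n2 + 1)[None, :], two_n, a[:, None], n2)

    def step(Q: np.ndarray) -> np.ndarray:
        out = np.einsum("ij,ijk,ijl->kl", Q, T1, T2, optimize=True)
        return out + inj

    def expected_at(g: int) -> np.ndarray:
        if g == 0:  # sample straight from the ancestral population
            return SA1.T @ (w[:, None] * SA2)
        # founding draw (generation 1) from the ancestral frequency
        P = np.einsum("a,ai,aj->ij", w, B1, B2) + inj
        for _ in range(g - 1):
            P = step(P)
        return S1.T @ P @ S2

    E0 = expected_at(g0)
    if frac == 0:
        return E0
    return (1 - frac) * E0 + frac * expected_at(g0 + 1)


def expected_joint_sfs(
    model: str,
    params: dict,
    sample_sizes: tuple[int, int],
    grid_diploids: int = 100,
    fold: bool = True,
) -> JointSFS:
    """Expected joint SFS per unit theta under a demographic model.

    ``params``: nu1, nu2, T (both models); M12, M21 (``split_mig`` only,
    dadi-scaled: migrants per 2 N_ref generations).
    """
    n1, n2 = sample_sizes
    if model == "split_nomig":
        E = _nomig_expected(
            params["nu1"], params["nu2"], params["T"], n1, n2, grid_diploids
        )
    elif model == "split_mig":
        E = _mig_expected(
            params["nu1"], params["nu2"], params["T"],
            params.get("M12", 0.0), params.get("M21", 0.0),
            n1, n2, grid_diploids,
        )
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    E = np.clip(E, 0.0, None)
    sfs = JointSFS(E, folded=False)
    return fold_sfs(sfs) if fold else sfs


def coalescent_joint_sfs(
    model: str,
    params: dict,
    sample_sizes: tuple[int, int],
    N_ref: int,
    mu: float,
    sequence_length: float,
    num_replicates: int = 200,
    seed: int | None = None,
    fold: bool = False,
    return_replicates: bool = False,
):
    """Stochastic oracle: joint SFS from msprime discrete-time WF simulation.

    Simulates ``num_replicates`` independent chromosomes of
    ``sequence_length`` bp under the same demography and tabulates allele
    counts; expectation is ``theta * expected_joint_sfs`` with
    theta = 4 N_ref mu L_total.  With ``return_replicates`` the stack of
    per-replicate spectra is returned as well (sites on one replicate share
    genealogies, so the empirical spread across replicates is the right
    Monte Carlo error, not the Poisson one).
    """
    import msprime

    n1, n2 = sample_sizes
    dem = msprime.Demography()
    dem.add_population(name="P1", initial_size=params["nu1"] * N_ref)
    dem.add_population(name="P2", initial_size=params["nu2"] * N_ref)
    dem.add_population(name="ANC", initial_size=N_ref)
    if model == "split_mig":
        # msprime migration rate = per-generation fraction
        dem.set_migration_rate("P1", "P2", params.get("M12", 0.0) / (2 * N_ref))
        dem.set_migration_rate("P2", "P1", params.get("M21", 0.0) / (2 * N_ref))
    dem.add_population_split(
        time=max(params["T"] * 2 * N_ref, 1e-9), derived=["P1", "P2"], ancestral="ANC"
    )
    if n1 % 2 or n2 % 2:
        raise ValueError("haplotype sample sizes must be even (diploid DTWF)")
    per_rep = []
    reps = msprime.sim_ancestry(
        samples={"P1": n1 // 2, "P2": n2 // 2},
        demography=dem,
        ploidy=2,
        sequence_length=sequence_length,
        model="dtwf",
        num_replicates=num_replicates,
        random_seed=None if seed is None else seed + 1,
    )
    rng = np.random.default_rng(None if seed is None else seed + 2)
    for ts in reps:
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            model=msprime.BinaryMutationModel(),
            random_seed=int(rng.integers(1, 2**31)),
        )
        afs = mts.allele_frequency_spectrum(
            sample_sets=[
                mts.samples(population=0).tolist(),
                mts.samples(population=1).tolist(),
            ],
            polarised=True,
            span_normalise=False,
        )
        per_rep.append(afs)
    stack = np.stack(per_rep)
    sfs = JointSFS(stack.sum(axis=0), folded=False)
    if fold:
        sfs = fold_sfs(sfs)
    return (sfs, stack) if return_replicates else sfs


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass
class DemographicFit:
    model: str
    params: dict
    theta: float
    loglik: float
    converged: bool
    n_restarts: int
    restarts: list = field(default_factory=list)  # (params, loglik, flagged)

    def flagged_restarts(self) -> list:
        return [r for r in self.restarts if r[2]]


DEFAULT_BOUNDS = {
    "nu1": (0.01, 0.99),
    "nu2": (0.01, 0.99),
    "T": (0.0, 0.5),
    "M12": (0.0, 5.0),
    "M21": (0.0, 5.0),
}


def _poisson_loglik(obs: JointSFS, model_sfs: JointSFS) -> tuple[float, float]:
    """Composite Poisson log-likelihood with theta profiled analytically."""
    o = obs.unmasked()
    m = np.clip(model_sfs.data[~obs.mask], 1e-300, None)
    theta = o.sum() / m.sum()
    mu_cells = theta * m
    ll = float(np.sum(o * np.log(mu_cells) - mu_cells))
    return ll, float(theta)


def _model_param_names(model: str) -> list[str]:
    return ["nu1", "nu2", "T"] + (["M12", "M21"] if model == "split_mig" else [])


def fit_model(
    obs: JointSFS,
    model: str = "split_nomig",
    n_restarts: int = 26,
    seed: int | None = None,
    grid_diploids: int = 100,
    bounds: dict | None = None,
    maxiter: int = 250,
    local_optimum_margin: float = 10.0,
    extra_starts: list[dict] | None = None,
    polish: bool = True,
) -> DemographicFit:
    """Fit a divergence model to an observed joint SFS.

    Poisson composite likelihood over unmasked cells, theta profiled
    analytically; COBYLA (derivative-free, constraint-respecting) from
    ``n_restarts`` random starts within the parameter bounds (plus any
    ``extra_starts``, e.g. a nested model's optimum when fitting the richer
    model for a likelihood-ratio test).  The constraint nu1 + nu2 <= 1
    keeps the daughter populations no larger in total than the ancestral
    one.  Restarts whose log-likelihood falls more than
    ``local_optimum_margin`` units below the best are flagged as local
    optima.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if obs.total() <= 0:
        raise ValueError("observed SFS is empty")
    names = _model_param_names(model)
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[p][0] for p in names])
    hi = np.array([bnds[p][1] for p in names])
    sizes = (obs.n1, obs.n2)
    # keep daughter grid populations at least as large as the samples
    two_n = 2 * grid_diploids
    lo[0] = max(lo[0], (max(sizes[0], 2) + 1) / two_n)
    lo[1] = max(lo[1], (max(sizes[1], 2) + 1) / two_n)

    def params_of(x: np.ndarray) -> dict:
        params = dict(zip(names, np.clip(x, lo, hi)))
        if 1 < params["nu1"] + params["nu2"] <= 1 + 1e-9:
            params["nu2"] = 1.0 - params["nu1"]  # shave fp overshoot
        return params

    def objective(x: np.ndarray) -> float:
        params = params_of(x)
        if params["nu1"] + params["nu2"] > 1:
            return 1e12 * (params["nu1"] + params["nu2"])
        try:
            m = expected_joint_sfs(
                model, params, sizes, grid_diploids=grid_diploids, fold=obs.folded
            )
        except (ValueError, FloatingPointError):
            return 1e12
        ll, _ = _poisson_loglik(obs, m)
        return -ll

    cons = [
        {"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]},
        *[
            {"type": "ineq", "fun": lambda x, k=k: x[k] - lo[k]}
            for k in range(len(names))
        ],
        *[
            {"type": "ineq", "fun": lambda x, k=k: hi[k] - x[k]}
            for k in range(len(names))
        ],
    ]
    rng = np.random.default_rng(seed)
    starts = []
    pre_evaluated = []
    for p in extra_starts or []:
        x0 = np.clip([p.get(name, 0.0) for name in names], lo, hi)
        starts.append(x0)
        # keep the start itself as a candidate so a nested optimum is never
        # lost to optimizer wander
        pre_evaluated.append((params_of(x0), -objective(x0), False))
    for _ in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        while x0[0] + x0[1] > 1:
            x0 = rng.uniform(lo, hi)
        starts.append(x0)
    restarts = list(pre_evaluated)
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="COBYLA",
            constraints=cons,
            options=dict(maxiter=maxiter, rhobeg=0.1, tol=1e-10),
        )
        # re-evaluate at the admissible point: COBYLA's reported optimum may
        # sit marginally outside the bounds
        restarts.append((params_of(res.x), -objective(res.x), False))
    if not restarts:
        raise RuntimeError("all restarts failed")
    if polish:
        # re-run from the best restart with a tighter trust region
        best_params0, _, _ = max(restarts, key=lambda r: r[1])
        x0 = np.array([best_params0[p] for p in names])
        res = optimize.minimize(
            objective, x0, method="COBYLA", constraints=cons,
            options=dict(maxiter=2 * maxiter, rhobeg=0.02, tol=1e-12),
        )
        restarts.append((params_of(res.x), -objective(res.x), False))
    best_ll = max(r[1] for r in restarts)
    restarts = [
        (p, ll, ll < best_ll - local_optimum_margin) for p, ll, _ in restarts
    ]
    best_params, best_ll, _ = max(restarts, key=lambda r: r[1])
    m = expected_joint_sfs(
        model, best_params, sizes, grid_diploids=grid_diploids, fold=obs.folded
    )
    ll, theta = _poisson_loglik(obs, m)
    n_flagged = sum(r[2] for r in restarts)
    if n_flagged:
        logger.info("fit_model: %d/%d restarts flagged as local optima",
                    n_flagged, len(restarts))
    return DemographicFit(
        model=model,
        params=best_params,
        theta=theta,
        loglik=ll,
        converged=bool(np.isfinite(ll)),
        n_restarts=n_restarts,
        restarts=restarts,
    )


def lrt(
    fit_simple: DemographicFit,
    fit_complex: DemographicFit,
    df: int = 2,
    alpha: float = 0.05,
    tolerance: float = 0.5,
) -> tuple[float, float, bool]:
    """Log-likelihood ratio test of a nested model pair.

    Returns (statistic, p, complex_supported).  A statistic below
    -tolerance indicates the richer model converged to a worse optimum than
    the nested one, i.e. an optimizer failure; it is flagged by raising.
    Sub-tolerance negatives (the migration backend rounds daughter grid
    sizes where the isolation backend interpolates them, which can cost a
    fraction of a log-likelihood unit) are clamped to zero — far below any
    chi-square critical value, so conclusions are unaffected.
    """
    D = 2 * (fit_complex.loglik - fit_simple.loglik)
    if D < -tolerance:
        raise RuntimeError(
            f"complex-model log-likelihood below simple model (D={D:.3g}); "
            "optimizer likely found a local optimum"
        )
    D = max(D, 0.0)
    p = float(stats.chi2.sf(D, df))
    return float(D), p, p < alpha


# ---------------------------------------------------------------------------
# Real-time scaling
# ---------------------------------------------------------------------------


def effective_length(total_sites: int, snps_pre: int, snps_post: int) -> float:
    """Effective sequence length: total sites x retained-SNP fraction."""
    if snps_pre <= 0 or total_sites <= 0 or snps_post < 0:
        raise ValueError("counts must be positive (snps_post may be zero)")
    if snps_post > snps_pre:
        raise ValueError("snps_post cannot exceed snps_pre")
    return total_sites * snps_post / snps_pre


@dataclass
class RealTimeScaling:
    mu: float
    L: float
    generation_time: float
    N_ref: float
    T_generations: float
    T_years: float


def scale_to_real(
    fit: DemographicFit,
    mu: float | dict = None,
    L: float = 1.0,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> dict[str, RealTimeScaling]:
    """Convert a fit to diploid N_ref and calendar time for each mutation rate.

    N_ref = theta / (4 mu L); T_generations = T * 2 N_ref;
    T_years = T_generations * generation_time.
    """
    if mu is None:
        mu = DEFAULT_MUTATION_RATES
    if not isinstance(mu, dict):
        mu = {"mu": float(mu)}
    if L <= 0 or generation_time <= 0 or any(v <= 0 for v in mu.values()):
        raise ValueError("mu, L and generation_time must be positive")
    out = {}
    for name, rate in mu.items():
        n_ref = fit.theta / (4 * rate * L)
        t_gen = fit.params["T"] * 2 * n_ref
        out[name] = RealTimeScaling(
            mu=rate,
            L=L,
            generation_time=generation_time,
            N_ref=n_ref,
            T_generations=t_gen,
            T_years=t_gen * generation_time,
        )
    return out


# ---------------------------------------------------------------------------
# Block bootstrap
# ---------------------------------------------------------------------------


def block_bootstrap(
    gm: GenotypeMatrix,
    pops: np.ndarray | list,
    pop1,
    pop2,
    block_size: int = 1_000_000,
    B: int = 100,
    seed: int | None = None,
    fold: bool = True,
    project: tuple[int, int] | None = None,
) -> list[JointSFS]:
    """Genome-block bootstrap of the joint SFS.

    The genome is tiled into contiguous ``block_size``-bp blocks by locus
    coordinate; blocks are resampled with replacement and each replicate's
    SFS is the multiplicity-weighted sum of per-block spectra.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    block_ids = np.array(
        [f"{c}:{p // block_size}" for c, p in zip(gm.chrom, gm.pos)], dtype=object
    )
    uniq = list(dict.fromkeys(block_ids))
    if len(uniq) == 1:
        logger.warning("block_bootstrap: single block; replicates are degenerate")
    per_block = []
    for b in uniq:
        sub = gm.take_loci(block_ids == b)
        per_block.append(
            joint_sfs(sub, pops, pop1, pop2, fold=fold, project=project).data
        )
    per_block = np.stack(per_block)
    rng = np.random.default_rng(seed)
    template = joint_sfs(gm.take_loci(np.arange(gm.n_loci)), pops, pop1, pop2,
                         fold=fold, project=project)
    out = []
    for _ in range(B):
        idx = rng.integers(0, len(uniq), size=len(uniq))
        out.append(JointSFS(per_block[idx].sum(axis=0), folded=fold,
                            mask=template.mask.copy()))
    return out
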