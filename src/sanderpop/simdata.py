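"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a two-species riverine
hybrid zone surveyed by genotyping-by-sequencing:

* two divergent parental gene pools (sauger-like species A, walleye-like
  species B) built from a shared ancestral polymorphism backbone with
  Balding-Nichols differentiation plus a configurable fraction of
  diagnostic (fixed-difference) loci;
* pure, F1, F2 and backcross genotypes with recorded true (q, Q);
* missing-completely-at-random genotype dropout at GBS-like rates;
* a sex-differentiated locus block on one chromosome;
* a population split (drift-only divergence for a known number of
  generations) and stepping-stone populations along a linear river, both
  simulated with msprime.

All functions are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import ParentalFreqs
from .vcfio import MISSING, GenotypeMatrix

#: Per-locus ancestry-state probabilities (AA, AB, BB) for each cross class.
CROSS_CLASSES = {
    "pureA": (1.0, 0.0, 0.0),
    "pureB": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC_A": (0.5, 0.5, 0.0),
    "BC_B": (0.0, 0.5, 0.5),
}


@dataclass
class SplitParams:
    """Parameters of the two-population divergence simulation."""

    N_ref: int = 1000           # ancestral diploid size
    nu1: float = 0.5            # daughter sizes relative to N_ref
    nu2: float = 0.5
    T_gens: float = 200.0       # generations since the split
    mu: float = 1e-8            # per-site per-generation mutation rate
    n1: int = 20                # sampled haplotypes per population
    n2: int = 20
    sequence_length: float = 5e6
    recombination_rate: float = 1e-8


@dataclass
class SimConfig:
    """Configuration of the one-command synthetic study."""

    n_loci: int = 2000
    divergence_d: float = 0.3
    diagnostic_fraction: float = 0.05
    class_counts: dict = field(
        default_factory=lambda: {
            "pureA": 30, "pureB": 30, "F1": 5, "F2": 5, "BC_A": 5, "BC_B": 5
        }
    )
    n_ref_per_panel: int = 20
    missing_rate: float = 0.2
    sex_block: tuple = ("chr7", 40, 0.8)   # (chromosome, locus count, effect)
    split_params: SplitParams = field(default_factory=SplitParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.divergence_d < 1:
            raise ValueError("divergence_d must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if any(c <= 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be positive")


# ---------------------------------------------------------------------------
# Parental panels and crosses
# ---------------------------------------------------------------------------


def simulate_parental_panels(
    n_loci: int,
    divergence_d: float,
    seed: int | None = None,
    diagnostic_fraction: float = 0.05,
) -> ParentalFreqs:
    """Draw per-locus parental allele-frequency pairs (pA, pB).

    Each locus has a shared ancestral frequency drawn uniformly on
    (0.05, 0.95); both species' frequencies are then independent
    Balding-Nichols draws around it with differentiation ``divergence_d``
    (d = 0 collapses to pA = pB).  A fraction of loci is made diagnostic
    (fixed difference, random orientation).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0 <= divergence_d < 1:
        raise ValueError("divergence_d must be in [0, 1)")
    if not 0 <= diagnostic_fraction <= 1:
        raise ValueError("diagnostic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=n_loci)
    if divergence_d == 0:
        p_a = anc.copy()
        p_b = anc.copy()
    else:
        shape = (1 - divergence_d) / divergence_d
        p_a = rng.beta(anc * shape, (1 - anc) * shape)
        p_b = rng.beta(anc * shape, (1 - anc) * shape)
    n_diag = int(round(diagnostic_fraction * n_loci))
    if n_diag:
        idx = rng.choice(n_loci, size=n_diag, replace=False)
        orient = rng.random(n_diag) < 0.5
        p_a[idx] = np.where(orient, 1.0, 0.0)
        p_b[idx] = np.where(orient, 0.0, 1.0)
    return ParentalFreqs(p_a, p_b)


def locus_coordinates(
    n_loci: int,
    n_chromosomes: int = 4,
    chrom_length: int = 10_000_000,
    seed: int | None = None,
    names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 1-based locus coordinates spread over chromosomes."""
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    per = np.full(n_chromosomes, n_loci // n_chromosomes)
    per[: n_loci % n_chromosomes] += 1
    chrom, pos = [], []
    for name, k in zip(names, per):
        p = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=k, replace=False))
        chrom.extend([name] * k)
        pos.extend(p.tolist())
    return np.array(chrom, dtype=object), np.array(pos, dtype=np.int64)


def simulate_cross(
    freqs: ParentalFreqs,
    cross_class: str,
    n: int,
    seed: int | None = None,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    sample_prefix: str | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate ``n`` individuals of one ancestry class.

    Per individual and locus an ancestry state (AA/AB/BB) is drawn from the
    class distribution; alleles are then drawn from the corresponding
    parental frequency (state AB takes one allele from each pool).  Returns
    the genotypes and a truth table with realised per-individual (q, Q).
    """
    if cross_class not in CROSS_CLASSES:
        raise ValueError(
            f"unknown class {cross_class!r}; choose from {sorted(CROSS_CLASSES)}"
        )
    rng = np.random.default_rng(seed)
    L = freqs.n_loci
    probs = np.array(CROSS_CLASSES[cross_class])
    states = rng.choice(3, size=(n, L), p=probs)  # 0=AA, 1=AB, 2=BB
    u1 = rng.random((n, L))
    u2 = rng.random((n, L))
    # allele 1: from pool A unless state is BB; allele 2: from pool B unless AA
    p1 = np.where(states == 2, freqs.p_b, freqs.p_a)
    p2 = np.where(states == 0, freqs.p_a, freqs.p_b)
    gt = (u1 < p1).astype(np.int8) + (u2 < p2).astype(np.int8)
    if chrom is None or pos is None:
        chrom, pos = locus_coordinates(L, seed=rng.integers(2**31))
    prefix = sample_prefix or cross_class
    samples = [f"{prefix}_{i:03d}" for i in range(n)]
    gm = GenotypeMatrix(samples=samples, chrom=chrom, pos=pos, gt=gt)
    truth = pd.DataFrame(
        dict(
            sample_id=samples,
            true_class=cross_class,
            true_q=(states == 2).mean(axis=1) + (states == 1).mean(axis=1) / 2,
            true_Q=(states == 1).mean(axis=1),
        )
    )
    return gm, truth


def apply_missingness(
    gm: GenotypeMatrix,
    locus_rates: float | np.ndarray,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Set genotypes missing independently at per-locus rates in [0, 1)."""
    rates = np.broadcast_to(np.asarray(locus_rates, dtype=float), (gm.n_loci,))
    if np.any((rates < 0) | (rates >= 1)):
        raise ValueError("missingness rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.gt.shape) < rates[None, :]
    out = gm.copy()
    out.gt[mask] = MISSING
    return out


def simulate_sex_block(
    gm: GenotypeMatrix,
    chromosome: str,
    n_sexloci: int,
    effect: float,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Plant a block of sex-differentiated loci on one chromosome.

    Sexes are assigned 50/50; at each planted locus allele frequencies in
    the two sexes differ by ``effect`` (0.5 +/- effect/2).  Returns the
    modified matrix, the sex labels and the planted locus indices.
    """
    on_chrom = np.flatnonzero(gm.chrom == chromosome)
    if len(on_chrom) == 0:
        raise ValueError(f"chromosome {chromosome!r} not present")
    if n_sexloci > len(on_chrom):
        raise ValueError(
            f"requested {n_sexloci} sex loci but chromosome has {len(on_chrom)}"
        )
    if not 0 <= effect <= 1:
        raise ValueError("effect must be in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = np.sort(rng.choice(on_chrom, size=n_sexloci, replace=False))
    sexes = np.array(["F", "M"] * ((gm.n_samples + 1) // 2))[: gm.n_samples]
    p_f, p_m = 0.5 + effect / 2, 0.5 - effect / 2
    out = gm.copy()
    p = np.where(sexes == "F", p_f, p_m)[:, None, None]  # (n_samples, 1, 1)
    # two allele copies per individual x planted locus
    draws = rng.random((gm.n_samples, n_sexloci, 2)) < p
    out.gt[:, planted] = draws.sum(axis=2).astype(np.int8)
    return out, sexes, planted


# ---------------------------------------------------------------------------
# Coalescent simulations (split, river)
# ---------------------------------------------------------------------------


def _ts_to_genotype_matrix(ts, sample_names: list[str], chrom: str = "chr1") -> GenotypeMatrix:
    """Biallelic SNPs of a tree sequence as a diploid GenotypeMatrix."""
    rows, pos = [], []
    last = 0
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue
        p = int(var.site.position) + 1
        if p <= last:  # discretised positions must stay strictly increasing
            p = last + 1
        last = p
        pos.append(p)
        rows.append(var.genotypes.astype(np.int8))
    if rows:
        hap = np.stack(rows, axis=1)  # (n_haplotypes, n_loci)
        gt = hap[0::2] + hap[1::2]
    else:
        gt = np.zeros((len(sample_names), 0), dtype=np.int8)
    return GenotypeMatrix(
        samples=sample_names,
        chrom=np.array([chrom] * len(pos), dtype=object),
        pos=np.array(pos, dtype=np.int64),
        gt=gt,
    )


def simulate_split(
    params: SplitParams, seed: int | None = None, fold: bool = True
):
    """Simulate an ancestral population splitting into two isolated daughters.

    A neutral ancestral population of ``N_ref`` diploids splits ``T_gens``
    generations ago into populations of relative size ``nu1`` and ``nu2``
    (their sum may not exceed 1) with no subsequent migration.  Returns the
    sampled diploid genotypes, the realised folded joint SFS and a truth
    record of all generating parameters.
    """
    import msprime

    from .demography import joint_sfs

    if params.nu1 + params.nu2 > 1 + 1e-9:
        raise ValueError("nu1 + nu2 must not exceed 1")
    if params.n1 % 2 or params.n2 % 2:
        raise ValueError("sampled haplotype counts must be even (diploid samples)")
    dem = msprime.Demography()
    dem.add_population(name="P1", initial_size=max(params.nu1 * params.N_ref, 1))
    dem.add_population(name="P2", initial_size=max(params.nu2 * params.N_ref, 1))
    dem.add_population(name="ANC", initial_size=params.N_ref)
    dem.add_population_split(time=max(params.T_gens, 1e-9), derived=["P1", "P2"], ancestral="ANC")
    ts = msprime.sim_ancestry(
        samples={"P1": params.n1 // 2, "P2": params.n2 // 2},
        demography=dem,
        sequence_length=params.sequence_length,
        recombination_rate=params.recombination_rate,
        random_seed=None if seed is None else seed + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        random_seed=None if seed is None else seed + 2,
        model=msprime.BinaryMutationModel(),
    )
    names = [f"P1_{i:03d}" for i in range(params.n1 // 2)] + [
        f"P2_{i:03d}" for i in range(params.n2 // 2)
    ]
    gm = _ts_to_genotype_matrix(ts, names)
    pops = np.array(["P1"] * (params.n1 // 2) + ["P2"] * (params.n2 // 2))
    sfs = joint_sfs(gm, pops, "P1", "P2", fold=fold)
    truth = dict(
        N_ref=params.N_ref,
        nu1=params.nu1,
        nu2=params.nu2,
        T_gens=params.T_gens,
        T_scaled=params.T_gens / (2 * params.N_ref),
        mu=params.mu,
        n1=params.n1,
        n2=params.n2,
        sequence_length=params.sequence_length,
        theta=4 * params.N_ref * params.mu * params.sequence_length,
    )
    return gm, sfs, truth


def simulate_river(
    n_pops: int,
    spacing_km: float = 50.0,
    migration_rate: float = 1e-3,
    generations: float = 4000.0,
    seed: int | None = None,
    n_per_pop: int = 10,
    deme_size: int = 500,
    sequence_length: float = 5e5,
    mu: float = 1e-8,
) -> tuple[GenotypeMatrix, np.ndarray, pd.DataFrame]:
    """Stepping-stone populations along a linear river.

    ``n_pops`` demes of ``deme_size`` diploids exchange migrants at rate
    ``migration_rate`` per generation between adjacent demes; all demes
    derive from one ancestral population ``generations`` ago.  Returns
    genotypes (``n_per_pop`` diploids per deme), the deme labels, and the
    along-river pairwise distance matrix (spacing_km * |i - j|).
    """
    import msprime

    if n_pops < 3:
        raise ValueError("stepping-stone model needs at least 3 populations")
    dem = msprime.Demography()
    for i in range(n_pops):
        dem.add_population(name=f"D{i}", initial_size=deme_size)
    dem.add_population(name="ANC", initial_size=deme_size * n_pops)
    for i in range(n_pops - 1):
        dem.set_migration_rate(f"D{i}", f"D{i + 1}", migration_rate)
        dem.set_migration_rate(f"D{i + 1}", f"D{i}", migration_rate)
    dem.add_population_split(
        time=generations, derived=[f"D{i}" for i in range(n_pops)], ancestral="ANC"
    )
    ts = msprime.sim_ancestry(
        samples={f"D{i}": n_per_pop for i in range(n_pops)},
        demography=dem,
        sequence_length=sequence_length,
        recombination_rate=1e-8,
        random_seed=None if seed is None else seed + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        random_seed=None if seed is None else seed + 2,
        model=msprime.BinaryMutationModel(),
    )
    names, labels = [], []
    for i in range(n_pops):
        names += [f"D{i}_{k:02d}" for k in range(n_per_pop)]
        labels += [f"D{i}"] * n_per_pop
    gm = _ts_to_genotype_matrix(ts, names)
    idx = np.arange(n_pops)
    dist = spacing_km * np.abs(idx[:, None] - idx[None, :]).astype(float)
    dist_df = pd.DataFrame(dist, index=[f"D{i}" for i in idx], columns=[f"D{i}" for i in idx])
    return gm, np.array(labels), dist_df


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig) -> dict:
    """Generate the full synthetic study: panels, crosses, missingness, sex block.

    Returns a dict with the genotype matrix, sample metadata table (panel
    flags for the reference individuals), parental frequencies, truth table,
    sex labels and planted sex-locus indices.
    """
    rng = np.random.default_rng(config.seed)
    freqs = simulate_parental_panels(
        config.n_loci,
        config.divergence_d,
        seed=int(rng.integers(2**31)),
        diagnostic_fraction=config.diagnostic_fraction,
    )
    chrom, pos = locus_coordinates(config.n_loci, seed=int(rng.integers(2**31)),
                                   n_chromosomes=8)
    pieces, truths, panels = [], [], []
    for cls, prefix, panel in (
        ("pureA", "refA", "refA"),
        ("pureB", "refB", "refB"),
    ):
        gm_c, tr = simulate_cross(
            freqs, cls, config.n_ref_per_panel, seed=int(rng.integers(2**31)),
            chrom=chrom, pos=pos, sample_prefix=prefix,
        )
        pieces.append(gm_c)
        truths.append(tr)
        panels += [panel] * config.n_ref_per_panel
    for cls, n in config.class_counts.items():
        gm_c, tr = simulate_cross(
            freqs, cls, n, seed=int(rng.integers(2**31)), chrom=chrom, pos=pos
        )
        pieces.append(gm_c)
        truths.append(tr)
        panels += ["query"] * n
    gt = np.vstack([p.gt for p in pieces])
    samples = sum((p.samples for p in pieces), [])
    gm = GenotypeMatrix(samples=samples, chrom=chrom, pos=pos, gt=gt)
    sex_chrom, n_sexloci, effect = config.sex_block
    available = int((chrom == sex_chrom).sum())
    gm, sexes, planted = simulate_sex_block(
        gm, sex_chrom, min(n_sexloci, available), effect,
        seed=int(rng.integers(2**31)),
    )
    gm = apply_missingness(gm, config.missing_rate, seed=int(rng.integers(2**31)))
    truth = pd.concat(truths, ignore_index=True)
    meta = pd.DataFrame(
        dict(
            sample_id=samples,
            location="synthetic",
            date="2018-09-01",
            sex=sexes,
            phenotype=["unknown"] * len(samples),
            panel=panels,
        )
    )
    return dict(
        genotypes=gm,
        metadata=meta,
        freqs=freqs,
        truth=truth,
        sexes=sexes,
        sex_loci=planted,
    )
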