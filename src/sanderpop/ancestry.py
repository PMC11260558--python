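"""Hybrid-ancestry estimation: per-individual q and Q, and hybrid classes.

For a two-species system (species A = sauger, species B = walleye) each
locus of a diploid individual carries an ancestry state ``z`` in
{AA, AB, BB}: both allele copies from species A, one from each, or both
from species B.  Writing pi = (pi_AA, pi_AB, pi_BB) for the genome-wide
proportions of these states,

    q = pi_BB + pi_AB / 2      (proportion of species-B ancestry)
    Q = pi_AB                  (interspecific ancestry: fraction of loci
                                with one copy from each species)

pi is estimated per individual by an EM algorithm on called genotypes,
holding the parental allele frequencies fixed.  Genotype likelihoods under
each state follow Hardy-Weinberg draws from the parental pools: state AA
draws both alleles from species A's frequency, BB from species B's, and AB
one from each.  This estimator targets the same (q, Q) estimands as the
hierarchical Bayesian "entropy" k=2 model, trading its genotype-uncertainty
modelling for a fast deterministic fit.

Classification thresholds on (q, Q) follow the field's convention:
q < 0.1 -> sauger, q > 0.9 -> walleye, otherwise hybrid, sub-typed as
F1 (0.4 <= q <= 0.6, Q > 0.8), F2 (0.4 <= q <= 0.6, 0.4 <= Q <= 0.6),
BC_sauger (|Q - 2q| <= 0.1), BC_walleye (1.9 <= Q + 2q <= 2.1), applied in
that order; hybrids matching no sub-rule are ``hybrid_unassigned``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

HYBRID_CLASSES = (
    "sauger",
    "walleye",
    "F1",
    "F2",
    "BC_sauger",
    "BC_walleye",
    "hybrid_unassigned",
)


@dataclass
class ParentalFreqs:
    """Per-locus alternate-allele frequencies in the two parental panels.

    ``p_a[j]`` / ``p_b[j]`` are the alternate-allele frequencies of locus j in
    species A (sauger) and species B (walleye).
    """

    p_a: np.ndarray
    p_b: np.ndarray
    flagged: np.ndarray | None = None  # loci where a panel had zero calls

    def __post_init__(self) -> None:
        self.p_a = np.asarray(self.p_a, dtype=float)
        self.p_b = np.asarray(self.p_b, dtype=float)
        if self.p_a.shape != self.p_b.shape:
            raise ValueError("panel frequency arrays differ in length")
        if self.flagged is None:
            self.flagged = np.zeros(self.p_a.shape, dtype=bool)

    @property
    def n_loci(self) -> int:
        return len(self.p_a)

    def take(self, index: np.ndarray) -> "ParentalFreqs":
        return ParentalFreqs(self.p_a[index], self.p_b[index], self.flagged[index])


@dataclass
class AncestryEstimate:
    sample_id: str
    q: float
    Q: float
    loglik: float
    n_informative_loci: int
    valid: bool = True
    ci_q: tuple[float, float] | None = None
    ci_Q: tuple[float, float] | None = None


def estimate_parental_freqs(
    gm: GenotypeMatrix,
    panel: np.ndarray | list,
    pseudocount: float = 0.5,
) -> ParentalFreqs:
    """Estimate parental allele frequencies from reference panels.

    Parameters
    ----------
    panel : array of str
        Per-sample panel assignment, ``refA``/``refB`` for the parental
        reference panels; anything else is ignored.
    pseudocount : float
        Additive smoothing per allele, so panel frequencies avoid exact 0/1
        (default 0.5); set to 0 for plain frequencies.
    """
    panel = np.asarray(panel)
    freqs = []
    flagged = np.zeros(gm.n_loci, dtype=bool)
    for label in ("refA", "refB"):
        sub = gm.take_samples(panel == label)
        if sub.n_samples == 0:
            raise ValueError(f"parental panel {label!r} is empty")
        alt, n = sub.alt_counts()
        flagged |= n == 0
        freqs.append((alt + pseudocount) / np.maximum(n + 2 * pseudocount, 1e-12))
    if flagged.any():
        logger.warning(
            "estimate_parental_freqs: %d loci with zero calls in a panel", flagged.sum()
        )
    return ParentalFreqs(freqs[0], freqs[1], flagged)


def _state_likelihoods(g: np.ndarray, p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """P(genotype | ancestry state) for states (AA, AB, BB); shape (n_loci, 3)."""
    qa, qb = 1 - p_a, 1 - p_b
    lik = np.empty((len(g), 3))
    # state AA: Binomial(2, p_a)
    lik[:, 0] = np.where(g == 0, qa * qa, np.where(g == 1, 2 * p_a * qa, p_a * p_a))
    # state AB: one allele from each pool
    lik[:, 1] = np.where(
        g == 0, qa * qb, np.where(g == 1, p_a * qb + p_b * qa, p_a * p_b)
    )
    # state BB: Binomial(2, p_b)
    lik[:, 2] = np.where(g == 0, qb * qb, np.where(g == 1, 2 * p_b * qb, p_b * p_b))
    return lik


def _em_pi(
    lik: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, float, list[float]]:
    """EM for genome-wide ancestry-state proportions given per-locus likelihoods."""
    pi = np.array([1 / 3, 1 / 3, 1 / 3])
    history: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        joint = lik * pi  # (L, 3)
        rowsum = joint.sum(axis=1)
        rowsum = np.maximum(rowsum, 1e-300)
        ll = float(np.log(rowsum).sum())
        history.append(ll)
        resp = joint / rowsum[:, None]
        pi = resp.mean(axis=0)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return pi, history[-1], history


def estimate_qQ(
    gm: GenotypeMatrix,
    freqs: ParentalFreqs,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[AncestryEstimate]:
    """Estimate (q, Q) for every individual in ``gm`` by EM.

    Missing genotypes are skipped.  An individual with no informative locus
    is returned with ``valid=False``.
    """
    if freqs.n_loci != gm.n_loci:
        raise ValueError("parental frequencies and genotype matrix disagree on loci")
    out = []
    for i, sid in enumerate(gm.samples):
        g = gm.gt[i]
        use = g != MISSING
        n_inf = int(use.sum())
        if n_inf == 0:
            out.append(AncestryEstimate(sid, np.nan, np.nan, np.nan, 0, valid=False))
            continue
        lik = _state_likelihoods(g[use], freqs.p_a[use], freqs.p_b[use])
        pi, ll, _ = _em_pi(lik, tol=tol, max_iter=max_iter)
        q = float(pi[2] + pi[1] / 2)
        Q = float(pi[1])
        out.append(AncestryEstimate(sid, q, Q, ll, n_inf))
    return out


def classify_hybrid(q: float, Q: float) -> str:
    """Assign a hybrid class from (q, Q); see module docstring for the rules."""
    if not (0 <= q <= 1 and 0 <= Q <= 1):
        raise ValueError(f"q, Q must lie in [0, 1]; got q={q}, Q={Q}")
    if q < 0.1:
        return "sauger"
    if q > 0.9:
        return "walleye"
    # hybrid sub-rules, applied in fixed order F1 -> F2 -> BC
    if 0.4 <= q <= 0.6 and Q > 0.8:
        return "F1"
    if 0.4 <= q <= 0.6 and 0.4 <= Q <= 0.6:
        return "F2"
    if -0.1 <= Q - 2 * q <= 0.1:
        return "BC_sauger"
    if 1.9 <= Q + 2 * q <= 2.1:
        return "BC_walleye"
    return "hybrid_unassigned"


def bootstrap_qQ(
    gm: GenotypeMatrix,
    freqs: ParentalFreqs,
    sample_id: str,
    B: int = 200,
    seed: int | None = None,
    tol: float = 1e-8,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """95% percentile bootstrap intervals for one individual's (q, Q).

    Loci are resampled with replacement B times (B >= 100).
    """
    if B < 100:
        raise ValueError("bootstrap requires B >= 100")
    i = gm.samples.index(sample_id)
    g = gm.gt[i]
    use = g != MISSING
    lik0 = _state_likelihoods(g[use], freqs.p_a[use], freqs.p_b[use])
    rng = np.random.default_rng(seed)
    L = lik0.shape[0]
    qs, Qs = np.empty(B), np.empty(B)
    for b in range(B):
        idx = rng.integers(0, L, size=L)
        pi, _, _ = _em_pi(lik0[idx], tol=tol)
        qs[b] = pi[2] + pi[1] / 2
        Qs[b] = pi[1]
    ci_q = tuple(np.percentile(qs, [2.5, 97.5]))
    ci_Q = tuple(np.percentile(Qs, [2.5, 97.5]))
    return ci_q, ci_Q


def ancestry_table(estimates: list[AncestryEstimate]) -> pd.DataFrame:
    """Tabulate estimates with hybrid classes as a DataFrame (TSV-ready)."""
    rows = []
    for e in estimates:
        label = classify_hybrid(e.q, e.Q) if e.valid else "invalid"
        rows.append(
            dict(
                sample_id=e.sample_id,
                q=e.q,
                Q=e.Q,
                hybrid_class=label,
                loglik=e.loglik,
                n_informative_loci=e.n_informative_loci,
                ci_q_low=e.ci_q[0] if e.ci_q else np.nan,
                ci_q_high=e.ci_q[1] if e.ci_q else np.nan,
                ci_Q_low=e.ci_Q[0] if e.ci_Q else np.nan,
                ci_Q_high=e.ci_Q[1] if e.ci_Q else np.nan,
            )
        )
    return pd.DataFrame(rows)
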