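"""Genotype-matrix container, VCF input/output and the study's filtering presets.

Genotypes are stored as counts of the alternate allele (0/1/2) in an
``int8`` matrix of shape ``(n_samples, n_loci)`` with ``-1`` for missing
calls.  Only biallelic SNPs are represented; multiallelic and non-SNP
records are skipped on read, with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: Filtering presets mirroring the published analysis stages.
#: ``hybrid``     — hybrid detection dataset (MAF >= 0.03, locus missingness <= 0.5)
#: ``pca``        — principal-component dataset (locus missingness <= 0.25)
#: ``sauger``     — within-species structure after hybrid/walleye removal
#: ``demography`` — SFS dataset: no MAF filter, sex loci kept, missingness <= 0.7
PRESETS: dict[str, dict] = {
    "hybrid": dict(maf_min=0.03, max_locus_missing=0.5, drop_sex_loci=True),
    "pca": dict(maf_min=0.03, max_locus_missing=0.25, drop_sex_loci=True),
    "sauger": dict(maf_min=0.03, max_locus_missing=0.25, drop_sex_loci=True),
    "demography": dict(maf_min=0.0, max_locus_missing=0.7, drop_sex_loci=False),
}

#: Default individual-missingness removal threshold; individuals with this
#: fraction of missing calls *or more* are dropped.
DEFAULT_INDIV_MISSING = 0.8


class VcfFormatError(ValueError):
    """Raised when a VCF file cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci genotype matrix.

    Attributes
    ----------
    samples : list of str
        Sample identifiers (rows).
    chrom, pos : ndarray
        Per-locus chromosome id and 1-based position (columns); positions are
        strictly increasing within each chromosome.
    gt : ndarray of int8
        Alternate-allele copy counts, ``-1`` for missing.
    ref, alt : ndarray of str
        Per-locus alleles (synthetic data uses A/T placeholders).
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    gt: np.ndarray
    ref: np.ndarray = field(default=None)  # type: ignore[assignment]
    alt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.ref is None:
            self.ref = np.full(self.n_loci, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_loci, "T", dtype=object)
        if self.gt.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"genotype matrix shape {self.gt.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.pos)} loci"
            )
        if len(self.chrom) != len(self.pos):
            raise ValueError("chrom/pos length mismatch")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        bad = ~np.isin(self.gt, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotypes must be in {-1, 0, 1, 2}")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.gt != MISSING

    def alt_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (alt allele count, called chromosome count)."""
        called = self.called()
        alt = np.where(called, self.gt, 0).sum(axis=0)
        n = 2 * called.sum(axis=0)
        return alt.astype(np.int64), n.astype(np.int64)

    def alt_freq(self) -> np.ndarray:
        """Per-locus alternate allele frequency among called genotypes (NaN if none)."""
        alt, n = self.alt_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1 - p)

    def locus_missing_rate(self) -> np.ndarray:
        return 1.0 - self.called().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return 1.0 - self.called().mean(axis=1)

    # -- subsetting ----------------------------------------------------
    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[index],
            pos=self.pos[index],
            gt=self.gt[:, index],
            ref=self.ref[index],
            alt=self.alt[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            chrom=self.chrom,
            pos=self.pos,
            gt=self.gt[index],
            ref=self.ref,
            alt=self.alt,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            gt=self.gt.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
        )

    def imputed(self) -> np.ndarray:
        """Float matrix with missing genotypes replaced by the per-locus mean."""
        called = self.called()
        cnt = called.sum(axis=0)
        mean = np.where(called, self.gt, 0).sum(axis=0) / np.maximum(cnt, 1)
        return np.where(called, self.gt.astype(float), mean[None, :])


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

# cyvcf2 gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
_CYVCF2_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (a count is logged).
    Missing genotypes (``./.``) map to the missing code.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfFormatError(f"cannot parse {path}: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(_CYVCF2_CODE[np.asarray(v.gt_types)])
    if n_skipped:
        logger.warning("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    gt = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        gt=gt,
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT field only)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_loci):
            calls = "\t".join(_GT_STR[int(g)] for g in gm.gt[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "location", "date", "sex", "phenotype", "panel"]


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata TSV (sample_id, location, date, sex, phenotype, panel)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    return df


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    n_loci_before: int
    n_loci_after: int
    n_removed_maf: int
    n_removed_missing: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_loci(
    gm: GenotypeMatrix,
    maf_min: float = 0.03,
    max_locus_missing: float = 0.5,
    return_report: bool = False,
):
    """Drop loci below the MAF threshold or above the missingness threshold.

    Both criteria are evaluated on the input matrix, then failing loci are
    dropped at once, so the result does not depend on filter ordering.
    Loci with no called genotypes fail the missingness criterion.
    """
    if not (0 <= maf_min <= 1 and 0 <= max_locus_missing <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    maf = gm.maf()
    miss = gm.locus_missing_rate()
    ok_maf = ~np.isnan(maf) & (maf >= maf_min)
    ok_miss = miss <= max_locus_missing
    keep = ok_maf & ok_miss
    if not keep.any():
        logger.warning("filter_loci: no loci survive filtering")
    out = gm.take_loci(keep)
    report = FilterReport(
        n_loci_before=gm.n_loci,
        n_loci_after=int(keep.sum()),
        n_removed_maf=int((~ok_maf).sum()),
        n_removed_missing=int((~ok_miss).sum()),
    )
    return (out, report) if return_report else out


def filter_individuals(
    gm: GenotypeMatrix, max_indiv_missing: float = DEFAULT_INDIV_MISSING
) -> GenotypeMatrix:
    """Remove individuals whose missing-data fraction is >= the threshold."""
    if not 0 <= max_indiv_missing <= 1:
        raise ValueError("threshold must be in [0, 1]")
    miss = gm.sample_missing_rate()
    drop = miss >= max_indiv_missing
    if drop.any():
        removed = [s for s, d in zip(gm.samples, drop) if d]
        logger.info("filter_individuals: removed %d individuals: %s",
                    len(removed), ", ".join(removed[:10]))
    return gm.take_samples(~drop)


def apply_preset(
    gm: GenotypeMatrix,
    preset: str,
    sex_loci: set | None = None,
    max_indiv_missing: float = DEFAULT_INDIV_MISSING,
) -> GenotypeMatrix:
    """Apply a named filtering preset (see :data:`PRESETS`)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    out = filter_loci(gm, maf_min=cfg["maf_min"], max_locus_missing=cfg["max_locus_missing"])
    if cfg["drop_sex_loci"] and sex_loci:
        keep = ~np.array(
            [(c, p) in sex_loci for c, p in zip(out.chrom, out.pos)], dtype=bool
        )
        out = out.take_loci(keep)
    return filter_individuals(out, max_indiv_missing=max_indiv_missing)
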