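"""Reading, writing and filtering pseudo-haploid datasets.

Native on-disk format is the EIGENSTRAT triplet (``.geno``/``.snp``/``.ind``):
the geno file holds one line per SNP with one character per individual
(``9`` = missing), which fits single-allele data naturally and interoperates
with the f-statistics ecosystem.  VCF input is supported by random
haploidization of diploid GT fields.  The filters implement the standard
PLINK-style site/individual screens for sparse data: minor-allele frequency,
minor-allele count, per-site and per-individual missingness.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_eigenstrat",
    "write_eigenstrat",
    "read_vcf_haploidize",
    "write_vcf",
    "filter_snps",
    "filter_snps_by_count",
    "filter_individuals",
    "GroupFrequencies",
    "group_allele_frequencies",
]

_GENO_TO_CODE = {"0": 0, "1": 1, "2": 2, "9": MISSING}
_CODE_TO_GENO = {0: "0", 1: "1", 2: "2", MISSING: "9"}


# ---------------------------------------------------------------------------
# EIGENSTRAT triplet
# ---------------------------------------------------------------------------

def write_eigenstrat(dataset: Dataset, prefix: str | Path) -> None:
    """Write ``<prefix>.geno``, ``<prefix>.snp`` and ``<prefix>.ind``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.geno", "w") as fh:
        for j in range(dataset.n_snps):
            fh.write("".join(_CODE_TO_GENO[int(v)] for v in dataset.calls[:, j]) + "\n")
    snp = dataset.snps
    with open(f"{prefix}.snp", "w") as fh:
        for row in snp.itertuples(index=False):
            fh.write(f"{row.snp_id}\t{row.chrom}\t0.0\t{row.pos}\t{row.ref}\t{row.alt}\n")
    with open(f"{prefix}.ind", "w") as fh:
        for row in dataset.samples.itertuples(index=False):
            fh.write(f"{row.sample_id}\tU\t{row.group}\n")


def read_eigenstrat(prefix: str | Path, haploid: bool = True) -> Dataset:
    """Read an EIGENSTRAT triplet written by :func:`write_eigenstrat`.

    With ``haploid=True`` (strict mode, the native convention here) a ``2``
    in the geno file is an error; with ``haploid=False`` diploid dosages are
    preserved as-is for the caller to haploidize.
    """
    prefix = Path(prefix)
    snp_rows = []
    with open(f"{prefix}.snp") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{prefix}.snp line {ln}: expected 6 columns, got {len(parts)}")
            snp_rows.append((parts[0], parts[1], int(parts[3]), parts[4], parts[5]))
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])

    ind_rows = []
    with open(f"{prefix}.ind") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{prefix}.ind line {ln}: expected 3 columns, got {len(parts)}")
            ind_rows.append((parts[0], parts[2]))
    samples = pd.DataFrame(ind_rows, columns=["sample_id", "group"])
    samples["n_calls"] = 0

    n_ind = len(samples)
    calls = np.empty((len(snps), n_ind), dtype=np.int8)
    with open(f"{prefix}.geno") as fh:
        ln = 0
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if len(line) != n_ind:
                raise ValueError(
                    f"{prefix}.geno line {ln}: {len(line)} genotypes for {n_ind} individuals"
                )
            try:
                calls[ln - 1] = [_GENO_TO_CODE[ch] for ch in line]
            except KeyError as exc:
                raise ValueError(
                    f"{prefix}.geno line {ln}: genotype symbol {exc.args[0]!r} "
                    "outside {0,1,2,9}"
                ) from None
        if ln != len(snps):
            raise ValueError(f"{prefix}.geno has {ln} lines but {prefix}.snp lists {len(snps)} SNPs")
    dataset = Dataset(calls.T, snps, samples)
    if haploid:
        dataset.validate_calls(haploid=True)
    return dataset


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_haploidize(path: str | Path, seed=None) -> Dataset:
    """Read a VCF and draw one allele per diploid GT uniformly at random.

    Multi-allelic records are skipped (count logged); half-calls and ``./.``
    become missing.  Requires GT in the FORMAT field.
    """
    from cyvcf2 import VCF

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path}: no samples in VCF header")

    cols, snp_rows, n_multi = [], [], 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gts = variant.genotype.array()  # (n_samples, ploidy+1); -1 = missing allele
        if gts is None:
            raise ValueError(f"{path}: record without GT at {variant.CHROM}:{variant.POS}")
        alleles = gts[:, :-1]
        col = np.full(len(sample_ids), MISSING, dtype=np.int8)
        full = (alleles >= 0).all(axis=1)  # half-calls -> missing
        pick = rng.integers(0, alleles.shape[1], size=len(sample_ids))
        col[full] = alleles[np.arange(len(sample_ids)), pick][full]
        cols.append(col)
        snp_rows.append((
            variant.ID or f"{variant.CHROM}_{variant.POS}",
            variant.CHROM, variant.POS, variant.REF, variant.ALT[0],
        ))
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, path)
    if not cols:
        raise ValueError(f"{path}: no usable biallelic records")
    calls = np.stack(cols, axis=1)
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    samples = pd.DataFrame({"sample_id": sample_ids, "group": "unknown", "n_calls": 0})
    return Dataset(calls, snps, samples)


def write_vcf(dataset: Dataset, path: str | Path) -> None:
    """Write haploid GT calls (``0``/``1``/``.``) as minimal VCF 4.2 text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dataset.snps["chrom"].drop_duplicates():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.sample_ids) + "\n")
        for j, row in enumerate(dataset.snps.itertuples(index=False)):
            gts = "\t".join(gt_map[int(v)] for v in dataset.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _site_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n_called, count of 1 alleles, count of 0 alleles)."""
    observed = calls != MISSING
    n_called = observed.sum(axis=0)
    n_alt = ((calls == 1) & observed).sum(axis=0)
    return n_called, n_alt, n_called - n_alt


def filter_snps(dataset: Dataset, maf_min: float = 0.01, max_missing: float = 0.5) -> Dataset:
    """Keep SNPs with missing fraction <= ``max_missing`` and MAF >= ``maf_min``.

    Minor-allele frequency is computed from pooled non-missing calls across
    all current individuals (PLINK ``--maf``/``--geno`` semantics); the
    missing denominator is the current individual count.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= max_missing <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    n_called, n_alt, n_ref = _site_stats(dataset.calls)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    missing_frac = 1.0 - n_called / dataset.n_individuals
    keep = (missing_frac <= max_missing) & (n_called > 0) & (maf >= maf_min)
    if not keep.any():
        warnings.warn("filter_snps removed every SNP", stacklevel=2)
    return dataset.take_snps(keep)


def filter_snps_by_count(dataset: Dataset, max_missing: float = 0.6,
                         min_minor_count: int = 3) -> Dataset:
    """Keep SNPs with missing fraction <= ``max_missing`` and minor-allele
    count >= ``min_minor_count`` (monomorphic SNPs have count 0 and drop)."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    if min_minor_count < 0:
        raise ValueError("min_minor_count must be non-negative")
    n_called, n_alt, n_ref = _site_stats(dataset.calls)
    minor = np.minimum(n_alt, n_ref)
    missing_frac = 1.0 - n_called / dataset.n_individuals
    keep = (missing_frac <= max_missing) & (minor >= min_minor_count)
    if not keep.any():
        warnings.warn("filter_snps_by_count removed every SNP", stacklevel=2)
    return dataset.take_snps(keep)


def filter_individuals(dataset: Dataset, max_missing: float = 0.7) -> Dataset:
    """Drop individuals whose missing fraction exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    missing_frac = 1.0 - dataset.samples["n_calls"].to_numpy() / dataset.n_snps
    return dataset.take_individuals(missing_frac <= max_missing)


# ---------------------------------------------------------------------------
# Group allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class GroupFrequencies:
    """Per-group allele frequencies with per-cell call counts.

    ``freqs[g, j]`` is the mean of non-missing calls of group *g* at SNP *j*
    (NaN where the group has no call); ``counts[g, j]`` is the number of
    haploid calls behind it.
    """

    groups: list[str]
    freqs: np.ndarray   # (n_groups, n_snps), NaN = unavailable
    counts: np.ndarray  # (n_groups, n_snps) int

    def row(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group label: {group!r}") from None


def group_allele_frequencies(dataset: Dataset, groups=None) -> GroupFrequencies:
    """Pooled haploid allele frequency per group per SNP."""
    indices = dataset.group_indices(groups)
    names = list(indices)
    freqs = np.full((len(names), dataset.n_snps), np.nan)
    counts = np.zeros((len(names), dataset.n_snps), dtype=np.int64)
    for g, name in enumerate(names):
        sub = dataset.calls[indices[name]]
        observed = sub != MISSING
        n = observed.sum(axis=0)
        s = ((sub == 1) & observed).sum(axis=0)
        counts[g] = n
        with np.errstate(invalid="ignore"):
            freqs[g] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return GroupFrequencies(names, freqs, counts)
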