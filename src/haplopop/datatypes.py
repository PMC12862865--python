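"""Core containers for pseudo-haploid genotype data.

The central object is :class:`Dataset`, a bundle of a pseudo-haploid
genotype matrix (individuals x SNPs, values 0/1/missing), a SNP table
(chromosome, 1-based position, alleles) and a sample table (id, group
label, non-missing call count).  All analysis modules operate on it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Internal missing-genotype code (EIGENSTRAT '9' on disk).
MISSING: int = -1

SNP_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")
SAMPLE_COLUMNS = ("sample_id", "group", "n_calls")


def count_calls(calls: np.ndarray) -> np.ndarray:
    """Per-individual count of non-missing genotypes."""
    return np.asarray((calls != MISSING).sum(axis=1))


@dataclass
class Dataset:
    """Pseudo-haploid genotype matrix plus SNP and sample metadata.

    Parameters
    ----------
    calls
        ``(n_individuals, n_snps)`` int8 array.  ``0``/``1`` encode the two
        alleles of the single sampled base; :data:`MISSING` (``-1``) marks
        sites without a usable call.  ``2`` may appear only when a
        diploid-coded file was read with haploid checking disabled.
    snps
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``;
        positions are 1-based and strictly increasing within a chromosome.
    samples
        One row per individual with columns ``sample_id, group, n_calls``.
        ``n_calls`` is recomputed from ``calls`` on construction so it can
        never drift out of sync with the matrix.
    """

    calls: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.ascontiguousarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D (individuals x SNPs) array")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if len(self.samples) != self.calls.shape[0]:
            raise ValueError(
                f"sample table has {len(self.samples)} rows but the call "
                f"matrix has {self.calls.shape[0]} individuals"
            )
        if len(self.snps) != self.calls.shape[1]:
            raise ValueError(
                f"SNP table has {len(self.snps)} rows but the call matrix "
                f"has {self.calls.shape[1]} SNPs"
            )
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        self.samples = self.samples.assign(n_calls=count_calls(self.calls))

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return self.samples["group"].drop_duplicates().tolist()

    def validate_calls(self, haploid: bool = True) -> None:
        """Raise if the matrix contains out-of-range genotype codes."""
        allowed = {0, 1, MISSING} if haploid else {0, 1, 2, MISSING}
        seen = set(np.unique(self.calls).tolist())
        bad = seen - allowed
        if bad:
            raise ValueError(f"genotype codes outside {sorted(allowed)}: {sorted(bad)}")

    # -- subsetting -----------------------------------------------------
    def take_snps(self, index) -> "Dataset":
        """New dataset restricted to the SNPs selected by mask or indices."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Dataset(self.calls[:, index], self.snps.iloc[index], self.samples)

    def take_individuals(self, index) -> "Dataset":
        """New dataset restricted to the individuals selected by mask or indices."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Dataset(self.calls[index], self.snps, self.samples.iloc[index])

    def drop_individuals(self, sample_ids) -> "Dataset":
        drop = set(sample_ids)
        unknown = drop - set(self.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)}")
        keep = ~self.samples["sample_id"].isin(drop).to_numpy()
        return self.take_individuals(keep)

    def group_indices(self, groups=None) -> dict[str, np.ndarray]:
        """Row indices per group label, in the requested (or natural) order."""
        labels = self.samples["group"].to_numpy()
        if groups is None:
            groups = self.groups
        out = {}
        for g in groups:
            idx = np.flatnonzero(labels == g)
            if idx.size == 0:
                raise KeyError(f"unknown or empty group label: {g!r}")
            out[g] = idx
        return out

    def copy(self) -> "Dataset":
        return Dataset(self.calls.copy(), self.snps.copy(), self.samples.copy())


@dataclass
class SimTruth:
    """Generator-side ground truth, consumed only by tests and reports.

    ``true_pop`` records each individual's actual source population (which
    differs from the capture label for planted migrants); ``duplicate_pairs``
    lists sample-id pairs that share an underlying diploid genome.
    """

    true_pop: pd.Series                 # index = sample_id, value = source pop
    duplicate_pairs: list[tuple[str, str]]
    pop_freqs: np.ndarray               # (n_pops, n_snps) true frequencies
    ancestral_freqs: np.ndarray         # (n_snps,)
    pop_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for arr, name in ((self.pop_freqs, "pop_freqs"),
                          (self.ancestral_freqs, "ancestral_freqs")):
            a = np.asarray(arr, dtype=float)
            if a.size and (a.min() < 0.0 or a.max() > 1.0):
                raise ValueError(f"{name} outside [0, 1]")

    def migrants(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Individuals whose capture label differs from their true source."""
        cap = samples.set_index("sample_id")["group"]
        truth = self.true_pop.reindex(cap.index)
        mask = (truth != cap) & truth.notna()
        return pd.DataFrame({
            "sample_id": cap.index[mask],
            "capture_label": cap[mask].to_numpy(),
            "true_source": truth[mask].to_numpy(),
        })
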