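"""f3/f4 statistics over group allele frequencies with block-jackknife errors.

``f3(target; A, B)`` is the mean over usable SNPs of
``(p_target - p_A)(p_target - p_B)`` — the covariance of allele-frequency
differences, i.e. drift shared by A and B relative to the target (with an
outgroup as target, larger values mean a closer A-B relationship).
``f4(A, B; C, D)`` is the mean of ``(p_A - p_B)(p_C - p_D)``: zero under a
tree relating the four groups, and systematically non-zero under gene flow.

No finite-sample heterozygosity correction is applied to f3: the usual
diploid correction is invalid for single-sampled-allele calls, so f3 values
carry an additive sampling-noise term that cancels in comparisons between
configurations (flagged here so absolute f3 values are read with care).

Standard errors come from a weighted delete-one-block jackknife over
genomic blocks of fixed base-pair span, which is robust to linkage between
nearby SNPs; block weights are their usable SNP counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import GroupFrequencies

__all__ = [
    "BlockPartition",
    "FStatResult",
    "block_partition",
    "jackknife_sem",
    "f3_statistic",
    "f4_statistic",
    "enumerate_f3",
    "enumerate_f4",
]


@dataclass
class BlockPartition:
    """Disjoint per-chromosome SNP blocks of bounded base-pair span."""

    blocks: list[tuple[str, int, int, np.ndarray]]  # (chrom, start, end, snp indices)
    block_bp: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, n_snps: int) -> np.ndarray:
        """Block index per SNP."""
        out = np.full(n_snps, -1, dtype=np.int64)
        for b, (_, _, _, idx) in enumerate(self.blocks):
            out[idx] = b
        return out


@dataclass
class FStatResult:
    """One f3/f4 estimate with jackknife error and Z-score."""

    populations: tuple[str, ...]
    estimate: float
    sem: float
    z: float
    n_snps: int
    n_blocks: int
    available: bool = True


def block_partition(snps: pd.DataFrame, block_bp: int = 3_000_000) -> BlockPartition:
    """Greedy contiguous blocks: a new block opens when a SNP's position
    exceeds the current block start + ``block_bp``.  Blocks never span
    chromosomes; positions must be strictly increasing within chromosome."""
    if block_bp <= 0:
        raise ValueError("block_bp must be positive")
    pos = snps["pos"].to_numpy()
    chrom = snps["chrom"].to_numpy()
    blocks = []
    j = 0
    n = len(snps)
    while j < n:
        c = chrom[j]
        start = int(pos[j])
        members = [j]
        j += 1
        while j < n and chrom[j] == c and pos[j] < start + block_bp:
            if pos[j] <= pos[j - 1]:
                raise ValueError(
                    f"SNP table not sorted: {c}:{pos[j]} after {chrom[j-1]}:{pos[j-1]}")
            members.append(j)
            j += 1
        if j < n and chrom[j] == c and pos[j] <= pos[j - 1]:
            raise ValueError(
                f"SNP table not sorted: {c}:{pos[j]} after {chrom[j-1]}:{pos[j-1]}")
        blocks.append((c, start, int(pos[members[-1]]),
                       np.asarray(members, dtype=np.int64)))
    return BlockPartition(blocks, block_bp)


def jackknife_sem(block_estimates, block_weights, overall: float) -> tuple[float, float]:
    """Weighted delete-one-block jackknife standard error.

    ``block_estimates`` are per-block means, ``block_weights`` their sizes
    (SNP counts); ``overall`` is the full-data estimate.  With *g* blocks,
    total weight *n*, ``h_j = n / m_j`` and leave-one-out estimates
    ``theta_{-j}``, the variance is::

        theta_J = g * overall - sum_j (1 - m_j/n) * theta_{-j}
        var = (1/g) * sum_j (h_j*overall - (h_j-1)*theta_{-j} - theta_J)^2 / (h_j - 1)

    which reduces exactly to the classical delete-one formula for equal
    weights.  Returns ``(sem, bias-corrected estimate theta_J)``.
    """
    theta_j = np.asarray(block_estimates, dtype=float)
    m = np.asarray(block_weights, dtype=float)
    if theta_j.shape != m.shape or theta_j.ndim != 1:
        raise ValueError("block estimates and weights must be matching 1-D arrays")
    if theta_j.size < 2:
        raise ValueError("need at least two blocks for a jackknife")
    if np.any(m <= 0):
        raise ValueError("block weights must be positive")
    g = theta_j.size
    n = m.sum()
    total = (m * theta_j).sum()
    loo = (total - m * theta_j) / (n - m)   # theta_{-j}
    h = n / m
    theta_jack = g * overall - ((1.0 - m / n) * loo).sum()
    pseudo = h * overall - (h - 1.0) * loo
    var = ((pseudo - theta_jack) ** 2 / (h - 1.0)).sum() / g
    return float(np.sqrt(var)), float(theta_jack)


def _f_stat(terms: np.ndarray, usable: np.ndarray, partition: BlockPartition,
            populations: tuple[str, ...]) -> FStatResult:
    """Assemble estimate/sem/Z from per-SNP products and a usability mask."""
    n_used = int(usable.sum())
    if n_used == 0:
        return FStatResult(populations, float("nan"), float("nan"), float("nan"),
                           0, 0, available=False)
    estimate = float(terms[usable].mean())
    block_means, block_sizes = [], []
    for _, _, _, idx in partition.blocks:
        mask = usable[idx]
        k = int(mask.sum())
        if k == 0:
            continue
        block_means.append(terms[idx][mask].mean())
        block_sizes.append(k)
    n_blocks = len(block_means)
    if n_blocks < 2:
        return FStatResult(populations, estimate, float("nan"), float("nan"),
                           n_used, n_blocks)
    sem, _ = jackknife_sem(np.array(block_means), np.array(block_sizes), estimate)
    z = estimate / sem if sem > 0 else float("nan")
    return FStatResult(populations, estimate, sem, z, n_used, n_blocks)


def f3_statistic(freqs: GroupFrequencies, target: str, a: str, b: str,
                 partition: BlockPartition) -> FStatResult:
    """f3(target; a, b): mean of (p_t - p_a)(p_t - p_b) over usable SNPs.

    A SNP is usable when all three groups have at least one call.  No
    finite-sample bias correction is applied (see module docstring).
    """
    if len({target, a, b}) != 3:
        raise ValueError("f3 needs three distinct groups")
    pt = freqs.freqs[freqs.row(target)]
    pa = freqs.freqs[freqs.row(a)]
    pb = freqs.freqs[freqs.row(b)]
    usable = ~(np.isnan(pt) | np.isnan(pa) | np.isnan(pb))
    terms = np.where(usable, (pt - pa) * (pt - pb), 0.0)
    return _f_stat(terms, usable, partition, (target, a, b))


def f4_statistic(freqs: GroupFrequencies, a: str, b: str, c: str, d: str,
                 partition: BlockPartition) -> FStatResult:
    """f4(a, b; c, d): mean of (p_a - p_b)(p_c - p_d) over usable SNPs."""
    if len({a, b, c, d}) != 4:
        raise ValueError("f4 needs four distinct groups")
    rows = [freqs.freqs[freqs.row(g)] for g in (a, b, c, d)]
    usable = ~np.any([np.isnan(r) for r in rows], axis=0)
    terms = np.where(usable, (rows[0] - rows[1]) * (rows[2] - rows[3]), 0.0)
    return _f_stat(terms, usable, partition, (a, b, c, d))


def enumerate_f3(freqs: GroupFrequencies, partition: BlockPartition) -> pd.DataFrame:
    """f3 for every (target; a, b) with a < b, deterministic order.

    Configurations without any usable SNP are kept with NaN values and
    ``available=False`` rather than dropped.
    """
    names = freqs.groups
    if len(names) < 3:
        raise ValueError("need at least three groups")
    rows = []
    for target in names:
        others = sorted(g for g in names if g != target)
        for a, b in combinations(others, 2):
            r = f3_statistic(freqs, target, a, b, partition)
            rows.append((target, a, b, r.estimate, r.sem, r.z, r.n_snps,
                         r.n_blocks, r.available))
    return pd.DataFrame(rows, columns=["target", "a", "b", "f3", "sem", "z",
                                       "n_snps", "n_blocks", "available"])


def enumerate_f4(freqs: GroupFrequencies, partition: BlockPartition) -> pd.DataFrame:
    """f4 for every canonical quartet: a < b, c < d, (a, b) < (c, d).

    Each unordered 4-set of groups contributes its three distinct pairings.
    """
    names = sorted(freqs.groups)
    if len(names) < 4:
        raise ValueError("need at least four groups")
    rows = []
    for quartet in combinations(names, 4):
        w, x, y, z = quartet
        for (a, b), (c, d) in (((w, x), (y, z)), ((w, y), (x, z)), ((w, z), (x, y))):
            r = f4_statistic(freqs, a, b, c, d, partition)
            rows.append((a, b, c, d, r.estimate, r.sem, r.z, r.n_snps,
                         r.n_blocks, r.available))
    return pd.DataFrame(rows, columns=["pop1", "pop2", "pop3", "pop4", "f4",
                                       "sem", "z", "n_snps", "n_blocks", "available"])
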