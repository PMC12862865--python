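"""Weir-Cockerham F_ST for pseudo-haploid groups with permutation p-values.

The estimator is the haploid-sample adaptation of the Weir-Cockerham
variance-components ANOVA: treating each pseudo-haploid call as one sampled
allele, per usable SNP with group call counts ``n_i``, sample frequencies
``p_i``, ``N = sum n_i``, ``r`` groups with data and weighted mean
``pbar = sum n_i p_i / N``::

    MSP = sum n_i (p_i - pbar)^2 / (r - 1)        # among groups
    MSG = sum n_i p_i (1 - p_i)  / sum (n_i - 1)  # within groups
    n_c = (N - sum n_i^2 / N) / (r - 1)
    a   = MSP - MSG                               # locus numerator
    b   = MSP + (n_c - 1) MSG                     # locus denominator

``theta = sum a / sum b`` over loci (ratio of averages, the standard
multi-locus form, stable under rare SNPs).  A SNP is usable when at least
two groups have calls, the within-group degrees of freedom are positive and
the pooled frequency is polymorphic.

Significance follows a label permutation scheme: group labels are randomly
reassigned among the listed individuals (sizes preserved), the identical
statistic recomputed each time, and the empirical p-value is
``(#{permuted >= observed} + 1) / (n_perm + 1)`` — ties count as
exceedances and p can never be exactly zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import MISSING, Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "FstResult",
    "wc_theta",
    "wc_theta_from_counts",
    "empirical_pvalue",
    "permutation_test",
    "pairwise_fst_table",
]


@dataclass
class FstResult:
    """One F_ST estimate with its permutation test summary."""

    groups: tuple[str, ...]
    theta: float
    n_snps_used: int
    n_perm: int = 0
    n_exceed: int = 0

    @property
    def p_empirical(self) -> float:
        """(n_exceed + 1) / (n_perm + 1), exact rational, NaN without perms."""
        if self.n_perm == 0:
            return float("nan")
        return empirical_pvalue(self.n_exceed, self.n_perm)


def empirical_pvalue(n_exceed: int, n_perm: int) -> float:
    """Permutation p-value ``(n_exceed + 1) / (n_perm + 1)``.

    Computed as an exact rational before conversion to float; bounded below
    by ``1 / (n_perm + 1)`` and above by 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 <= n_exceed <= n_perm:
        raise ValueError(f"n_exceed must lie in [0, {n_perm}], got {n_exceed}")
    return float(Fraction(n_exceed + 1, n_perm + 1))


def _group_counts(calls01: np.ndarray, observed: np.ndarray,
                  onehot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(allele-1 sums, call counts), each (n_groups, n_snps)."""
    return onehot @ calls01, onehot @ observed


def wc_theta_from_counts(alt_sums: np.ndarray, call_counts: np.ndarray,
                         return_components: bool = False):
    """Multi-locus theta from per-group allele-1 sums and call counts.

    Rows are groups, columns SNPs.  Returns ``theta`` (NaN when no SNP is
    usable) or ``(theta, a, b, usable)`` with per-locus components.
    """
    s = np.asarray(alt_sums, dtype=float)
    c = np.asarray(call_counts, dtype=float)
    if s.shape != c.shape or s.ndim != 2:
        raise ValueError("alt_sums and call_counts must be matching 2-D arrays")
    has_data = c > 0
    r = has_data.sum(axis=0).astype(float)           # groups with data per SNP
    N = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(has_data, s / np.maximum(c, 1), 0.0)
        pbar = s.sum(axis=0) / np.maximum(N, 1)
        df_within = N - r                            # sum (n_i - 1) over groups with data
        msp = (c * (p - pbar) ** 2).sum(axis=0) / np.maximum(r - 1, 1)
        msg = (c * p * (1.0 - p)).sum(axis=0) / np.maximum(df_within, 1)
        n_c = (N - (c ** 2).sum(axis=0) / np.maximum(N, 1)) / np.maximum(r - 1, 1)
    usable = (r >= 2) & (df_within > 0) & (pbar > 0) & (pbar < 1)
    a = np.where(usable, msp - msg, 0.0)
    b = np.where(usable, msp + (n_c - 1.0) * msg, 0.0)
    denom = b[usable].sum()
    theta = a[usable].sum() / denom if usable.any() and denom != 0 else float("nan")
    if return_components:
        return theta, a, b, usable
    return theta


def wc_theta(dataset: Dataset, groups=None, return_components: bool = False):
    """Weir-Cockerham theta across the listed groups of a dataset."""
    indices = dataset.group_indices(groups)
    observed = (dataset.calls != MISSING).astype(np.float64)
    calls01 = (dataset.calls == 1).astype(np.float64)
    onehot = np.zeros((len(indices), dataset.n_individuals))
    for g, idx in enumerate(indices.values()):
        onehot[g, idx] = 1.0
    alt_sums, call_counts = _group_counts(calls01, observed, onehot)
    return wc_theta_from_counts(alt_sums, call_counts, return_components)


def permutation_test(dataset: Dataset, groups=None, n_perm: int = 2500,
                     seed=None, scope: str = "all",
                     statistic_groups=None) -> FstResult:
    """Label-permutation empirical p-value for Weir-Cockerham theta.

    ``groups`` are the labels whose individuals enter the permutation pool
    (sizes preserved).  By default the statistic is theta across those same
    groups; ``statistic_groups`` restricts the statistic to a subset (e.g. a
    single pair) while still permuting labels across the whole pool
    (``scope="all"``) or only among the statistic's own groups
    (``scope="pair"``).  Permutations on which the statistic is undefined
    are redrawn and the event logged.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scope not in ("all", "pair"):
        raise ValueError("scope must be 'all' or 'pair'")
    indices = dataset.group_indices(groups)
    group_names = list(indices)
    if statistic_groups is None:
        statistic_groups = group_names
    else:
        statistic_groups = list(statistic_groups)
        unknown = set(statistic_groups) - set(group_names)
        if unknown:
            raise KeyError(f"statistic groups not in permutation pool: {sorted(unknown)}")
    if scope == "pair":
        indices = {g: indices[g] for g in statistic_groups}
        group_names = statistic_groups

    pool = np.concatenate([indices[g] for g in group_names])
    labels = np.concatenate([
        np.full(len(indices[g]), group_names.index(g)) for g in group_names
    ])
    stat_rows = [group_names.index(g) for g in statistic_groups]

    observed_m = (dataset.calls[pool] != MISSING).astype(np.float64)
    calls01 = ((dataset.calls[pool] == 1)).astype(np.float64)

    def theta_for(label_vec: np.ndarray) -> float:
        onehot = np.zeros((len(group_names), len(pool)))
        onehot[label_vec, np.arange(len(pool))] = 1.0
        alt, cnt = _group_counts(calls01, observed_m, onehot)
        return wc_theta_from_counts(alt[stat_rows], cnt[stat_rows])

    theta_obs, a, b, usable = wc_theta(
        dataset, groups=statistic_groups, return_components=True)
    if np.isnan(theta_obs):
        raise ValueError("observed statistic undefined (all groups monomorphic?)")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_exceed = 0
    done = 0
    while done < n_perm:
        perm = theta_for(rng.permutation(labels))
        if np.isnan(perm):
            logger.info("statistic undefined on a permutation; redrawing")
            continue
        if perm >= theta_obs:
            n_exceed += 1
        done += 1
    return FstResult(tuple(statistic_groups), float(theta_obs), int(usable.sum()),
                     n_perm, n_exceed)


def pairwise_fst_table(dataset: Dataset, groups=None, subsets=(),
                       n_perm: int = 0, seed=None, scope: str = "all") -> pd.DataFrame:
    """Theta (and optional permutation p) for every unordered group pair.

    Adds a multi-group row over all listed groups, plus one row per entry
    of ``subsets`` (each an iterable of labels).  Pair rows are ordered
    lexicographically.  With ``n_perm > 0`` each row gets an empirical
    p-value; pairwise rows permute labels across the full pool by default
    (``scope="all"``) or only within the pair (``scope="pair"``).
    """
    indices = dataset.group_indices(groups)
    names = sorted(indices)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    configs: list[tuple[str, str, list[str]]] = [
        (g1, g2, [g1, g2]) for g1, g2 in combinations(names, 2)
    ]
    configs.append(("Multi", "all", names))
    for sub in subsets:
        sub = sorted(sub)
        configs.append(("Multi", "subset:" + "+".join(sub), sub))

    rows = []
    for pair1, pair2, stat_groups in configs:
        if n_perm > 0:
            res = permutation_test(dataset, groups=names, n_perm=n_perm, seed=rng,
                                   scope=scope, statistic_groups=stat_groups)
            rows.append((pair1, pair2, res.theta, res.n_snps_used,
                         res.n_exceed, res.p_empirical))
        else:
            theta, a, b, usable = wc_theta(dataset, groups=stat_groups,
                                           return_components=True)
            rows.append((pair1, pair2, theta, int(usable.sum()), np.nan, np.nan))
    return pd.DataFrame(rows, columns=["pair1", "pair2", "fst", "n_snps",
                                       "n_exceed", "p_empirical"])
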