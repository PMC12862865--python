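"""Pairwise mismatch rates (PMR) and duplicate screening.

The PMR of a pair is the fraction of SNPs called in both individuals at
which their single sampled alleles differ.  Under Hardy-Weinberg
proportions an unrelated pair mismatches at rate ``2pq`` per site while two
independent draws from the same diploid individual mismatch at ``pq`` —
half the unrelated rate — so duplicate libraries, identical twins and
mislabelled resamples stand out as pairs whose PMR is about half the
within-group median.  More generally a pair with coefficient of
relationship *r* has expected PMR ``baseline * (1 - r/2)``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "PmrResult",
    "pairwise_mismatch",
    "pmr_matrix",
    "expected_pmr",
    "detect_duplicates",
    "resolve_duplicates",
]


@dataclass(frozen=True)
class PmrResult:
    """Mismatch summary for one unordered pair of individuals."""

    pair: tuple[str, str]
    n_overlap: int
    n_mismatch: int

    @property
    def pmr(self) -> float:
        """Mismatch fraction; NaN (undefined) when the pair never overlaps."""
        return self.n_mismatch / self.n_overlap if self.n_overlap else float("nan")


def pairwise_mismatch(a: np.ndarray, b: np.ndarray,
                      ids: tuple[str, str] = ("a", "b")) -> PmrResult:
    """PMR of two haploid call rows of equal length."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"rows must be 1-D of equal length, got {a.shape} vs {b.shape}")
    both = (a != MISSING) & (b != MISSING)
    return PmrResult(tuple(ids), int(both.sum()), int((a[both] != b[both]).sum()))


def pmr_matrix(dataset: Dataset, min_overlap: int = 500) -> pd.DataFrame:
    """All-pairs PMR table.

    Returns one row per unordered pair with columns ``id1, id2, n_overlap,
    n_mismatch, pmr, group1, group2, low_overlap``.  Pairs with overlap
    below ``min_overlap`` are flagged, never dropped.
    """
    if dataset.n_individuals < 2:
        raise ValueError("need at least two individuals")
    obs0 = ((dataset.calls == 0)).astype(np.float32)
    obs1 = ((dataset.calls == 1)).astype(np.float32)
    overlap = (obs0 + obs1) @ (obs0 + obs1).T
    mismatch = obs0 @ obs1.T + obs1 @ obs0.T

    ids = dataset.sample_ids
    grp = dataset.samples["group"].to_numpy()
    i, k = np.triu_indices(dataset.n_individuals, k=1)
    n_over = np.rint(overlap[i, k]).astype(np.int64)
    n_mis = np.rint(mismatch[i, k]).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        pmr = np.where(n_over > 0, n_mis / np.maximum(n_over, 1), np.nan)
    return pd.DataFrame({
        "id1": np.asarray(ids)[i],
        "id2": np.asarray(ids)[k],
        "n_overlap": n_over,
        "n_mismatch": n_mis,
        "pmr": pmr,
        "group1": grp[i],
        "group2": grp[k],
        "low_overlap": n_over < min_overlap,
    })


def expected_pmr(r: float, baseline: float) -> float:
    """Expected PMR of a pair with coefficient of relationship *r*.

    ``baseline`` is the PMR of unrelated individuals from the same
    population; the pair shares a fraction *r* of alleles identical by
    descent, and shared alleles mismatch at half the unshared rate, giving
    ``baseline * (1 - r/2)`` (r = 1, duplicates/twins, halves the PMR).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if not 0.0 <= baseline <= 1.0:
        raise ValueError("baseline must lie in [0, 1]")
    return baseline * (1.0 - r / 2.0)


def detect_duplicates(pairs: pd.DataFrame, samples: pd.DataFrame,
                      factor: float = 0.6, min_overlap: int = 500) -> pd.DataFrame:
    """Flag pairs whose PMR falls below ``factor`` x the group median PMR.

    The reference median is taken over within-group pairs of the pair's own
    group (both members in the same group with >= 3 members, hence >= 3
    pairs); otherwise the global median of within-group PMRs is used and a
    warning is logged.  Pairs under ``min_overlap`` are never flagged.
    The default ``factor`` 0.6 sits midway between the 0.5 expectation for
    duplicates and 1.0 for unrelated pairs.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError("factor must lie in [0, 1]")
    usable = pairs[(pairs["n_overlap"] >= min_overlap) & pairs["pmr"].notna()]
    within = usable[usable["group1"] == usable["group2"]]
    global_median = float(within["pmr"].median()) if len(within) else float("nan")
    group_sizes = samples["group"].value_counts()
    medians = {}
    for g, sub in within.groupby("group1"):
        if group_sizes.get(g, 0) >= 3:
            medians[g] = float(sub["pmr"].median())

    rows = []
    for row in usable.itertuples(index=False):
        if row.group1 == row.group2 and row.group1 in medians:
            ref = medians[row.group1]
            context = row.group1
        else:
            ref = global_median
            context = "global"
            if row.group1 == row.group2:
                logger.warning(
                    "group %s too small for a median; pair (%s, %s) compared "
                    "against the global median", row.group1, row.id1, row.id2)
        if np.isnan(ref):
            continue
        if row.pmr <= factor * ref:
            rows.append((row.id1, row.id2, row.n_overlap, row.n_mismatch,
                         row.pmr, context, ref))
    return pd.DataFrame(rows, columns=["id1", "id2", "n_overlap", "n_mismatch",
                                       "pmr", "group_context", "reference_median"])


def resolve_duplicates(flagged: pd.DataFrame, samples: pd.DataFrame) -> list[str]:
    """Individuals to drop so each duplicate cluster keeps one member.

    Flagged pairs form a graph; per connected component the individual with
    the largest non-missing call count is kept, ties broken by keeping the
    lexicographically smallest sample id (logged).
    """
    n_calls = samples.set_index("sample_id")["n_calls"]
    unknown = (set(flagged["id1"]) | set(flagged["id2"])) - set(n_calls.index)
    if unknown:
        raise KeyError(f"flagged pairs reference unknown samples: {sorted(unknown)}")

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row in flagged.itertuples(index=False):
        for node in (row.id1, row.id2):
            parent.setdefault(node, node)
        ra, rb = find(row.id1), find(row.id2)
        if ra != rb:
            parent[ra] = rb

    components: dict[str, list[str]] = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    drop: list[str] = []
    for members in components.values():
        ranked = sorted(members, key=lambda s: (-n_calls[s], s))
        keep = ranked[0]
        if len(ranked) > 1 and n_calls[ranked[1]] == n_calls[keep]:
            logger.info("coverage tie in duplicate cluster %s: keeping %s "
                        "(lexicographic)", sorted(members), keep)
        drop.extend(ranked[1:])
    return sorted(drop)
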