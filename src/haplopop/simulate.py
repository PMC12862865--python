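"""Synthetic pseudo-haploid datasets with known truth.

The generator emulates the statistical structure of sparse
reduced-representation SNP data from several weakly differentiated
populations: Balding-Nichols population allele frequencies around a shared
ancestral frequency, binomial diploid genotypes (optionally admixed),
random single-allele (pseudo-haploid) calls, heavy per-individual missing
data, technical duplicate individuals, and "migrant" individuals whose
true source population differs from the label under which they were
sampled.  The accompanying :class:`~haplopop.datatypes.SimTruth` records
everything the generator knows, so parameter-recovery and detection tests
can score results against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, Dataset, SimTruth

__all__ = [
    "SimConfig",
    "draw_ancestral_frequencies",
    "balding_nichols_frequencies",
    "simulate_diploids",
    "pseudo_haploidize",
    "make_duplicate",
    "apply_missingness",
    "assign_snp_positions",
    "build_dataset",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_ancestral_frequencies(n_snps: int, low: float = 0.05, high: float = 0.95,
                               seed=None) -> np.ndarray:
    """Ancestral allele frequencies drawn uniformly on [low, high]."""
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if not (0.0 < low <= high < 1.0):
        raise ValueError(f"require 0 < low <= high < 1, got low={low}, high={high}")
    return _rng(seed).uniform(low, high, size=n_snps)


def balding_nichols_frequencies(ancestral: np.ndarray, pop_F, seed=None) -> np.ndarray:
    """Per-population frequencies under the Balding-Nichols model.

    Population *k* with divergence parameter ``F_k`` draws its frequency at
    SNP *j* from ``Beta(p_j (1-F_k)/F_k, (1-p_j)(1-F_k)/F_k)``, which has
    mean ``p_j`` and variance ``F_k p_j (1-p_j)``.  ``F_k = 0`` reproduces
    the ancestral frequencies exactly (no drift).
    """
    ancestral = np.asarray(ancestral, dtype=float)
    pop_F = np.atleast_1d(np.asarray(pop_F, dtype=float))
    if np.any((pop_F < 0.0) | (pop_F >= 1.0)):
        raise ValueError("each F must lie in [0, 1); F = 1 is a degenerate Beta")
    if np.any((ancestral <= 0.0) | (ancestral >= 1.0)):
        if np.any(pop_F > 0.0):
            raise ValueError("ancestral frequencies must lie in (0, 1) when F > 0")
    rng = _rng(seed)
    out = np.empty((pop_F.size, ancestral.size), dtype=float)
    for k, F in enumerate(pop_F):
        if F == 0.0:
            out[k] = ancestral
        else:
            scale = (1.0 - F) / F
            out[k] = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
    return out


def simulate_diploids(pop_freqs: np.ndarray, admixture: np.ndarray, seed=None) -> np.ndarray:
    """Diploid dosages (0/1/2): Binomial(2, q) with q = admixture @ pop_freqs.

    ``admixture`` is (n_individuals, n_pops) with rows summing to 1; pure
    individuals use one-hot rows.
    """
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    admixture = np.atleast_2d(np.asarray(admixture, dtype=float))
    if admixture.shape[1] != pop_freqs.shape[0]:
        raise ValueError(
            f"admixture has {admixture.shape[1]} ancestry columns but there "
            f"are {pop_freqs.shape[0]} populations"
        )
    if not np.allclose(admixture.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("admixture rows must sum to 1")
    q = admixture @ pop_freqs
    return _rng(seed).binomial(2, q).astype(np.int8)


def pseudo_haploidize(diploid: np.ndarray, seed=None) -> np.ndarray:
    """One random allele per genotype: 0 -> 0, 2 -> 1, 1 -> fair coin.

    Missing entries stay missing.  This is the random-read genotyping used
    for data too shallow for reliable diploid calls.
    """
    diploid = np.asarray(diploid)
    valid = {0, 1, 2, MISSING}
    seen = set(np.unique(diploid).tolist())
    if seen - valid:
        raise ValueError(f"diploid genotypes outside {{0,1,2,missing}}: {sorted(seen - valid)}")
    out = np.where(diploid == 2, 1, diploid).astype(np.int8)
    het = diploid == 1
    if het.any():
        out[het] = _rng(seed).integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def make_duplicate(diploid_row: np.ndarray, seed=None) -> np.ndarray:
    """An independent pseudo-haploid draw from the same diploid genotypes.

    Models a second, independently built library of the same individual:
    homozygous sites reproduce exactly, heterozygous sites disagree with the
    first draw with probability 1/2.
    """
    diploid_row = np.asarray(diploid_row)
    if diploid_row.ndim != 1:
        raise ValueError("expected a single diploid row")
    return pseudo_haploidize(diploid_row, seed=seed)


def apply_missingness(matrix: np.ndarray, per_individual_rate, seed=None) -> np.ndarray:
    """Mask each observed call independently at the individual's rate (MCAR)."""
    matrix = np.asarray(matrix)
    rates = np.broadcast_to(
        np.atleast_1d(np.asarray(per_individual_rate, dtype=float)), (matrix.shape[0],)
    )
    if np.any((rates < 0.0) | (rates >= 1.0)):
        raise ValueError("missing rates must lie in [0, 1)")
    mask = _rng(seed).random(matrix.shape) < rates[:, None]
    out = matrix.astype(np.int8, copy=True)
    out[mask] = MISSING
    return out


def assign_snp_positions(n_snps: int, chrom_lengths, seed=None) -> pd.DataFrame:
    """Distinct sorted 1-based SNP positions, chromosomes weighted by length."""
    lengths = np.asarray(chrom_lengths, dtype=np.int64)
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    total = int(lengths.sum())
    if n_snps > total:
        raise ValueError(f"cannot place {n_snps} distinct SNPs on {total} bp")
    rng = _rng(seed)
    counts = rng.multinomial(n_snps, lengths / total)
    # redistribute overflow from saturated chromosomes
    while np.any(counts > lengths):
        over = counts > lengths
        excess = int((counts - lengths)[over].sum())
        counts[over] = lengths[over]
        room = lengths - counts
        order = np.argsort(-room)
        for i in order:
            if excess == 0:
                break
            add = min(excess, int(room[i]))
            counts[i] += add
            excess -= add
    rows = []
    for c, (count, length) in enumerate(zip(counts, lengths), start=1):
        if count == 0:
            continue
        if count == length:
            pos = np.arange(1, length + 1, dtype=np.int64)
        elif count > length // 2:
            pos = np.sort(rng.permutation(length)[:count]) + 1
        else:
            chosen: set[int] = set()
            while len(chosen) < count:
                draw = rng.integers(0, length, size=count - len(chosen))
                chosen.update(draw.tolist())
            pos = np.sort(np.fromiter(chosen, dtype=np.int64, count=count)) + 1
        rows.append(pd.DataFrame({"chrom": f"chr{c}", "pos": pos}))
    snps = pd.concat(rows, ignore_index=True)
    snps.insert(0, "snp_id", [f"snp{i:07d}" for i in range(len(snps))])
    snps["ref"] = "A"
    snps["alt"] = "T"
    return snps


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset.

    ``migrants`` lists ``(capture_label, true_source_pop, count)`` triples:
    ``count`` individuals carrying ``capture_label`` in the sample table are
    actually drawn from ``true_source_pop``.  ``duplicate_pairs`` technical
    duplicates are appended after the base individuals, re-sampled from the
    same diploid genomes.  ``missing_rate`` is a scalar, a per-individual
    sequence, or a ``(low, high)`` range sampled per individual.
    """

    n_pops: int = 6
    n_snps: int = 20_000
    chrom_lengths: tuple = tuple([15_000_000] * 10)
    pop_F: tuple = (0.09, 0.05, 0.03, 0.03, 0.035, 0.09)
    sample_sizes: tuple = (8, 7, 26, 25, 22, 26)
    admixture: np.ndarray | None = None          # default: pure (one-hot) rows
    missing_rate: float | tuple = (0.2, 0.6)
    duplicate_pairs: int = 0
    migrants: list = field(default_factory=list)
    migrant_source_fraction: float = 1.0         # 1.0 = pure-source migrants
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    pop_names: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops <= 0 or self.n_snps <= 0:
            raise ValueError("n_pops and n_snps must be positive")
        if len(self.pop_F) != self.n_pops or len(self.sample_sizes) != self.n_pops:
            raise ValueError("pop_F and sample_sizes must have one entry per population")
        if any(s <= 0 for s in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.duplicate_pairs < 0:
            raise ValueError("duplicate_pairs must be non-negative")
        if not self.pop_names:
            self.pop_names = tuple(f"P{k + 1}" for k in range(self.n_pops))
        if len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names must have one entry per population")
        per_capture: dict[str, int] = {}
        for capture, source, count in self.migrants:
            if capture not in self.pop_names or source not in self.pop_names:
                raise ValueError(f"migrant labels {capture!r}/{source!r} not in pop_names")
            if count <= 0:
                raise ValueError("migrant counts must be positive")
            per_capture[capture] = per_capture.get(capture, 0) + count
        for capture, count in per_capture.items():
            size = self.sample_sizes[self.pop_names.index(capture)]
            if count > size:
                raise ValueError(
                    f"{count} migrants exceed the {size} individuals labelled {capture!r}"
                )


def _missing_rates(config: SimConfig, n_total: int, rng: np.random.Generator) -> np.ndarray:
    mr = config.missing_rate
    if np.isscalar(mr):
        return np.full(n_total, float(mr))
    mr = np.asarray(mr, dtype=float)
    if mr.shape == (2,) and n_total != 2:
        return rng.uniform(mr[0], mr[1], size=n_total)
    if mr.size == n_total:
        return mr
    raise ValueError("missing_rate must be scalar, a (low, high) pair, or per-individual")


def build_dataset(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Generate one dataset plus its ground truth.

    Individuals are laid out population by population; within each capture
    group the last ``count`` individuals of each migrant triple are replaced
    by pure draws from the true source population (their capture label is
    unchanged).  Duplicates are appended with ids suffixed ``_dup``.
    """
    rng = np.random.default_rng(config.seed)
    anc = draw_ancestral_frequencies(config.n_snps, config.ancestral_low,
                                     config.ancestral_high, seed=rng)
    pop_freqs = balding_nichols_frequencies(anc, config.pop_F, seed=rng)

    names = list(config.pop_names)
    capture, true_pop, ids = [], [], []
    for k, size in enumerate(config.sample_sizes):
        for i in range(size):
            ids.append(f"{names[k]}_{i + 1:02d}")
            capture.append(names[k])
            true_pop.append(names[k])
    n_base = len(ids)

    if config.admixture is None:
        admixture = np.zeros((n_base, config.n_pops))
        for i, pop in enumerate(true_pop):
            admixture[i, names.index(pop)] = 1.0
    else:
        admixture = np.asarray(config.admixture, dtype=float)
        if admixture.shape != (n_base, config.n_pops):
            raise ValueError("admixture must be (total individuals, n_pops)")

    # plant migrants: overwrite the LAST `count` rows of each capture group
    frac = float(config.migrant_source_fraction)
    if not (0.0 < frac <= 1.0):
        raise ValueError("migrant_source_fraction must lie in (0, 1]")
    taken: dict[str, int] = {}  # rows already claimed per capture group
    for cap, source, count in config.migrants:
        used = taken.get(cap, 0)
        members = [i for i, g in enumerate(capture) if g == cap]
        rows = members[len(members) - used - count: len(members) - used]
        taken[cap] = used + count
        for i in rows:
            admixture[i] = 0.0
            admixture[i, names.index(source)] = frac
            admixture[i, names.index(cap)] += 1.0 - frac
            true_pop[i] = source

    diploid = simulate_diploids(pop_freqs, admixture, seed=rng)

    # technical duplicates: independent haploid redraws of existing genomes
    if config.duplicate_pairs > n_base:
        raise ValueError("more duplicate pairs than individuals")
    dup_sources = rng.choice(n_base, size=config.duplicate_pairs, replace=False)
    haploid = pseudo_haploidize(diploid, seed=rng)
    dup_rows, dup_pairs = [], []
    for src in dup_sources:
        dup_rows.append(make_duplicate(diploid[src], seed=rng))
        dup_id = f"{ids[src]}_dup"
        dup_pairs.append((ids[src], dup_id))
        ids.append(dup_id)
        capture.append(capture[src])
        true_pop.append(true_pop[src])
    if dup_rows:
        haploid = np.vstack([haploid, np.array(dup_rows, dtype=np.int8)])

    rates = _missing_rates(config, haploid.shape[0], rng)
    haploid = apply_missingness(haploid, rates, seed=rng)

    snps = assign_snp_positions(config.n_snps, config.chrom_lengths, seed=rng)
    samples = pd.DataFrame({"sample_id": ids, "group": capture, "n_calls": 0})
    dataset = Dataset(haploid, snps, samples)
    truth = SimTruth(
        true_pop=pd.Series(true_pop, index=ids, name="true_pop"),
        duplicate_pairs=dup_pairs,
        pop_freqs=pop_freqs,
        ancestral_freqs=anc,
        pop_names=names,
    )
    return dataset, truth
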