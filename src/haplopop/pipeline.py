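"""End-to-end orchestration: simulate/load -> filter -> dedupe -> PCA ->
F_ST + permutations -> f3/f4 -> migrant screen -> report.

Stage order follows the standard low-coverage workflow: site filters on the
raw pseudo-haploid matrix, mismatch-rate duplicate removal, individual and
minor-allele-count filters, then the population-structure analyses.  Every
stage logs its survivor counts; all randomness flows from one root seed via
named per-stage substreams so single stages can be reproduced in isolation;
all tables are tab-separated with ``#`` provenance headers.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import Dataset, SimTruth
from .io import (filter_individuals, filter_snps, filter_snps_by_count,
                 group_allele_frequencies, read_eigenstrat, write_eigenstrat)
from .fst import pairwise_fst_table
from .fstats import block_partition, enumerate_f4, f4_statistic
from .pca import PcaResult, pca
from .relatedness import detect_duplicates, pmr_matrix, resolve_duplicates
from .simulate import SimConfig, build_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report",
           "flag_migrants", "replica_config"]

_STAGE_STREAMS = {"simulate": 1, "permutation": 2, "haploidize": 3}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named per-stage substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGE_STREAMS[stage])))


@dataclass
class PipelineConfig:
    """All stage parameters of one run (echoed verbatim into the run log)."""

    sim: SimConfig | None = None          # either simulate ...
    input_prefix: str | None = None       # ... or read an EIGENSTRAT triplet
    maf: float = 0.01
    geno: float = 0.5                     # max per-SNP missing fraction (stage 1)
    mind: float = 0.7                     # max per-individual missing fraction
    geno2: float = 0.6                    # max per-SNP missing fraction (stage 2)
    mac: int = 3                          # min minor-allele count (stage 2)
    pmr_factor: float = 0.6
    min_overlap: int = 500
    n_components: int = 10
    min_pairs: int = 100
    n_perm: int = 2500
    fst_subsets: tuple = ()               # extra multi-group F_ST rows
    block_bp: int = 3_000_000
    migrant_z: float = 2.0
    seed: int = 0
    outdir: str = "haplopop_run"

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # hash the analysis, not where it lands
        if self.sim is not None:
            payload["sim"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                              for k, v in asdict(self.sim).items()}
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def replica_config(seed: int = 0, n_snps: int = 50_000,
                   n_perm: int = 2500, outdir: str = "haplopop_run") -> PipelineConfig:
    """Desk-scale six-population replica: group sizes (8, 7, 26, 25, 22, 26),
    four duplicate pairs and nine planted migrants (2+1 into P3, 1 into P4,
    5 into P5) from genetically distinct sources."""
    sim = SimConfig(
        n_snps=n_snps,
        duplicate_pairs=4,
        migrants=[("P3", "P2", 2), ("P3", "P6", 1), ("P4", "P6", 1), ("P5", "P6", 5)],
        seed=seed,
    )
    return PipelineConfig(sim=sim, n_perm=n_perm, seed=seed, outdir=outdir)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output (all also on disk)."""

    config: PipelineConfig
    dataset: Dataset                  # final filtered dataset
    truth: SimTruth | None
    stage_counts: list[tuple[str, int, int]]   # (stage, n_individuals, n_snps)
    pmr: pd.DataFrame
    flagged_pairs: pd.DataFrame
    dropped: list[str]
    pca: PcaResult
    migrants: pd.DataFrame
    fst: pd.DataFrame
    f4: pd.DataFrame
    outdir: Path


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# haplopop {__version__}\tconfig={config.digest()}\tseed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def flag_migrants(dataset: Dataset, coords: np.ndarray, n_pcs: int,
                  block_bp: int = 3_000_000, z_threshold: float = 2.0) -> pd.DataFrame:
    """Candidate migrants: capture label vs. nearest PC-space group centroid,
    confirmed by an f4 test.

    Each individual is assigned to the group whose centroid over the top
    ``n_pcs`` components is nearest (its own group's centroid excludes it).
    A candidate captured in P but nearest to Q is confirmed when
    ``f4(X, candidate; P, Q) >= z_threshold`` s.e.m. above zero, with X the
    largest group outside {P, Q} and the candidate as a singleton group —
    positive values mean the candidate shares drift with Q, not P.
    """
    labels = dataset.samples["group"].to_numpy()
    ids = np.asarray(dataset.sample_ids)
    groups = dataset.groups
    X = coords[:, :n_pcs]

    rows = []
    for i in range(len(ids)):
        best, best_d = None, np.inf
        for g in groups:
            members = np.flatnonzero((labels == g) & (np.arange(len(ids)) != i))
            if members.size == 0:
                continue
            d = float(np.linalg.norm(X[i] - X[members].mean(axis=0)))
            if d < best_d:
                best, best_d = g, d
        if best is not None and best != labels[i]:
            rows.append((ids[i], labels[i], best))
    if not rows:
        return pd.DataFrame({
            "sample_id": pd.Series(dtype=str),
            "capture_label": pd.Series(dtype=str),
            "nearest_group": pd.Series(dtype=str),
            "f4": pd.Series(dtype=float),
            "sem": pd.Series(dtype=float),
            "z": pd.Series(dtype=float),
            "confirmed": pd.Series(dtype=bool),
        })

    partition = block_partition(dataset.snps, block_bp)
    out = []
    candidate_ids = {r[0] for r in rows}
    for sample_id, cap, near in rows:
        relabel = dataset.samples.copy()
        # candidate becomes a singleton group; other candidates are set aside
        relabel.loc[relabel["sample_id"] == sample_id, "group"] = "cand"
        others = relabel["sample_id"].isin(candidate_ids - {sample_id})
        relabel.loc[others, "group"] = "excluded"
        tmp = Dataset(dataset.calls, dataset.snps, relabel)
        sizes = relabel[~relabel["group"].isin(("cand", "excluded"))]["group"].value_counts()
        ref = next((g for g in sizes.index if g not in (cap, near)), None)
        if ref is None or cap == near:
            out.append((sample_id, cap, near, np.nan, np.nan, np.nan, False))
            continue
        freqs = group_allele_frequencies(tmp, groups=[ref, "cand", cap, near])
        r = f4_statistic(freqs, ref, "cand", cap, near, partition)
        confirmed = bool(np.isfinite(r.z) and r.z >= z_threshold)
        out.append((sample_id, cap, near, r.estimate, r.sem, r.z, confirmed))
    return pd.DataFrame(out, columns=["sample_id", "capture_label", "nearest_group",
                                      "f4", "sem", "z", "confirmed"])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write every table under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: list[tuple[str, int, int]] = []

    def log_stage(name: str, ds: Dataset) -> None:
        counts.append((name, ds.n_individuals, ds.n_snps))
        logger.info("%s: %d individuals x %d SNPs", name, ds.n_individuals, ds.n_snps)

    # stage 0: input
    truth = None
    if config.sim is not None:
        sim_cfg = config.sim
        dataset, truth = build_dataset(sim_cfg)
        write_eigenstrat(dataset, outdir / "simulated")
        truth_df = pd.DataFrame({
            "sample_id": truth.true_pop.index,
            "true_pop": truth.true_pop.to_numpy(),
        })
        truth_df["is_duplicate"] = truth_df["sample_id"].isin(
            [b for _, b in truth.duplicate_pairs])
        _write_table(truth_df, outdir / "sim_truth.tsv", config)
    elif config.input_prefix is not None:
        dataset = read_eigenstrat(config.input_prefix)
    else:
        raise ValueError("config needs either a SimConfig or an input prefix")
    log_stage("input", dataset)

    # stage 1: site filter (MAF + missingness)
    dataset = filter_snps(dataset, maf_min=config.maf, max_missing=config.geno)
    log_stage("snp_filter", dataset)

    # stage 2: mismatch-rate duplicate screen
    pmr = pmr_matrix(dataset, min_overlap=config.min_overlap)
    flagged = detect_duplicates(pmr, dataset.samples, factor=config.pmr_factor,
                                min_overlap=config.min_overlap)
    dropped = resolve_duplicates(flagged, dataset.samples)
    dataset = dataset.drop_individuals(dropped)
    log_stage("dedupe", dataset)

    # stage 3: individual filter, then minor-allele-count filter
    dataset = filter_individuals(dataset, max_missing=config.mind)
    log_stage("individual_filter", dataset)
    dataset = filter_snps_by_count(dataset, max_missing=config.geno2,
                                   min_minor_count=config.mac)
    log_stage("count_filter", dataset)

    # stage 4: PCA and migrant screen
    n_groups = len(dataset.groups)
    pca_res, _sim = pca(dataset, n_components=max(config.n_components, n_groups),
                        min_pairs=config.min_pairs)
    migrants = flag_migrants(dataset, pca_res.coordinates,
                             n_pcs=max(2, n_groups - 1),
                             block_bp=config.block_bp,
                             z_threshold=config.migrant_z)
    confirmed = migrants[migrants["confirmed"]]["sample_id"].tolist()

    # stage 5: F_ST with permutations on the main groups (confirmed migrants
    # set aside, mirroring outlier regrouping)
    core = dataset.drop_individuals(confirmed) if confirmed else dataset
    perm_rng = stage_rng(config.seed, "permutation")
    fst = pairwise_fst_table(core, n_perm=config.n_perm, seed=perm_rng,
                             subsets=config.fst_subsets)

    # stage 6: f4 over the main groups
    freqs = group_allele_frequencies(core)
    partition = block_partition(core.snps, config.block_bp)
    f4 = enumerate_f4(freqs, partition) if len(core.groups) >= 4 else pd.DataFrame(
        columns=["pop1", "pop2", "pop3", "pop4", "f4", "sem", "z",
                 "n_snps", "n_blocks", "available"])

    # outputs
    _write_table(pmr, outdir / "pmr.tsv", config)
    _write_table(flagged, outdir / "flagged_pairs.tsv", config)
    (outdir / "drop_list.txt").write_text("".join(f"{s}\n" for s in dropped))
    coords = pd.DataFrame(
        pca_res.coordinates,
        columns=[f"PC{c + 1}" for c in range(pca_res.coordinates.shape[1])])
    coords.insert(0, "sample_id", pca_res.ids)
    coords.insert(1, "group", dataset.samples["group"].to_numpy())
    _write_table(coords, outdir / "pca_coords.tsv", config)
    _write_table(pd.DataFrame({"eigenvalue": pca_res.eigenvalues}),
                 outdir / "pca_eigenvalues.tsv", config)
    _write_table(migrants, outdir / "migrants.tsv", config)
    _write_table(fst, outdir / "fst.tsv", config)
    _write_table(f4, outdir / "f4.tsv", config)
    _write_table(pd.DataFrame(counts, columns=["stage", "n_individuals", "n_snps"]),
                 outdir / "stage_counts.tsv", config)
    write_eigenstrat(dataset, outdir / "filtered")

    result = PipelineResult(config, dataset, truth, counts, pmr, flagged, dropped,
                            pca_res, migrants, fst, f4, outdir)
    write_report(outdir)
    return result


def write_report(outdir: str | Path, p_threshold: float = 0.05,
                 z_threshold: float = 2.0) -> str:
    """Regenerate the human-readable summary from the on-disk tables alone."""
    outdir = Path(outdir)

    def load(name: str) -> pd.DataFrame:
        return pd.read_csv(outdir / name, sep="\t", comment="#")

    stages = load("stage_counts.tsv")
    eig = load("pca_eigenvalues.tsv")["eigenvalue"].to_numpy()
    fst = load("fst.tsv")
    f4 = load("f4.tsv")
    migrants = load("migrants.tsv")
    dropped = [s for s in (outdir / "drop_list.txt").read_text().splitlines() if s]

    positive = eig[eig > 0].sum()
    top = eig[:2] / positive if positive > 0 else eig[:2] * 0.0
    lines = ["# haplopop run report", "", "## Survivor counts per stage"]
    for row in stages.itertuples(index=False):
        lines.append(f"  {row.stage}: {row.n_individuals} individuals x {row.n_snps} SNPs")
    lines += ["", f"## Duplicates removed ({len(dropped)})"]
    lines += [f"  {s}" for s in dropped] or ["  none"]
    lines += ["", "## PCA",
              f"  PC1 variance explained: {top[0]:.4f}" if len(top) > 0 else "  n/a",
              f"  PC2 variance explained: {top[1]:.4f}" if len(top) > 1 else "  n/a"]
    sig = fst[fst["p_empirical"].notna() & (fst["p_empirical"] <= p_threshold)]
    lines += ["", f"## F_ST rows with empirical p <= {p_threshold} ({len(sig)})"]
    lines += [f"  {r.pair1} vs {r.pair2}: F_ST={r.fst:.4f} p={r.p_empirical:.2e}"
              for r in sig.itertuples(index=False)] or ["  none"]
    strong = f4[f4["z"].notna() & (f4["z"].abs() >= z_threshold)]
    lines += ["", f"## f4 rows with |Z| >= {z_threshold} ({len(strong)})"]
    lines += [f"  f4({r.pop1},{r.pop2};{r.pop3},{r.pop4}) = {r.f4:.5f} Z={r.z:.2f}"
              for r in strong.itertuples(index=False)] or ["  none"]
    conf = migrants[migrants["confirmed"] == True] if len(migrants) else migrants  # noqa: E712
    lines += ["", f"## Migrant candidates confirmed by f4 ({len(conf)})"]
    lines += [f"  {r.sample_id}: captured {r.capture_label}, nearest {r.nearest_group}, "
              f"Z={r.z:.2f}" for r in conf.itertuples(index=False)] or ["  none"]
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text
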