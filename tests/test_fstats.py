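"""Block partitioning, f3/f4 algebra, and the weighted jackknife."""
import numpy as np
import pandas as pd
import pytest

import haplopop as hp


def freq_table(**rows):
    names = list(rows)
    freqs = np.array([rows[g] for g in names], dtype=float)
    counts = np.where(np.isnan(freqs), 0, 10).astype(np.int64)
    return hp.GroupFrequencies(names, freqs, counts)


def snp_table(chrom_pos):
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(chrom_pos))],
        "chrom": [c for c, _ in chrom_pos],
        "pos": [p for _, p in chrom_pos],
        "ref": "A", "alt": "T",
    })


class TestBlockPartition:
    def test_span_boundary_opens_new_block(self):
        part = hp.block_partition(snp_table([("chr1", 1), ("chr1", 3_000_001)]),
                                  block_bp=3_000_000)
        assert part.n_blocks == 2

    def test_single_block_within_span(self):
        part = hp.block_partition(snp_table([("chr1", 1), ("chr1", 500), ("chr1", 900)]),
                                  block_bp=3_000_000)
        assert part.n_blocks == 1
        np.testing.assert_array_equal(part.blocks[0][3], [0, 1, 2])

    def test_blocks_never_span_chromosomes(self):
        part = hp.block_partition(snp_table([("chr1", 1), ("chr2", 2)]), 3_000_000)
        assert part.n_blocks == 2

    def test_exhaustive_span_invariant(self):
        snps = hp.assign_snp_positions(5000, [4_000_000] * 10, seed=81)
        part = hp.block_partition(snps, block_bp=1_000_000)
        seen = np.concatenate([idx for _, _, _, idx in part.blocks])
        assert sorted(seen) == list(range(5000))  # disjoint cover
        pos = snps["pos"].to_numpy()
        for chrom, start, end, idx in part.blocks:
            assert end - start <= 1_000_000
            assert (snps["chrom"].to_numpy()[idx] == chrom).all()
            assert pos[idx].min() == start and pos[idx].max() == end

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            hp.block_partition(snp_table([("chr1", 5), ("chr1", 2)]), 100)


class TestF3:
    def test_hand_arithmetic(self):
        ft = freq_table(t=[0.5, 0.5], a=[0.1, 0.9], b=[0.3, 0.7])
        part = hp.block_partition(snp_table([("chr1", 1), ("chr1", 2)]), 100)
        r = hp.f3_statistic(ft, "t", "a", "b", part)
        assert r.estimate == pytest.approx(0.08)  # (0.4*0.2 + (-0.4)*(-0.2)) / 2

    def test_equal_sister_frequencies_nonnegative(self):
        rng = np.random.default_rng(82)
        p = rng.uniform(0.1, 0.9, 50)
        ft = freq_table(t=rng.uniform(0.1, 0.9, 50), a=p, b=p.copy())
        part = hp.block_partition(snp_table([("chr1", i + 1) for i in range(50)]), 10)
        r = hp.f3_statistic(ft, "t", "a", "b", part)
        assert r.estimate >= 0.0

    def test_shared_drift_ordering(self):
        # sisters A, B share a drift branch absent from C: f3(O; A, B) must
        # exceed f3(O; A, C) in nearly every replicate
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            p0 = rng.uniform(0.2, 0.8, 5000)
            shared = np.clip(p0 + rng.normal(0, 0.08, p0.size), 0.01, 0.99)
            pa = np.clip(shared + rng.normal(0, 0.04, p0.size), 0.005, 0.995)
            pb = np.clip(shared + rng.normal(0, 0.04, p0.size), 0.005, 0.995)
            pc = np.clip(p0 + rng.normal(0, 0.08, p0.size), 0.01, 0.99)
            po = np.clip(p0 + rng.normal(0, 0.08, p0.size), 0.01, 0.99)
            ft = freq_table(o=po, a=pa, b=pb, c=pc)
            part = hp.block_partition(
                snp_table([("chr1", i + 1) for i in range(5000)]), 250)
            fab = hp.f3_statistic(ft, "o", "a", "b", part).estimate
            fac = hp.f3_statistic(ft, "o", "a", "c", part).estimate
            wins += fab > fac
        assert wins >= 19

    def test_distinct_groups_required(self):
        ft = freq_table(t=[0.5], a=[0.1], b=[0.3])
        part = hp.block_partition(snp_table([("chr1", 1)]), 10)
        with pytest.raises(ValueError, match="distinct"):
            hp.f3_statistic(ft, "t", "a", "a", part)


class TestF4:
    def test_hand_arithmetic(self):
        ft = freq_table(a=[0.2, 0.8], b=[0.4, 0.4], c=[0.1, 0.9], d=[0.5, 0.5])
        part = hp.block_partition(snp_table([("chr1", 1), ("chr1", 2)]), 100)
        r = hp.f4_statistic(ft, "a", "b", "c", "d", part)
        assert r.estimate == pytest.approx(0.12)  # ((-0.2)(-0.4) + 0.4*0.4) / 2

    def test_identical_first_pair_is_zero(self):
        rng = np.random.default_rng(83)
        p = rng.uniform(0.1, 0.9, 30)
        ft = freq_table(a=p, b=p.copy(), c=rng.uniform(0.1, 0.9, 30),
                        d=rng.uniform(0.1, 0.9, 30))
        part = hp.block_partition(snp_table([("chr1", i + 1) for i in range(30)]), 5)
        assert hp.f4_statistic(ft, "a", "b", "c", "d", part).estimate == 0.0

    def test_symmetry_algebra(self):
        rng = np.random.default_rng(84)
        ft = freq_table(**{g: rng.uniform(0.1, 0.9, 40) for g in "abcd"})
        part = hp.block_partition(snp_table([("chr1", i + 1) for i in range(40)]), 8)
        base = hp.f4_statistic(ft, "a", "b", "c", "d", part).estimate
        swapped = hp.f4_statistic(ft, "b", "a", "c", "d", part).estimate
        pairs = hp.f4_statistic(ft, "c", "d", "a", "b", part).estimate
        assert swapped == pytest.approx(-base, abs=1e-12)
        assert pairs == pytest.approx(base, abs=1e-12)

    def test_additivity_in_first_slot(self):
        # f4(A,B;C,D) = f4(A,X;C,D) + f4(X,B;C,D), exact per SNP
        rng = np.random.default_rng(85)
        ft = freq_table(**{g: rng.uniform(0.1, 0.9, 25) for g in "abcdx"})
        part = hp.block_partition(snp_table([("chr1", i + 1) for i in range(25)]), 5)
        whole = hp.f4_statistic(ft, "a", "b", "c", "d", part).estimate
        left = hp.f4_statistic(ft, "a", "x", "c", "d", part).estimate
        right = hp.f4_statistic(ft, "x", "b", "c", "d", part).estimate
        assert whole == pytest.approx(left + right, abs=1e-12)


class TestJackknife:
    def test_identical_blocks_zero_sem(self):
        sem, _ = hp.jackknife_sem([0.3] * 5, [10, 20, 10, 5, 8], 0.3)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_equal_weights_reduce_to_classical(self):
        est = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        overall = est.mean()
        g = len(est)
        loo = (est.sum() - est) / (g - 1)
        classical = np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
        sem, _ = hp.jackknife_sem(est, [7] * 5, overall)
        assert sem == pytest.approx(classical, abs=1e-12)

    def test_weight_scale_invariance(self):
        est = [0.1, 0.25, 0.2, 0.15]
        w = np.array([4, 8, 2, 6], dtype=float)
        overall = float((w * est).sum() / w.sum())
        sem1, _ = hp.jackknife_sem(est, w, overall)
        sem2, _ = hp.jackknife_sem(est, 2 * w, overall)
        assert sem1 == pytest.approx(sem2, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two blocks"):
            hp.jackknife_sem([0.1], [5], 0.1)
        with pytest.raises(ValueError, match="positive"):
            hp.jackknife_sem([0.1, 0.2], [5, 0], 0.15)


class TestEnumeration:
    def _table(self, n_groups, n_snps=60, seed=86, nan_group=None):
        rng = np.random.default_rng(seed)
        rows = {}
        for g in range(n_groups):
            name = f"g{g}"
            rows[name] = (np.full(n_snps, np.nan) if name == nan_group
                          else rng.uniform(0.1, 0.9, n_snps))
        ft = freq_table(**rows)
        part = hp.block_partition(
            snp_table([("chr1", i + 1) for i in range(n_snps)]), n_snps // 6)
        return ft, part

    def test_f3_combinatorics(self):
        ft, part = self._table(4)
        table = hp.enumerate_f3(ft, part)
        assert len(table) == 12  # 4 targets x C(3, 2)

    def test_f3_all_missing_group_flagged(self):
        ft, part = self._table(4, nan_group="g3")
        table = hp.enumerate_f3(ft, part)
        involved = table[(table[["target", "a", "b"]] == "g3").any(axis=1)]
        assert (~involved["available"]).all()
        assert table[~table.index.isin(involved.index)]["available"].all()

    def test_f3_rows_match_direct_calls(self):
        ft, part = self._table(4)
        table = hp.enumerate_f3(ft, part)
        for row in table.itertuples(index=False):
            direct = hp.f3_statistic(ft, row.target, row.a, row.b, part)
            assert row.f3 == pytest.approx(direct.estimate, abs=1e-12)
            assert row.sem == pytest.approx(direct.sem, abs=1e-12)

    def test_f4_canonical_quartet_count(self):
        ft, part = self._table(5)
        table = hp.enumerate_f4(ft, part)
        assert len(table) == 15  # 3 x C(5, 4)
        # canonical ordering: pop1 < pop2, pop3 < pop4, (pop1,pop2) < (pop3,pop4)
        for row in table.itertuples(index=False):
            assert row.pop1 < row.pop2 and row.pop3 < row.pop4
            assert (row.pop1, row.pop2) < (row.pop3, row.pop4)

    def test_f4_three_pairings_satisfy_zero_sum(self):
        # per 4-set: f4(w,x;y,z) - f4(w,y;x,z) + f4(w,z;x,y) = 0
        ft, part = self._table(5)
        table = hp.enumerate_f4(ft, part).set_index(["pop1", "pop2", "pop3", "pop4"])
        from itertools import combinations
        for w, x, y, z in combinations(sorted(ft.groups), 4):
            a = table.loc[(w, x, y, z), "f4"]
            b = table.loc[(w, y, x, z), "f4"]
            c = table.loc[(w, z, x, y), "f4"]
            assert a - b + c == pytest.approx(0.0, abs=1e-12)

    def test_z_times_sem_reconstructs_estimate(self):
        ft, part = self._table(4)
        table = hp.enumerate_f3(ft, part)
        ok = table["sem"] > 0
        np.testing.assert_allclose(table[ok]["z"] * table[ok]["sem"],
                                   table[ok]["f3"], atol=1e-10)
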