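import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from bacmap.assembly import (AssemblyParams, build_contigs, dq_resplit,
                             end_merge, map_length_mb, map_stats, match_bands,
                             n50, sulston_score)
from bacmap.bands import BandFingerprint

AFLP = AssemblyParams.aflp()


def oracle_sulston(m, n_low, n_high, tol, gel_length):
    """Independent brute-force binomial sum for the overlap tail."""
    p = (2 * tol + 1) / gel_length
    q = 1 - (1 - p) ** n_high
    return sum(
        math.comb(n_low, j) * q**j * (1 - q) ** (n_low - j)
        for j in range(m, n_low + 1)
    )


def spread_fp(clone_id, values):
    return BandFingerprint(clone_id, sorted(values))


class TestSulstonScore:
    def test_no_matches_scores_one(self):
        f1 = spread_fp("a", range(1000, 1300, 20))
        f2 = spread_fp("b", range(5000, 5300, 20))
        assert sulston_score(f1, f2, AFLP).score == 1.0

    def test_empty_fingerprint_scores_one(self):
        f1 = BandFingerprint("a", [])
        f2 = spread_fp("b", range(1000, 1300, 20))
        assert sulston_score(f1, f2, AFLP).score == 1.0

    def test_identical_30_band_exact_mode(self):
        params = AssemblyParams(tolerance=0, gel_length=5501, build_cutoff=1e-9)
        f1 = spread_fp("a", range(1000, 1600, 20))
        f2 = spread_fp("b", range(1000, 1600, 20))
        r = sulston_score(f1, f2, params)
        assert r.m == 30
        assert r.score < 1e-50

    def test_symmetry(self, rng):
        for _ in range(20):
            b1 = sorted(int(x) for x in rng.choice(5500, 25, replace=False) + 1000)
            b2 = sorted(int(x) for x in rng.choice(5500, 35, replace=False) + 1000)
            r1 = sulston_score(BandFingerprint("a", b1), BandFingerprint("b", b2), AFLP)
            r2 = sulston_score(BandFingerprint("b", b2), BandFingerprint("a", b1), AFLP)
            assert r1.score == r2.score and r1.m == r2.m

    def test_matches_binomial_oracle(self, rng):
        # scipy tail vs independent brute-force sum, 1e-12 relative
        for _ in range(50):
            n_low = int(rng.integers(1, 50))
            n_high = int(rng.integers(n_low, 60))
            m = int(rng.integers(0, n_low + 1))
            q = 1 - (1 - (2 * 5 + 1) / 5501) ** n_high
            scipy_tail = float(binom.sf(m - 1, n_low, q)) if m > 0 else 1.0
            expected = oracle_sulston(m, n_low, n_high, 5, 5501)
            assert scipy_tail == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_exact_mode_counts_shared_values(self):
        params = AssemblyParams.wgp()
        f1 = BandFingerprint("a", [1000, 1005, 2000, 3000])
        f2 = BandFingerprint("b", [1000, 1006, 3000, 4000])
        assert sulston_score(f1, f2, params).m == 2

    def test_monte_carlo_tail(self, rng):
        """Empirical chance-match tail vs the binomial score.

        The one-to-one matching constraint makes the score a slightly
        conservative (upper-bound) approximation; agreement is checked to a
        small absolute tolerance plus sampling error.
        """
        n, reps = 30, 20000
        counts = np.zeros(n + 1, dtype=int)
        pool = np.arange(1000, 6501)
        for _ in range(reps):
            b1 = sorted(int(x) for x in rng.choice(pool, n, replace=False))
            b2 = sorted(int(x) for x in rng.choice(pool, n, replace=False))
            counts[len(match_bands(b1, b2, 5))] += 1
        q = 1 - (1 - 11 / 5501) ** n
        for m in (3, 4, 5):
            emp = counts[m:].sum() / reps
            s = float(binom.sf(m - 1, n, q))
            se = math.sqrt(s * (1 - s) / reps)
            assert emp <= s + 4 * se  # conservative bound
            assert abs(emp - s) <= 0.02

    @given(
        st.lists(st.integers(1000, 6500), min_size=1, max_size=40),
        st.lists(st.integers(1000, 6500), min_size=1, max_size=40),
    )
    @settings(max_examples=50, deadline=None)
    def test_match_one_to_one(self, b1, b2):
        b1, b2 = sorted(b1), sorted(b2)
        pairs = match_bands(b1, b2, 5)
        assert len({i for i, _ in pairs}) == len(pairs)
        assert len({j for _, j in pairs}) == len(pairs)
        assert all(abs(b1[i] - b2[j]) <= 5 for i, j in pairs)


REGION = [1000 + 13 * i for i in range(90)]


class TestBuildContigs:
    def test_all_unrelated_are_singletons(self):
        fps = [
            spread_fp("a", range(1000, 1300, 20)),
            spread_fp("b", range(3000, 3300, 20)),
            spread_fp("c", range(5000, 5300, 20)),
        ]
        pmap = build_contigs(fps, AFLP)
        assert pmap.contigs == [] and sorted(pmap.singletons) == ["a", "b", "c"]

    def test_three_clone_tiling_order(self):
        reg = [1000 + 13 * i for i in range(60)]
        fps = [
            spread_fp("ca", reg[0:30]),
            spread_fp("cb", reg[15:45]),
            spread_fp("cc", reg[30:60]),
        ]
        pmap = build_contigs(fps, AFLP)
        assert len(pmap.contigs) == 1
        order = [c for c, _ in pmap.contigs[0].members]
        assert order in (["ca", "cb", "cc"], ["cc", "cb", "ca"])

    def test_partition_property(self, tiny_map, tiny_dataset):
        clones = sorted(tiny_map.all_clones())
        seen = {}
        for ctg in tiny_map.contigs:
            for cid in ctg.clone_ids:
                assert cid not in seen
                seen[cid] = ctg.contig_id
        for cid in tiny_map.singletons:
            assert cid not in seen
        assert len(clones) == len(set(clones))

    def test_cb_length_at_least_max_member_bands(self, tiny_map):
        for ctg in tiny_map.contigs:
            max_bands = max(
                tiny_map.fingerprints[c].n_bands for c in ctg.clone_ids
            )
            assert ctg.cb_length >= max_bands

    def test_duplicate_clone_ids_rejected(self):
        fps = [spread_fp("a", range(1000, 1300, 20))] * 2
        with pytest.raises(ValueError):
            build_contigs(fps, AFLP)


class TestQuestionable:
    def test_clean_tiling_has_no_q(self):
        reg = [1000 + 13 * i for i in range(60)]
        fps = [spread_fp(f"c{i}", reg[i * 5 : i * 5 + 30]) for i in range(6)]
        pmap = build_contigs(fps, AFLP)
        assert all(not ctg.q_clones for ctg in pmap.contigs)

    def test_chimera_forced_link_flags_q(self):
        r1 = [1000 + 13 * i for i in range(45)]
        r2 = [3000 + 13 * i for i in range(45)]
        tile = [spread_fp(f"r1_{i}", r1[i * 5 : i * 5 + 30]) for i in range(3)]
        unrelated = spread_fp("xx", r2[0:30])
        chimera = spread_fp("dd", r1[15:31] + r2[0:14])
        pmap = build_contigs(tile + [unrelated, chimera], AFLP)
        (ctg,) = pmap.contigs
        assert "xx" in ctg.q_clones

    def test_q_count_nonincreasing_with_stricter_cutoff(self, tiny_dataset):
        from bacmap.bands import preprocess

        kept, _ = preprocess(list(tiny_dataset.fingerprints.values()))
        q_counts = []
        for cutoff in (1e-9, 1e-11, 1e-13):
            params = AssemblyParams.aflp(
                build_cutoff=cutoff,
                dq_cutoffs=(cutoff / 10,),
                merge_cutoffs=(cutoff,),
            )
            pmap = build_contigs(kept, params)
            q_counts.append(sum(len(c.q_clones) for c in pmap.contigs))
        assert q_counts == sorted(q_counts, reverse=True)


def _mixed_contig_fixture():
    ra = [1000 + 13 * i for i in range(40)]
    rb = [4000 + 13 * i for i in range(40)]
    fps = [spread_fp(f"a{i}", ra[i * 3 : i * 3 + 30]) for i in range(4)]
    fps += [spread_fp(f"b{i}", rb[i * 3 : i * 3 + 30]) for i in range(4)]
    fps += [
        spread_fp("br1", ra[26:40] + rb[0:14] + [2500, 2513]),
        spread_fp("br2", ra[25:39] + rb[1:15] + [2600, 2613]),
    ]
    for j in range(6):
        junk = [2700 + 200 * j + 13 * i for i in range(16)]
        fps.append(spread_fp(f"q{j}", ra[0:14] + junk))
    return fps


class TestDQResplit:
    def test_unchanged_without_q_heavy_contigs(self):
        reg = [1000 + 13 * i for i in range(60)]
        fps = [spread_fp(f"c{i}", reg[i * 5 : i * 5 + 30]) for i in range(6)]
        pmap = build_contigs(fps, AFLP)
        after = dq_resplit(pmap)
        assert [sorted(c.clone_ids) for c in after.contigs] == [
            sorted(c.clone_ids) for c in pmap.contigs
        ]

    def test_planted_mixed_contig_splits(self):
        pmap = build_contigs(_mixed_contig_fixture(), AFLP)
        assert len(pmap.contigs) == 1
        assert len(pmap.contigs[0].q_clones) > AFLP.dq_max_q
        after = dq_resplit(pmap)
        member_sets = [set(c.clone_ids) for c in after.contigs]
        assert {"a0", "a1", "a2", "a3"} in member_sets
        assert {"b0", "b1", "b2", "b3"} in member_sets

    def test_clone_count_conserved(self):
        pmap = build_contigs(_mixed_contig_fixture(), AFLP)
        after = dq_resplit(pmap)
        assert sorted(after.all_clones()) == sorted(pmap.all_clones())


class TestEndMerge:
    def test_unchanged_without_links(self):
        fps = [
            spread_fp("a1", REGION[0:30]),
            spread_fp("a2", REGION[0:30]),
            spread_fp("b1", [5000 + 13 * i for i in range(30)]),
            spread_fp("b2", [5000 + 13 * i for i in range(30)]),
        ]
        pmap = build_contigs(fps, AFLP)
        after = end_merge(pmap)
        assert len(after.contigs) == len(pmap.contigs) == 2

    def test_coverage_gap_merges_at_relaxed_cutoff(self):
        fps = [
            spread_fp("a1", REGION[0:30]),
            spread_fp("a2", REGION[0:30]),
            spread_fp("b1", REGION[17:47]),
            spread_fp("b2", REGION[17:47]),
        ]
        pmap = build_contigs(fps, AFLP)
        assert len(pmap.contigs) == 2  # 13 shared bands miss the build cutoff
        after = end_merge(pmap)
        assert len(after.contigs) == 1
        assert sorted(after.contigs[0].clone_ids) == ["a1", "a2", "b1", "b2"]

    def test_contig_count_never_increases(self, tiny_map):
        again = end_merge(tiny_map)
        assert len(again.contigs) <= len(tiny_map.contigs)


class TestMapStats:
    def test_published_band_totals(self):
        assert map_length_mb(391465, 3477) == 1361
        assert map_length_mb(401465, 3477) == 1396

    def test_n50_uniform(self):
        assert n50([10, 10, 10, 10]) == 10

    def test_n50_paper_definition(self):
        # descending cumulative sum reaching half the total
        assert n50([50, 30, 20, 10, 5]) == 30

    def test_empty_map_zeros(self):
        pmap = build_contigs([], AFLP)
        stats = map_stats(pmap)
        assert stats["n_contigs"] == 0 and stats["total_mb"] == 0

    def test_totals_consistent(self, tiny_map):
        stats = map_stats(tiny_map)
        assert stats["n_clones_in_contigs"] + stats["n_singletons"] == stats[
            "n_clones_total"
        ]
        assert stats["total_bands"] == sum(c.cb_length for c in tiny_map.contigs)
        assert sum(stats["size_classes"].values()) == stats["n_contigs"]
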