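"""Target-site scoring, scanning, degradome categories and empirical p-values."""

import numpy as np
import pytest

from whorlspec import (SimConfig, align_mirna_target, categorize_site,
                       scan_targets, simulate_degradome, site_pvalue,
                       tplot_table)
from whorlspec.degradome import (_alignment_scores, _encode, _scan_codes,
                                 _weights, categorize_hits, merge_library_hits,
                                 validate_mirna)

MIR = "UGAAGCUGCCAGCAUGAUCUA"  # 21 nt
COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def perfect_site(mirna: str) -> str:
    return "".join(COMP[c] for c in reversed(mirna))


class TestScoring:
    def test_perfect_complement_scores_zero(self):
        assert align_mirna_target(MIR, perfect_site(MIR)) == 0.0

    def test_mismatch_outside_seed_costs_one(self):
        site = list(perfect_site(MIR))
        k = 15 - 1                       # miRNA position 15 (0-based index)
        ti = len(MIR) - 1 - k            # paired transcript index in the site
        site[ti] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[ti]]
        assert align_mirna_target(MIR, "".join(site)) == 1.0

    def test_seed_wobble_costs_doubled_half(self):
        # miRNA position 5 is G; pairing it with U is a G:U wobble, doubled
        # in the position 2-13 region: 0.5 * 2 = 1.0
        assert MIR[4] == "G"
        site = list(perfect_site(MIR))
        site[len(MIR) - 1 - 4] = "U"
        assert align_mirna_target(MIR, "".join(site)) == 1.0

    def test_seed_mismatch_costs_two(self):
        site = list(perfect_site(MIR))
        k = 3 - 1
        ti = len(MIR) - 1 - k
        site[ti] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[ti]]
        assert align_mirna_target(MIR, "".join(site)) == 2.0

    def test_site_length_limits(self):
        with pytest.raises(ValueError):
            align_mirna_target(MIR, perfect_site(MIR)[:-3])

    def test_non_rna_characters_rejected(self):
        with pytest.raises(ValueError):
            align_mirna_target("UGAXGCUGCCAGCAUGAUCUA", perfect_site(MIR))

    def test_pairwise_and_vectorized_scores_agree(self):
        """The windowed scanner reproduces the pairwise scorer for every
        offset and gap configuration on a random transcript."""
        rng = np.random.default_rng(0)
        tx = "".join("ACGU"[i] for i in rng.integers(0, 4, size=120))
        m = _encode(MIR)
        codes = _encode(tx)
        cands = _scan_codes(m, codes, cutoff=np.inf)
        w = _weights(len(m))
        for score, s, length, gap, _ in cands:
            site = tx[s:s + length]
            variants = _alignment_scores(m, _encode(site), w)
            assert any(abs(score - v) < 1e-9 for v in variants)


class TestScan:
    def test_planted_site_slice_coordinates(self):
        rng = np.random.default_rng(1)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
        start0 = 83
        tx = bg[:start0] + perfect_site(MIR).replace("U", "T") + bg[start0 + 21:]
        hits = scan_targets({"m1": MIR}, {"t1": tx}, score_cutoff=0.0)
        assert len(hits) == 1
        h = hits[0]
        assert h.score == 0.0
        assert h.start == start0 + 1
        # slice position = site start + (site length - 10)
        assert h.slice_pos == h.start + 21 - 10

    def test_random_transcripts_give_no_perfect_hits(self):
        rng = np.random.default_rng(2)
        transcripts = {
            f"t{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, size=1000))
            for i in range(100)}
        hits = scan_targets({"m1": MIR}, transcripts, score_cutoff=0.0)
        assert hits == []

    def test_cutoff_monotonicity(self):
        cfg = SimConfig(seed=5)
        sim = simulate_degradome(cfg, n_mirnas=3, n_targets=2,
                                 n_transcripts=10, transcript_length=300)
        low = {(h.mirna_id, h.transcript_id, h.slice_pos)
               for h in scan_targets(sim.mirnas, sim.transcripts, 3.0)}
        high = {(h.mirna_id, h.transcript_id, h.slice_pos)
                for h in scan_targets(sim.mirnas, sim.transcripts, 5.0)}
        assert low <= high

    def test_five_prime_truncation_shifts_slice_position(self):
        rng = np.random.default_rng(3)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        start0 = 150
        tx = bg[:start0] + perfect_site(MIR).replace("U", "T") + bg[start0 + 21:]
        k = 37
        full = scan_targets({"m1": MIR}, {"t": tx}, 0.0)[0]
        trunc = scan_targets({"m1": MIR}, {"t": tx[k:]}, 0.0)[0]
        assert full.slice_pos - trunc.slice_pos == k

    def test_mirna_length_validation(self):
        with pytest.raises(ValueError):
            validate_mirna("ACGU" * 2)  # 8 nt, below the 18-30 range


class TestCategories:
    PROFILE = {"t1": {10: 50, 200: 3, 300: 2}}

    def test_unique_maximum_is_category_zero(self):
        assert categorize_site(self.PROFILE, "t1", 10) == 0

    def test_single_read_is_category_four(self):
        assert categorize_site({"t1": {10: 1}}, "t1", 10) == 4

    def test_tied_maximum_is_category_one(self):
        assert categorize_site({"t1": {10: 5, 20: 5, 30: 1}}, "t1", 10) == 1

    def test_above_median_is_category_two(self):
        prof = {"t1": {10: 9, 20: 100, 30: 2, 40: 2, 50: 2}}
        assert categorize_site(prof, "t1", 10) == 2

    def test_below_median_is_category_three(self):
        prof = {"t1": {10: 2, 20: 100, 30: 50, 40: 60, 50: 70}}
        assert categorize_site(prof, "t1", 10) == 3

    def test_no_read_no_category(self):
        assert categorize_site(self.PROFILE, "t1", 99) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_site(self.PROFILE, "t1", 0)

    def test_depends_only_on_count_multiset(self):
        rng = np.random.default_rng(4)
        counts = dict(zip(rng.choice(np.arange(1, 400), 30, replace=False),
                          rng.integers(2, 40, size=30)))
        site_pos = list(counts)[7]
        base = categorize_site({"t": counts}, "t", site_pos)
        # permute positions, keeping the site's own count
        positions = list(counts)
        values = [counts[p] for p in positions]
        perm_positions = list(rng.permutation(positions))
        site_count = counts[site_pos]
        permuted = dict(zip(perm_positions, values))
        permuted[site_pos] = site_count
        # only compare when the permutation preserved the multiset
        if sorted(permuted.values()) == sorted(values):
            assert categorize_site({"t": permuted}, "t", site_pos) == base


class TestPvalue:
    def _planted(self):
        cfg = SimConfig(seed=6)
        sim = simulate_degradome(cfg, n_mirnas=2, n_targets=1,
                                 n_transcripts=6, transcript_length=300)
        hits = scan_targets(sim.mirnas, sim.transcripts, 5.0)
        hits = categorize_hits(hits, sim.profiles["L1"])
        planted = {(m, t, p) for m, t, p in sim.truth.true_targets}
        hit = next(h for h in hits
                   if (h.mirna_id, h.transcript_id, h.slice_pos) in planted)
        return sim, hit

    def test_perfect_planted_site_minimum_p(self):
        sim, hit = self._planted()
        assert hit.category == 0 and hit.score == 0.0
        p = site_pvalue(hit, sim.mirnas[hit.mirna_id], sim.transcripts,
                        sim.profiles["L1"], n_shuffles=99, seed=0)
        # no shuffled miRNA finds a perfect category-0 site: p = (1+0)/(1+99)
        assert p == pytest.approx(0.01)

    def test_shuffle_floor_enforced(self):
        sim, hit = self._planted()
        with pytest.raises(ValueError):
            site_pvalue(hit, sim.mirnas[hit.mirna_id], sim.transcripts,
                        sim.profiles["L1"], n_shuffles=10)

    def test_uncategorized_hit_rejected(self):
        sim, hit = self._planted()
        from dataclasses import replace
        with pytest.raises(ValueError):
            site_pvalue(replace(hit, category=None), sim.mirnas[hit.mirna_id],
                        sim.transcripts, sim.profiles["L1"])


class TestTplot:
    def test_rows_flags_and_conservation(self):
        from whorlspec.degradome import SiteHit

        profile = {"t1": {5: 4, 9: 2, 30: 11}}
        hit = SiteHit(mirna_id="m1", transcript_id="t1", slice_pos=30,
                      score=0.0, start=19, end=39)
        tab = tplot_table("t1", profile, [hit])
        assert len(tab) == 3
        assert tab["count"].sum() == sum(profile["t1"].values())
        assert tab.set_index("position")["m1@30"].tolist() == [0, 0, 1]

    def test_no_hits_zero_flags(self):
        tab = tplot_table("t1", {"t1": {5: 4}}, [])
        assert list(tab.columns) == ["position", "count"]


class TestMergeLibraries:
    def test_identical_libraries_preserve_hits(self):
        cfg = SimConfig(seed=8)
        sim = simulate_degradome(cfg, n_mirnas=3, n_targets=2,
                                 n_transcripts=8, transcript_length=250,
                                 libraries=("a",))
        profiles = {"x": sim.profiles["a"], "y": sim.profiles["a"]}
        merged = merge_library_hits(sim.mirnas, sim.transcripts, profiles)
        key = lambda h: (h.mirna_id, h.transcript_id, h.slice_pos)
        assert {key(h) for h in merged.per_library["x"]} == \
               {key(h) for h in merged.merged}

    def test_summed_counts_upgrade_category(self):
        rng = np.random.default_rng(9)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        tx = bg[:40] + perfect_site(MIR).replace("U", "T") + bg[61:]
        hits = scan_targets({"m": MIR}, {"t": tx}, 0.0)
        pos = hits[0].slice_pos
        lib_a = {"t": {pos: 1}}
        lib_b = {"t": {pos: 1}}
        cat_single = categorize_hits(hits, lib_a)[0].category
        merged = merge_library_hits({"m": MIR}, {"t": tx},
                                    {"a": lib_a, "b": lib_b})
        assert cat_single == 4
        assert merged.merged[0].category == 0  # 1+1 reads, unique maximum

    def test_overlap_counts_inclusion_exclusion(self):
        cfg = SimConfig(seed=10)
        sim = simulate_degradome(cfg, n_mirnas=4, n_targets=3,
                                 n_transcripts=10, transcript_length=250,
                                 libraries=("shoot", "bud"))
        merged = merge_library_hits(sim.mirnas, sim.transcripts, sim.profiles)
        key = lambda h: (h.mirna_id, h.transcript_id, h.slice_pos)
        union = set()
        for hs in merged.per_library.values():
            union |= {key(h) for h in hs}
        union |= {key(h) for h in merged.merged}
        assert sum(merged.overlap.values()) == len(union)


class TestEndToEnd:
    def test_planted_sites_recovered_with_significance(self):
        cfg = SimConfig(seed=12)
        sim = simulate_degradome(cfg, n_mirnas=5, n_targets=3,
                                 n_transcripts=15, transcript_length=300)
        profile = sim.profiles["L1"]
        hits = scan_targets(sim.mirnas, sim.transcripts, 5.0)
        supported = [h for h in categorize_hits(hits, profile)
                     if h.category is not None]
        planted = set(map(tuple, sim.truth.true_targets))
        confident = set()
        for h in supported:
            p = site_pvalue(h, sim.mirnas[h.mirna_id], sim.transcripts,
                            profile, n_shuffles=49, seed=3)
            if p < 0.05:
                confident.add((h.mirna_id, h.transcript_id, h.slice_pos))
        assert planted <= confident
        assert len(confident - planted) <= 1
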