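import numpy as np
import pytest

from promotif.comparison import kl_distance
from promotif.discovery import (
    MotifCandidate,
    MotifGroup,
    Site,
    dedupe_across_widths,
    filter_valid,
    gibbs_discover,
    rank_and_group,
    replicate_runs,
)
from promotif.promoters import PromoterUniverse
from promotif.pwm import PWM
from promotif.simulate import (
    PlantedMotif,
    SyntheticSpec,
    block_pwm,
    generate_promoter_set,
    uniform_background,
)
from promotif.promoters import extract_promoters


def planted_universe(seed=7, n=20, length=200, word="TTGACCAT", major=0.97, prob=1.0):
    pm = PlantedMotif(block_pwm(word, major, "planted"), "WRKY", prob, prob)
    spec = SyntheticSpec(
        seed=seed,
        n_genes=n,
        promoter_length=length,
        background=uniform_background(),
        planted_motifs=[pm],
    )
    genome, genes, truth = generate_promoter_set(spec)
    return extract_promoters(genome, genes, l_prom=length), truth, pm


def fake_candidate(pwm, run_id, score, n_sites=5):
    sites = [Site(f"p{i}", 0, "+") for i in range(n_sites)]
    return MotifCandidate(pwm=pwm, run_id=run_id, score=score, sites=sites,
                          information_content=pwm.information_content())


class TestGibbsDiscover:
    def test_recovers_planted_sites(self, uniform_bg):
        uni, truth, pm = planted_universe()
        cands = gibbs_discover(
            uni, uniform_bg, widths=(8,), n_motifs_per_run=1, n_iterations=100, seed=3
        )
        top = max(cands, key=lambda c: c.score)
        planted = {r.transcript_id: truth.planted_sites[r.transcript_id][0][1] for r in uni.records}
        near = sum(1 for s in top.sites if abs(s.offset - planted[s.promoter_id]) <= 1)
        assert near >= 0.9 * len(planted)

    def test_signal_exceeds_pure_background_information(self, uniform_bg):
        uni_signal, _, _ = planted_universe(seed=7)
        uni_null, _, _ = planted_universe(seed=8, prob=0.0)
        c_signal = gibbs_discover(
            uni_signal, uniform_bg, widths=(8,), n_motifs_per_run=1, n_iterations=100, seed=3
        )
        c_null = gibbs_discover(
            uni_null, uniform_bg, widths=(8,), n_motifs_per_run=1, n_iterations=100, seed=3
        )
        top_ic = max(c.information_content for c in c_signal)
        null_ic = max(c.information_content for c in c_null)
        assert top_ic > null_ic

    def test_single_motif_per_run_cardinality(self, uniform_bg):
        uni, _, _ = planted_universe(n=10, length=120)
        cands = gibbs_discover(
            uni, uniform_bg, widths=(8,), n_motifs_per_run=1, n_iterations=30, seed=1
        )
        assert len(cands) == 1

    def test_site_count_respects_max_per_seq(self, uniform_bg):
        uni, _, _ = planted_universe(n=10, length=120)
        cands = gibbs_discover(
            uni, uniform_bg, widths=(8,), n_motifs_per_run=1, n_iterations=30,
            max_sites_per_seq=2, seed=1,
        )
        from collections import Counter

        for c in cands:
            per_seq = Counter(s.promoter_id for s in c.sites)
            assert max(per_seq.values()) <= 2

    def test_too_few_promoters_rejected(self, uniform_bg):
        uni, _, _ = planted_universe(n=20)
        small = PromoterUniverse(uni.records[:3], [])
        with pytest.raises(ValueError, match="at least 5"):
            gibbs_discover(small, uniform_bg, widths=(8,), seed=1)


class TestReplicateRuns:
    def test_same_master_seed_identical_output(self, uniform_bg):
        uni, _, _ = planted_universe(n=8, length=100)
        kw = dict(widths=(6,), n_motifs_per_run=1, n_iterations=20)
        a = replicate_runs(uni, uniform_bg, n_runs=2, seed=99, **kw)
        b = replicate_runs(uni, uniform_bg, n_runs=2, seed=99, **kw)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.run_id == y.run_id and x.score == y.score
            assert np.array_equal(x.pwm.matrix, y.pwm.matrix)
            assert [(s.promoter_id, s.offset, s.strand) for s in x.sites] == [
                (s.promoter_id, s.offset, s.strand) for s in y.sites
            ]

    def test_zero_runs_empty(self, uniform_bg):
        uni, _, _ = planted_universe(n=8, length=100)
        assert replicate_runs(uni, uniform_bg, n_runs=0, seed=1) == []

    def test_run_ids_tagged(self, uniform_bg):
        uni, _, _ = planted_universe(n=8, length=100)
        cands = replicate_runs(
            uni, uniform_bg, n_runs=3, seed=5, widths=(6,), n_motifs_per_run=1, n_iterations=10
        )
        assert {c.run_id for c in cands} == {0, 1, 2}


class TestRankAndGroup:
    def test_identical_pwms_from_two_runs_one_group(self, random_pwm_factory):
        p = random_pwm_factory(6)
        cands = [fake_candidate(p, 0, 10.0), fake_candidate(PWM(p.matrix.copy()), 1, 9.0)]
        groups = rank_and_group(cands, 0.3)
        assert len(groups) == 1 and groups[0].n_runs_found == 2

    def test_dissimilar_point_mass_pwms_two_groups(self):
        all_a = PWM(np.tile([0.97, 0.01, 0.01, 0.01], (6, 1)))
        all_c = PWM(np.tile([0.01, 0.97, 0.01, 0.01], (6, 1)))
        groups = rank_and_group(
            [fake_candidate(all_a, 0, 10.0), fake_candidate(all_c, 1, 9.0)], 0.3
        )
        assert len(groups) == 2

    def test_grouping_stable_when_distances_are_clear_cut(self, rng):
        # oracle: exhaustive pairwise distances are all << delta or >> delta,
        # so any order of equal-score candidates yields the same partition
        all_a = PWM(np.tile([0.97, 0.01, 0.01, 0.01], (6, 1)))
        all_c = PWM(np.tile([0.01, 0.97, 0.01, 0.01], (6, 1)))
        cands = [
            fake_candidate(PWM(all_a.matrix.copy()), i, 5.0) for i in range(3)
        ] + [fake_candidate(PWM(all_c.matrix.copy()), 3 + i, 5.0) for i in range(2)]
        sizes_ref = None
        for _ in range(4):
            perm = [cands[i] for i in rng.permutation(len(cands))]
            groups = rank_and_group(perm, 0.3)
            sizes = sorted(len(g.members) for g in groups)
            if sizes_ref is None:
                sizes_ref = sizes
            assert sizes == sizes_ref == [2, 3]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            rank_and_group([], 0.3)


class TestFilterValid:
    def _groups(self, run_counts):
        groups = []
        for i, rc in enumerate(run_counts):
            p = PWM(np.tile([0.97, 0.01, 0.01, 0.01], (6, 1)))
            members = [fake_candidate(p, run_id, 1.0) for run_id in range(rc)]
            groups.append(MotifGroup(f"g{i}", p, members))
        return groups

    def test_run_count_fixture_yields_two_valid(self):
        # run-count fixture {12, 10, 9, 1} with the >= 10-of-100 rule
        valid = filter_valid(self._groups([12, 10, 9, 1]), min_runs=10, total_runs=100)
        assert len(valid) == 2
        assert [g.n_runs_found for g in valid] == [12, 10]

    def test_min_runs_one_keeps_all(self):
        assert len(filter_valid(self._groups([5, 1]), min_runs=1, total_runs=100)) == 2

    def test_raising_min_runs_never_increases_valid_count(self, rng):
        counts = list(rng.integers(1, 30, size=8))
        prev = None
        for mr in range(1, 31):
            n = len(filter_valid(self._groups(counts), min_runs=mr, total_runs=100))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_min_runs_above_total_is_error(self):
        with pytest.raises(ValueError):
            filter_valid(self._groups([5]), min_runs=101, total_runs=100)


class TestDedupeAcrossWidths:
    def test_subwindow_motif_merged_keeping_higher_run_count(self):
        wide = PWM(np.vstack([np.tile([0.97, 0.01, 0.01, 0.01], (4, 1)),
                              np.tile([0.01, 0.97, 0.01, 0.01], (4, 1))]))
        narrow = PWM(wide.matrix[1:7].copy())
        g_wide = MotifGroup("gw", wide, [fake_candidate(wide, r, 1.0) for r in range(12)])
        g_narrow = MotifGroup("gn", narrow, [fake_candidate(narrow, r, 1.0) for r in range(5)])
        out = dedupe_across_widths({8: [g_wide], 6: [g_narrow]}, 0.3)
        assert len(out) == 1
        assert out[0].representative.width == 8

    def test_disjoint_motifs_unchanged(self):
        all_a = PWM(np.tile([0.97, 0.01, 0.01, 0.01], (6, 1)))
        all_c = PWM(np.tile([0.01, 0.97, 0.01, 0.01], (8, 1)))
        ga = MotifGroup("ga", all_a, [fake_candidate(all_a, 0, 1.0)])
        gc = MotifGroup("gc", all_c, [fake_candidate(all_c, 0, 1.0)])
        out = dedupe_across_widths([ga, gc], 0.3)
        assert {g.group_id for g in out} == {"ga", "gc"}

    def test_idempotent(self, random_pwm_factory):
        groups = []
        for i in range(6):
            p = random_pwm_factory(6 + 2 * (i % 2))
            groups.append(MotifGroup(f"g{i}", p, [fake_candidate(p, j, 1.0) for j in range(i + 1)]))
        once = dedupe_across_widths(list(groups), 0.4)
        twice = dedupe_across_widths(list(once), 0.4)
        assert [g.group_id for g in once] == [g.group_id for g in twice]
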