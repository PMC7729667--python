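import itertools

import numpy as np
import pytest

from promotif.background import BackgroundModel, build_background
from promotif.io_formats import SequenceSet
from promotif.pwm import PWM, BASE_INDEX, reverse_complement
from promotif.scanning import (
    MotifHit,
    build_consensus,
    mapping_rate,
    mark_genes,
    pvalue_lattice,
    scan_normalized,
    scan_pvalue,
)
from conftest import make_universe


def point_mass_pwm(word: str) -> PWM:
    mat = np.full((len(word), 4), 1e-9)
    for i, b in enumerate(word):
        mat[i, BASE_INDEX[b]] = 1 - 3e-9
    return PWM(mat / mat.sum(axis=1, keepdims=True), motif_id=f"pm_{word}")


def brute_force_normalized(seq: str, pwm: PWM, model: BackgroundModel, t: float):
    """Naive per-window rescan on both strands; independent of the scanner."""
    hits = []
    w = pwm.width
    logpwm = np.log(np.maximum(pwm.matrix, 1e-6))
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        L = len(s)
        for j in range(L - w + 1):
            window = s[j : j + w]
            if "N" in window:
                continue
            raw = lo = hi = 0.0
            for i, base in enumerate(window):
                ctx = s[max(0, j + i - model.order) : j + i]
                if "N" in ctx:
                    ctx = ctx[ctx.rindex("N") + 1 :]
                cond = np.log(model.conditional(ctx))
                odds = logpwm[i] - cond
                raw += odds[BASE_INDEX[base]]
                lo += odds.min()
                hi += odds.max()
            norm = (raw - lo) / (hi - lo) if hi > lo else 1.0
            if norm >= t:
                start = j if strand == "+" else L - w - j
                hits.append((start, strand, round(norm, 9)))
    return sorted(hits)


class TestScanNormalized:
    def test_point_mass_pwm_single_exact_hit(self, uniform_bg):
        word = "ACGTAC"
        seq = "TTTTTTTTTT" + word + "TTTTTTTTTT"
        uni = make_universe({"p1": seq})
        hits = scan_normalized(uni, point_mass_pwm(word), uniform_bg, t=0.99)
        forward = [h for h in hits if h.strand == "+"]
        assert len(forward) == 1
        (h,) = forward
        assert h.interval == (10, 16)
        assert h.normalized_score == pytest.approx(1.0, abs=1e-6)

    def test_threshold_one_without_consensus_word_no_hits(self, uniform_bg, rng):
        pwm = point_mass_pwm("ACGTACGT")
        seq = "".join(rng.choice(list("AT"), size=100))
        uni = make_universe({"p1": seq})
        assert scan_normalized(uni, pwm, uniform_bg, t=1.0) == []

    def test_invalid_threshold_rejected(self, uniform_bg, random_pwm_factory):
        with pytest.raises(ValueError):
            scan_normalized(make_universe({"p": "ACGTACGT"}), random_pwm_factory(4), uniform_bg, t=1.5)

    @pytest.mark.parametrize("order", [0, 2])
    def test_matches_brute_force_oracle(self, rng, order, random_pwm_factory):
        ref = "".join(rng.choice(list("ACGT"), size=5000))
        model = build_background(SequenceSet({"r": ref}), order=order)
        for trial in range(5):
            seq = "".join(rng.choice(list("ACGTN"), size=300, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            pwm = random_pwm_factory(7)
            pwm.motif_id = "m"
            hits = scan_normalized(make_universe({"p": seq}), pwm, model, t=0.7)
            got = sorted((h.interval[0], h.strand, round(h.normalized_score, 9)) for h in hits)
            expected = brute_force_normalized(seq, pwm, model, 0.7)
            assert got == expected

    def test_hit_count_monotone_in_threshold(self, rng, uniform_bg, random_pwm_factory):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        pwm = random_pwm_factory(6)
        uni = make_universe({"p": seq})
        counts = [
            len(scan_normalized(uni, pwm, uniform_bg, t=t))
            for t in (0.5, 0.7, 0.9, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_reverse_complement_mirrors_hits(self, rng, uniform_bg, random_pwm_factory):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pwm = random_pwm_factory(6)
        L = len(seq)
        fwd = scan_normalized(make_universe({"p": seq}), pwm, uniform_bg, t=0.8)
        rev = scan_normalized(
            make_universe({"p": reverse_complement(seq)}), pwm, uniform_bg, t=0.8
        )
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (L - h.interval[1], L - h.interval[0], flip[h.strand]) for h in rev
        )
        original = sorted((h.interval[0], h.interval[1], h.strand) for h in fwd)
        assert original == mirrored


def brute_force_pvalues(seq: str, pwm: PWM, stationary: np.ndarray):
    """Exhaustive-null oracle: enumerate all 4^w words on the integer lattice."""
    w = pwm.width
    q, _ = pvalue_lattice(pwm, stationary)
    word_scores = {}
    for word in itertools.product(range(4), repeat=w):
        s = sum(q[i, b] for i, b in enumerate(word))
        p = float(np.prod(stationary[list(word)]))
        word_scores[word] = (s, p)
    def pval(window_codes):
        obs = sum(q[i, b] for i, b in enumerate(window_codes))
        return sum(p for s, p in word_scores.values() if s >= obs)
    out = {}
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        L = len(s)
        for j in range(L - w + 1):
            window = s[j : j + w]
            if "N" in window:
                continue
            codes = [BASE_INDEX[b] for b in window]
            start = j if strand == "+" else L - w - j
            out[(start, strand)] = pval(codes)
    return out


class TestScanPvalue:
    def test_matches_exhaustive_null_enumeration(self, rng, random_pwm_factory, at_rich_bg):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        pwm = random_pwm_factory(4, concentration=0.5)
        pwm.motif_id = "m"
        hits = scan_pvalue(make_universe({"p": seq}), pwm, at_rich_bg, p_threshold=1.0)
        oracle = brute_force_pvalues(seq, pwm, at_rich_bg.stationary)
        assert len(hits) == len(oracle)
        for h in hits:
            assert h.p_value == pytest.approx(oracle[(h.interval[0], h.strand)], rel=1e-9)

    def test_best_window_has_minimum_pvalue(self, rng, uniform_bg, random_pwm_factory):
        pwm = random_pwm_factory(6, concentration=0.3)
        best_word = pwm.consensus()
        seq = "".join(rng.choice(list("ACGT"), size=150)) + best_word
        hits = scan_pvalue(make_universe({"p": seq}), pwm, uniform_bg, p_threshold=1.0)
        best_hits = [h for h in hits if h.interval == (150, 156) and h.strand == "+"]
        assert best_hits
        assert min(h.p_value for h in hits) == pytest.approx(best_hits[0].p_value)

    def test_hits_monotone_in_threshold(self, rng, uniform_bg, random_pwm_factory):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pwm = random_pwm_factory(5)
        uni = make_universe({"p": seq})
        small = {
            (h.interval, h.strand)
            for h in scan_pvalue(uni, pwm, uniform_bg, p_threshold=1e-3)
        }
        large = {
            (h.interval, h.strand)
            for h in scan_pvalue(uni, pwm, uniform_bg, p_threshold=2e-3)
        }
        assert small <= large

    def test_nonpositive_threshold_rejected(self, uniform_bg, random_pwm_factory):
        with pytest.raises(ValueError):
            scan_pvalue(make_universe({"p": "ACGTACGT"}), random_pwm_factory(4), uniform_bg, p_threshold=0)


class TestMappingRate:
    def _universes(self):
        target = make_universe({f"t{i}": "ACGT" * 10 for i in range(10)})
        rand = make_universe({f"r{i}": "ACGT" * 10 for i in range(10)})
        return target, rand

    def _hits(self, ids, motif="m"):
        return [
            MotifHit(i, motif, "F", (0, 4), "+", 1.0, normalized_score=0.95)
            for i in ids
        ]

    def test_fold_rule_enriched(self):
        target, rand = self._universes()
        res = mapping_rate(
            self._hits([f"t{i}" for i in range(9)]),
            target,
            rand,
            self._hits([f"r{i}" for i in range(5)]),
            fold=1.5,
        )
        assert res.rate_target == 0.9 and res.rate_random == 0.5
        assert res.enriched  # 0.9 > 1.5 * 0.5

    def test_equal_rates_not_enriched(self):
        target, rand = self._universes()
        res = mapping_rate(
            self._hits([f"t{i}" for i in range(5)]),
            target,
            rand,
            self._hits([f"r{i}" for i in range(5)]),
        )
        assert res.rate_target == res.rate_random == 0.5
        assert not res.enriched

    def test_planted_motif_enriched_under_any_fold(self, rng):
        # generator ground truth: motif in 60% of target, 0% of random
        target, rand = self._universes()
        hits = self._hits([f"t{i}" for i in range(6)])
        for fold in (1.0, 1.5, 3.0):
            res = mapping_rate(hits, target, rand, [], fold=fold)
            assert res.enriched

    def test_empty_universe_is_error(self):
        target, _ = self._universes()
        from promotif.promoters import PromoterUniverse

        with pytest.raises(ValueError):
            mapping_rate([], target, PromoterUniverse([], []), [])


def _hit(prom, fam, start, end, motif=None):
    return MotifHit(prom, motif or f"m_{fam}", fam, (start, end), "+", 1.0, normalized_score=0.9)


class TestBuildConsensus:
    def test_two_families_identical_interval(self):
        hits = [_hit("p1", "WRKY", 10, 18), _hit("p1", "bHLH", 10, 18)]
        (site,) = build_consensus(hits)
        assert site.families == {"WRKY", "bHLH"}
        assert site.interval == (10, 18)

    def test_single_family_never_consensus(self):
        hits = [_hit("p1", "WRKY", 10, 18), _hit("p1", "WRKY", 10, 18, motif="m2")]
        assert build_consensus(hits) == []

    def test_overlap_mode_matches_connected_components(self):
        hits = [
            _hit("p1", "WRKY", 0, 8),
            _hit("p1", "bHLH", 4, 12),
            _hit("p1", "AP2", 8, 16),
        ]
        (site,) = build_consensus(hits, colocate="overlap")
        # oracle: transitive closure of pairwise overlap is one component
        assert site.families == {"WRKY", "bHLH", "AP2"}
        assert site.interval == (0, 16)

    def test_deterministic_under_permutation(self, rng):
        hits = [
            _hit("p1", f, s, s + 8)
            for f, s in [("A", 0), ("B", 4), ("C", 30), ("D", 30), ("A", 100)]
        ]
        base = build_consensus(hits, colocate="overlap")
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            got = build_consensus(perm, colocate="overlap")
            assert [(c.promoter_id, c.interval, c.families) for c in got] == [
                (c.promoter_id, c.interval, c.families) for c in base
            ]


class TestMarkGenes:
    P2G = {"p1": "g1", "p2": "g2", "p3": "g3"}

    def test_two_hits_marked(self):
        hits = [_hit("p1", "WRKY", 0, 8), _hit("p1", "bHLH", 50, 58)]
        statuses = {s.gene_id: s for s in mark_genes(hits, [], self.P2G)}
        assert statuses["g1"].marked and statuses["g1"].total_hits == 2

    def test_single_hit_in_consensus_marked(self):
        hits = [_hit("p2", "WRKY", 10, 18), _hit("p2", "bHLH", 10, 18)]
        consensus = build_consensus(hits)
        statuses = {s.gene_id: s for s in mark_genes(hits[:1], consensus, self.P2G)}
        assert statuses["g2"].has_consensus and statuses["g2"].marked

    def test_single_plain_hit_not_marked(self):
        statuses = {
            s.gene_id: s for s in mark_genes([_hit("p3", "WRKY", 0, 8)], [], self.P2G)
        }
        assert not statuses["g3"].marked and statuses["g3"].total_hits == 1

    def test_unknown_promoter_is_error(self):
        with pytest.raises(KeyError):
            mark_genes([_hit("pX", "WRKY", 0, 8)], [], self.P2G)
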