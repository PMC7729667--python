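import numpy as np
import pandas as pd
import pytest

from promotif.orthology import chain_orthologs, top_hits
from promotif.promoters import extract_promoters
from promotif.simulate import (
    PlantedMotif,
    SyntheticSpec,
    at_rich_background,
    block_pwm,
    conditional_plant_probs,
    generate_ortholog_fixture,
    generate_promoter_set,
    simulate_association,
    uniform_background,
    write_ground_truth,
)


def spec_with_motif(seed=11, n=40, length=300, p_deg=0.8, p_nondeg=0.2):
    pm = PlantedMotif(block_pwm("TTGACC", 0.95), "WRKY", p_deg, p_nondeg)
    return SyntheticSpec(
        seed=seed, n_genes=n, promoter_length=length, planted_motifs=[pm]
    )


class TestGeneratePromoterSet:
    def test_same_seed_byte_identical(self):
        g1, t1, tr1 = generate_promoter_set(spec_with_motif())
        g2, t2, tr2 = generate_promoter_set(spec_with_motif())
        assert g1.records == g2.records
        pd.testing.assert_frame_equal(t1.df, t2.df)
        assert tr1.planted_sites == tr2.planted_sites
        assert tr1.deg_labels == tr2.deg_labels

    def test_different_seed_differs(self):
        g1, _, _ = generate_promoter_set(spec_with_motif(seed=1))
        g2, _, _ = generate_promoter_set(spec_with_motif(seed=2))
        assert g1.records != g2.records

    def test_extract_promoters_round_trip(self):
        # the core layout invariant: extraction recovers planted promoters,
        # so planted-site offsets are meaningful on extracted sequences
        spec = spec_with_motif(n=30)
        genome, genes, truth = generate_promoter_set(spec)
        uni = extract_promoters(genome, genes, l_prom=spec.promoter_length)
        assert len(uni.records) == spec.n_genes
        pm = spec.planted_motifs[0]
        w = pm.pwm.width
        consensus = pm.pwm.consensus()
        for rec in uni.records:
            for fam, off, strand in truth.planted_sites[rec.transcript_id]:
                site = rec.sequence[off : off + w]
                # site was sampled from a 0.95-concentrated PWM: allow 1 mismatch
                mism = sum(1 for a, b in zip(site, consensus) if a != b)
                assert mism <= 2, (rec.transcript_id, site, consensus)

    def test_round_trip_exact_on_both_strands(self):
        # regenerate with probability-1 planting; check strand mix is present
        spec = spec_with_motif(n=50, p_deg=1.0, p_nondeg=1.0)
        genome, genes, _ = generate_promoter_set(spec)
        strands = set(genes.df["strand"])
        assert strands == {"+", "-"}
        uni = extract_promoters(genome, genes, l_prom=spec.promoter_length)
        assert not uni.excluded
        assert all(len(r.sequence) == spec.promoter_length for r in uni.records)

    def test_planting_frequencies_match_probabilities(self):
        spec = spec_with_motif(seed=5, n=2000, length=120, p_deg=0.8, p_nondeg=0.2)
        _, _, truth = generate_promoter_set(spec)
        deg = [t for t, d in truth.deg_labels.items() if d]
        non = [t for t, d in truth.deg_labels.items() if not d]
        f_deg = np.mean([bool(truth.family_indicator[t]) for t in deg])
        f_non = np.mean([bool(truth.family_indicator[t]) for t in non])
        # 3 binomial SEs
        se_deg = 3 * np.sqrt(0.8 * 0.2 / len(deg))
        se_non = 3 * np.sqrt(0.2 * 0.8 / len(non))
        assert abs(f_deg - 0.8) < se_deg
        assert abs(f_non - 0.2) < se_non

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            PlantedMotif(block_pwm("ACGT"), "X", 1.2, 0.1)

    def test_planted_sites_non_overlapping(self):
        pms = [
            PlantedMotif(block_pwm("TTGACC"), "WRKY", 1.0, 1.0),
            PlantedMotif(block_pwm("CACGTGTC"), "bHLH", 1.0, 1.0),
            PlantedMotif(block_pwm("GCCGCCTCTA"), "AP2-ERF", 1.0, 1.0),
        ]
        spec = SyntheticSpec(seed=3, n_genes=30, promoter_length=200, planted_motifs=pms)
        _, _, truth = generate_promoter_set(spec)
        widths = {"WRKY": 6, "bHLH": 8, "AP2-ERF": 10}
        for sites in truth.planted_sites.values():
            ivals = sorted((o, o + widths[f]) for f, o, _ in sites)
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert e1 <= s2

    def test_deg_fraction_respected(self):
        spec = spec_with_motif(n=200)
        _, _, truth = generate_promoter_set(spec)
        assert sum(truth.deg_labels.values()) == round(0.2 * 200)


class TestOrthologFixture:
    def test_pipeline_recovers_exact_truth(self):
        tids = [f"sc_{i:05d}" for i in range(20)]
        sc_sb, sc_at, rel, targets, fams, triples = generate_ortholog_fixture(
            tids, seed=7, sc_per_sb=2, n_decoys=5
        )
        filtered = top_hits(sc_sb, n_top=10, e_max=1e-3)
        omap = chain_orthologs(filtered, None, rel)
        got = set(
            zip(
                omap.df["sugarcane_transcript_id"],
                omap.df["sorghum_gene_id"],
                omap.df["arabidopsis_gene_id"],
            )
        )
        assert got == set(triples)  # decoys excluded by the quality filters

    def test_decoys_do_not_change_map(self):
        tids = [f"sc_{i:05d}" for i in range(20)]
        out_clean = generate_ortholog_fixture(tids, seed=7, n_decoys=0)
        out_decoy = generate_ortholog_fixture(tids, seed=7, n_decoys=8)
        m1 = chain_orthologs(top_hits(out_clean[0], 10), None, out_clean[2])
        m2 = chain_orthologs(top_hits(out_decoy[0], 10), None, out_decoy[2])
        pd.testing.assert_frame_equal(m1.df, m2.df)

    def test_dropout_reduces_rows(self):
        tids = [f"sc_{i:05d}" for i in range(200)]
        full = generate_ortholog_fixture(tids, seed=1, dropout=0.0)
        half = generate_ortholog_fixture(tids, seed=1, dropout=0.5)
        assert len(full[0]) == 200
        assert 60 < len(half[0]) < 140
        assert len(half[5]) == len(half[0])  # triples track surviving rows

    def test_family_targets_propagate_to_tables(self):
        tids = [f"sc_{i:05d}" for i in range(10)]
        fam_targets = {"WRKY": {"sc_00000", "sc_00002"}, "MYB": {"sc_00004"}}
        *_, targets, fams, triples = generate_ortholog_fixture(
            tids, seed=2, families_targets=fam_targets
        )
        assert set(fams["tf_family"]) == {"WRKY", "MYB"}
        sc_to_at = {sc: at for sc, _, at in triples}
        wrky_at = set(targets[targets["tf_id"] == "at_tf_WRKY"]["target_gene_id"])
        assert wrky_at == {sc_to_at["sc_00000"], sc_to_at["sc_00002"]}


class TestConditionalPlantProbs:
    def test_odds_ratio_one_gives_equal_probs(self):
        p1, p0 = conditional_plant_probs(1000, 200, 300, 1.0)
        assert p1 == pytest.approx(p0, rel=1e-9)
        assert p1 == pytest.approx(0.3, rel=1e-6)

    def test_solution_satisfies_both_constraints(self):
        N, K, n_target, OR = 800, 150, 240, 3.0
        p1, p0 = conditional_plant_probs(N, K, n_target, OR)
        realized_or = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert realized_or == pytest.approx(OR, rel=1e-9)
        assert K * p1 + (N - K) * p0 == pytest.approx(n_target, rel=1e-9)

    def test_invalid_odds_ratio(self):
        with pytest.raises(ValueError):
            conditional_plant_probs(100, 20, 30, 0.0)

    def test_simulate_association_shapes(self, rng):
        universe, deg, tfbs = simulate_association(500, 100, 150, 2.5, rng)
        assert len(universe) == 500 and len(deg) == 100
        assert deg <= universe and tfbs <= universe
        assert 80 < len(tfbs) < 230


class TestWriteGroundTruth:
    def test_file_round_trips_labels(self, tmp_path):
        spec = spec_with_motif(n=15, length=100)
        _, _, truth = generate_promoter_set(spec)
        out = tmp_path / "truth.tsv"
        write_ground_truth(truth, out)
        df = pd.read_csv(out, sep="\t")
        assert len(df) == 15
        assert set(df.columns) == {"transcript_id", "deg", "families", "sites"}
        for _, row in df.iterrows():
            assert bool(row["deg"]) == truth.deg_labels[row["transcript_id"]]
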