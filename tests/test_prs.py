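"""Summary-stat QC, LD clumping, APOE/pathway restriction and scoring."""

import numpy as np
import pandas as pd
import pytest

from connectoprs import (GenotypePanel, PRSConfig, build_score_panel,
                         compute_score, enumerate_configs, exclude_apoe,
                         ld_clump, qc_filter, restrict_to_pathway)
from connectoprs.prs import P_THRESHOLDS, PATHWAYS, PRSError, align_alleles
from connectoprs.synthetic import GenotypePanelConfig, generate_genotype_panel

import oracles


def _records(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2",
                                       "BETA", "P", "MAF", "INFO"])


def _panel(dosages: dict, info_rows=None, individuals=None):
    snps = list(dosages)
    individuals = individuals or [f"i{k}" for k in range(len(next(iter(dosages.values()))))]
    if info_rows is None:
        info_rows = [(s, 1, 1000 * (i + 1), "A", "G") for i, s in enumerate(snps)]
    info = pd.DataFrame(info_rows, columns=["SNP", "CHR", "BP", "A1", "A2"]).set_index("SNP")
    return GenotypePanel(pd.DataFrame(dosages, index=individuals), info)


class TestQCFilter:
    def test_low_maf_removed_good_retained(self):
        recs = _records([("a", 1, 1, "A", "G", 0.1, 0.5, 0.05, 0.95),
                         ("b", 1, 2, "A", "G", 0.1, 0.5, 0.30, 0.95)])
        out = qc_filter(recs)
        assert list(out["SNP"]) == ["b"]

    def test_counting_on_toy_table(self):
        rows = []
        for i in range(10):
            maf = 0.05 if i < 2 else 0.2
            info = 0.8 if i == 5 else 0.95
            rows.append((f"s{i}", 1, i, "A", "G", 0.0, 0.5, maf, info))
        assert len(qc_filter(_records(rows))) == 7

    def test_missing_fields_rejected(self, caplog):
        recs = _records([("a", 1, 1, "A", "G", 0.1, 0.5, np.nan, 0.95)])
        assert qc_filter(recs).empty


class TestApoeExclusion:
    def test_in_region_snp_removed_other_chrom_retained(self):
        recs = _records([("in", 19, 45_000_000, "A", "G", 0.1, 0.5, 0.2, 0.95),
                         ("out", 2, 45_000_000, "A", "G", 0.1, 0.5, 0.2, 0.95)])
        assert list(exclude_apoe(recs)["SNP"]) == ["out"]

    def test_counting_four_of_twenty(self):
        rows = [(f"s{i}", 19 if i < 4 else 1,
                 44_500_000 if i < 4 else 1_000 * i, "A", "G", 0.0, 0.5, 0.2, 0.95)
                for i in range(20)]
        assert len(exclude_apoe(_records(rows))) == 16

    def test_interval_is_closed(self):
        recs = _records([("edge", 19, 44_400_000, "A", "G", 0.1, 0.5, 0.2, 0.95)])
        assert exclude_apoe(recs).empty


class TestPathwayRestriction:
    def test_empty_intersection_warns_and_empties(self, caplog):
        recs = _records([("a", 1, 1, "A", "G", 0.1, 0.5, 0.2, 0.95)])
        assert restrict_to_pathway(recs, ["z"]).empty

    def test_superset_is_identity(self):
        recs = _records([("a", 1, 1, "A", "G", 0.1, 0.5, 0.2, 0.95),
                         ("b", 1, 2, "A", "G", 0.1, 0.5, 0.2, 0.95)])
        out = restrict_to_pathway(recs, ["a", "b", "c"])
        pd.testing.assert_frame_equal(out, recs)

    def test_matches_set_intersection_oracle(self, rng):
        snps = [f"s{i}" for i in range(30)]
        recs = _records([(s, 1, i, "A", "G", 0.0, 0.5, 0.2, 0.95)
                         for i, s in enumerate(snps)])
        wanted = list(rng.choice(snps, size=12, replace=False))
        out = restrict_to_pathway(recs, wanted)
        assert set(out["SNP"]) == set(snps) & set(wanted)

    def test_empty_list_rejected(self):
        with pytest.raises(PRSError, match="empty"):
            restrict_to_pathway(_records([]), [])


class TestLDClump:
    def test_distant_snps_both_retained(self, rng):
        x = rng.integers(0, 3, 100).astype(float)
        panel = _panel({"a": x, "b": x},  # r2 = 1 but 600 kb apart
                       [("a", 1, 100_000, "A", "G"), ("b", 1, 700_000, "A", "G")])
        recs = _records([("a", 1, 100_000, "A", "G", 0.1, 1e-8, 0.2, 0.95),
                         ("b", 1, 700_000, "A", "G", 0.1, 1e-3, 0.2, 0.95)])
        assert set(ld_clump(recs, panel)["SNP"]) == {"a", "b"}

    def test_nearby_correlated_snp_removed_keeping_smaller_p(self, rng):
        x = rng.integers(0, 3, 100).astype(float)
        panel = _panel({"a": x, "b": x},
                       [("a", 1, 100_000, "A", "G"), ("b", 1, 200_000, "A", "G")])
        recs = _records([("a", 1, 100_000, "A", "G", 0.1, 1e-8, 0.2, 0.95),
                         ("b", 1, 200_000, "A", "G", 0.1, 1e-3, 0.2, 0.95)])
        assert list(ld_clump(recs, panel)["SNP"]) == ["a"]

    def test_disabled_cutoff_retains_everything(self):
        result = generate_genotype_panel(GenotypePanelConfig(
            n_individuals=200, n_snps=20, ld_block_size=5, seed=4))
        out = ld_clump(result.sumstats, result.genotypes, r2_cutoff=1.0 + 1e-9)
        assert len(out) == 20

    def test_block_panel_matches_independent_greedy_oracle(self):
        result = generate_genotype_panel(GenotypePanelConfig(
            n_individuals=400, n_snps=50, ld_block_size=10,
            within_block_r2=0.5, seed=11))
        got = ld_clump(result.sumstats, result.genotypes, r2_cutoff=0.1)
        dose = result.genotypes.dosages

        def r2(a, b):
            return np.corrcoef(dose[a], dose[b])[0, 1] ** 2

        snps = list(result.sumstats[["SNP", "CHR", "BP", "P"]].itertuples(index=False))
        expected = oracles.greedy_clump(snps, r2, 500_000.0, 0.1)
        assert set(got["SNP"]) == set(expected)

    def test_missing_genotype_column_fails_or_skips(self, rng):
        panel = _panel({"a": rng.integers(0, 3, 50).astype(float)})
        recs = _records([("a", 1, 1000, "A", "G", 0.1, 1e-4, 0.2, 0.95),
                         ("ghost", 1, 2000, "A", "G", 0.1, 1e-5, 0.2, 0.95)])
        with pytest.raises(PRSError, match="no genotypes"):
            ld_clump(recs, panel)
        out = ld_clump(recs, panel, on_missing_genotype="skip")
        assert list(out["SNP"]) == ["a"]


class TestScoring:
    def test_two_snp_hand_example(self):
        # (1 x 0.2 + 2 x (-0.1)) / (2 x 2) = 0.0
        panel = _panel({"a": [1.0], "b": [2.0]})
        recs = _records([("a", 1, 1000, "A", "G", 0.2, 1e-4, 0.2, 0.95),
                         ("b", 1, 2000, "A", "G", -0.1, 1e-4, 0.2, 0.95)])
        score = compute_score(recs, panel)
        assert score.iloc[0] == pytest.approx(0.0)

    def test_all_zero_effects_give_zero_scores(self, rng):
        panel = _panel({s: rng.integers(0, 3, 20).astype(float) for s in "abc"})
        recs = _records([(s, 1, 1000 * i, "A", "G", 0.0, 0.5, 0.2, 0.95)
                         for i, s in enumerate("abc", 1)])
        assert np.allclose(compute_score(recs, panel), 0.0)

    def test_allele_swap_invariance(self, rng):
        d = rng.integers(0, 3, 30).astype(float)
        panel = _panel({"a": d})
        straight = _records([("a", 1, 1000, "A", "G", 0.3, 0.5, 0.2, 0.95)])
        swapped = _records([("a", 1, 1000, "G", "A", -0.3, 0.5, 0.2, 0.95)])
        s1 = compute_score(straight, panel)
        s2 = compute_score(swapped, panel)
        assert np.allclose(s1, s2)

    def test_strand_ambiguous_snp_dropped(self, rng):
        d = rng.integers(0, 3, 10).astype(float)
        panel = _panel({"a": d}, [("a", 1, 1000, "A", "T")])
        recs = _records([("a", 1, 1000, "A", "T", 0.3, 0.5, 0.2, 0.95)])
        assert align_alleles(recs, panel).empty
        assert compute_score(recs, panel).isna().all()

    def test_column_order_invariance(self, rng):
        dosages = {s: rng.integers(0, 3, 25).astype(float) for s in "abcd"}
        panel = _panel(dosages)
        rows = [(s, 1, 1000 * i, "A", "G", rng.normal(), 0.5, 0.2, 0.95)
                for i, s in enumerate("abcd", 1)]
        recs = _records(rows)
        shuffled = recs.iloc[[2, 0, 3, 1]].reset_index(drop=True)
        assert np.allclose(compute_score(recs, panel), compute_score(shuffled, panel))

    def test_missing_dosages_use_mean_convention(self):
        panel = _panel({"a": [2.0, np.nan], "b": [1.0, 1.0]})
        recs = _records([("a", 1, 1000, "A", "G", 0.4, 0.5, 0.2, 0.95),
                         ("b", 1, 2000, "A", "G", 0.2, 0.5, 0.2, 0.95)])
        score = compute_score(recs, panel)
        assert score.iloc[0] == pytest.approx((2 * 0.4 + 1 * 0.2) / 4)
        assert score.iloc[1] == pytest.approx((1 * 0.2) / 2)

    def test_sum_convention(self):
        panel = _panel({"a": [1.0]})
        recs = _records([("a", 1, 1000, "A", "G", 0.4, 0.5, 0.2, 0.95)])
        assert compute_score(recs, panel, convention="sum").iloc[0] == pytest.approx(0.4)


class TestGrid:
    def test_twenty_definitions_eight_thresholds(self):
        configs = enumerate_configs()
        defs = {(c.score_name, c.include_apoe) for c in configs}
        assert len(defs) == 20
        assert len({c.p_threshold for c in configs}) == 8
        assert len(configs) == 160

    def test_nine_pathways(self):
        assert len(PATHWAYS) == 9
        assert "tau_protein_binding" in PATHWAYS
        assert "plasma_lipoprotein_particle_assembly" in PATHWAYS

    def test_primary_threshold_in_grid(self):
        assert 1e-3 in P_THRESHOLDS

    def test_invalid_threshold_rejected(self):
        with pytest.raises(PRSError, match="p_threshold"):
            PRSConfig("genome_wide", True, 0.2)

    def test_score_panel_has_full_grid(self):
        result = generate_genotype_panel(GenotypePanelConfig(
            n_individuals=120, n_snps=30, ld_block_size=5, seed=5))
        pathways = {name: list(result.sumstats["SNP"][:10]) for name in PATHWAYS}
        panel = build_score_panel(result.sumstats, result.genotypes, pathways)
        assert panel.scores.shape == (120, 160)
        assert set(panel.scores.columns) == {c.column for c in enumerate_configs()}

    def test_missing_pathway_list_gives_missing_scores(self):
        result = generate_genotype_panel(GenotypePanelConfig(
            n_individuals=60, n_snps=20, ld_block_size=5, seed=6))
        panel = build_score_panel(result.sumstats, result.genotypes, pathway_snps={})
        col = PRSConfig("tau_protein_binding", True, 0.5).column
        assert panel.scores[col].isna().all()
        gw = PRSConfig("genome_wide", True, 0.5).column
        assert panel.scores[gw].notna().all()

    def test_genome_wide_score_tracks_liability(self):
        result = generate_genotype_panel(GenotypePanelConfig(
            n_individuals=2000, n_snps=60, ld_block_size=5,
            causal_fraction=0.3, seed=9))
        panel = build_score_panel(result.sumstats, result.genotypes)
        col = PRSConfig("genome_wide", True, 0.5).column
        score = panel.scores[col]
        mask = score.notna()
        r = np.corrcoef(score[mask], result.liability[mask])[0, 1]
        from scipy import stats as sps
        n = mask.sum()
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert r > 0 and 2 * sps.t.sf(abs(t), n - 2) < 0.01


class TestVCF:
    def test_vcf_ds_round_trip(self, tmp_path):
        pytest.importorskip("cyvcf2")
        from connectoprs.prs import read_genotypes_vcf
        vcf = tmp_path / "tiny.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t1000\trs1\tG\tA\t.\tPASS\t.\tGT:DS\t0/1:1.0\t1/1:2.0\n"
            "1\t2000\trs2\tG\tA\t.\tPASS\t.\tGT:DS\t0/0:0.1\t0/1:0.9\n"
        )
        panel = read_genotypes_vcf(vcf)
        assert list(panel.dosages.index) == ["S1", "S2"]
        assert panel.dosages.loc["S2", "rs1"] == pytest.approx(2.0)
        assert panel.snp_info.loc["rs2", "A1"] == "A"  # ALT is the counted allele

    def test_dosage_bounds_enforced(self):
        with pytest.raises(PRSError, match=r"\[0, 2\]"):
            _panel({"a": [3.0]})

    def test_write_read_round_trip(self, tmp_path, rng):
        pytest.importorskip("cyvcf2")
        from connectoprs.prs import read_genotypes_vcf, write_genotypes_vcf
        panel = _panel({s: rng.integers(0, 3, 5).astype(float) for s in "ab"})
        path = tmp_path / "panel.vcf"
        write_genotypes_vcf(panel, path)
        back = read_genotypes_vcf(path)
        pd.testing.assert_frame_equal(back.dosages, panel.dosages,
                                      check_index_type=False)
        assert list(back.snp_info["A1"]) == list(panel.snp_info["A1"])
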