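"""Simulator: divergence targets, cross inheritance, map geometry, expression."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from sexchrom import io, simcross
from sexchrom._codon import STOP_CODONS, split_codons


def _no_internal_stops(cds: str) -> bool:
    return not any(c in STOP_CODONS for c in split_codons(cds))


class TestGametologTriplets:
    def test_zero_branch_gives_identical_sequences(self):
        cfg = simcross.SimConfig(codons_per_gene=50)
        genes = simcross.simulate_gametolog_triplets(cfg, "PAR", cfg.rng(), n_genes=3)
        for g in genes:
            assert g.x_cds == g.y_cds  # ds_xy target 0 in the PAR
            assert g.branches["X"].ds == 0.0

    def test_omega_zero_changes_only_synonymous_sites(self):
        cfg = simcross.SimConfig(codons_per_gene=80)
        cfg.branch_targets["qXdr"].omega_y = 0.0
        genes = simcross.simulate_gametolog_triplets(cfg, "qXdr", cfg.rng(), n_genes=5)
        for g in genes:
            assert str(Seq(g.y_cds).translate()) == str(Seq(g.ancestor).translate())
            assert g.branches["Y"].n_nonsyn == 0

    def test_no_internal_stop_in_any_emitted_cds(self):
        cfg = simcross.SimConfig(codons_per_gene=60)
        genes = simcross.simulate_gametolog_triplets(cfg, "Xpr", cfg.rng(), n_genes=10)
        for g in genes:
            assert all(_no_internal_stops(s) for s in (g.x_cds, g.y_cds, g.og_cds))

    def test_realized_ds_matches_event_log_and_target(self):
        """Mean realized X:Y dS from the event log hits the 0.063 target."""
        cfg = simcross.SimConfig(seed=11, codons_per_gene=500)
        genes = simcross.simulate_gametolog_triplets(cfg, "Xpr", cfg.rng(), n_genes=100)
        # oracle: count synonymous events per synonymous site from the truth log
        per_gene = [
            (g.branches["X"].n_syn / g.branches["X"].s_sites)
            + (g.branches["Y"].n_syn / g.branches["Y"].s_sites)
            for g in genes
        ]
        assert np.mean(per_gene) == pytest.approx(0.063, abs=0.007)
        # truth table agrees with the event log
        tt = simcross.triplet_truth_table(genes)
        assert tt["ds"].to_numpy() == pytest.approx(
            (tt["n_syn"] / tt["s_sites"]).to_numpy()
        )

    def test_convergence_at_500_genes(self):
        cfg = simcross.SimConfig(seed=5, codons_per_gene=200)
        genes = simcross.simulate_gametolog_triplets(cfg, "qXdr", cfg.rng(), n_genes=500)
        mean_ds = np.mean([g.realized_ds_xy for g in genes])
        assert abs(mean_ds - 0.091) / 0.091 < 0.05

    def test_unreachable_target_rejected(self):
        cfg = simcross.SimConfig()
        cfg.branch_targets["Xpr"].ds_x_og = 0.01  # < ds_xy/2
        with pytest.raises(simcross.ConfigurationError):
            cfg.validate()


class TestCross:
    def test_determinism_byte_identical_fastq(self, small_config, small_genes, tmp_path):
        outs = []
        for run in ("a", "b"):
            cross = simcross.simulate_cross(
                small_config, small_genes, np.random.default_rng(123)
            )
            d = tmp_path / run
            io.write_cross_fastq(cross, d)
            outs.append((d / "father_R1.fastq").read_bytes())
        assert outs[0] == outs[1]

    def test_every_offspring_allele_present_in_a_parent(self, small_cross):
        """Conservation: offspring haplotypes are copies of parental ones."""
        ped = small_cross.pedigree.set_index("sample_id")
        for gc in small_cross.genes.values():
            parental = {"X_ref", "Y", "X_m1", "X_m2"}
            for sid, (h1, h2) in gc.sample_haps.items():
                if ped.loc[sid, "role"] == "offspring":
                    assert {h1, h2} <= parental
                    if ped.loc[sid, "sex"] == "M":
                        assert "Y" in (h1, h2)
                    else:
                        assert "Y" not in (h1, h2)

    def test_truth_y_sites_absent_from_mother_and_daughters(self, small_cross):
        """At every true Y-SNP the mother and daughters carry no Y allele."""
        ped = small_cross.pedigree
        females = set(ped.loc[ped["sex"] == "F", "sample_id"])
        for gc in small_cross.genes.values():
            for _, site in gc.y_sites.iterrows():
                y_code = simcross.BASES.index(site["y_allele"])
                for sid in females:
                    for hap_name in gc.sample_haps[sid]:
                        assert gc.haplotypes[hap_name][site["pos"]] != y_code

    def test_mean_depth_matches_lander_waterman(self):
        """Observed per-site depth tracks the configured coverage."""
        cfg = simcross.SimConfig(
            seed=3,
            codons_per_gene=500,  # 1500 bp genes
            n_genes_per_region={"Xpr": 4},
            cross=simcross.CrossConfig(
                n_f1_genomic=2, n_f2_transcriptomic=0, coverage_genomic=20.0,
                read_length=150, error_rate=0.0,
            ),
        )
        rng = cfg.rng()
        genes = simcross.simulate_gametolog_triplets(cfg, "Xpr", rng, n_genes=4)
        cross = simcross.simulate_cross(cfg, genes, rng)
        depths = []
        for gc in cross.genes.values():
            rs = gc.reads["father"]
            L = gc.length
            cover = np.zeros(L)
            for starts in (rs.starts1, rs.starts2):
                for s in starts:
                    cover[s : s + 150] += 1
            depths.append(cover.mean())
        assert np.mean(depths) == pytest.approx(20.0, rel=0.15)

    def test_zero_progeny_of_one_sex_rejected(self):
        with pytest.raises(simcross.ConfigurationError):
            simcross.build_pedigree(
                simcross.CrossConfig(n_f1_genomic=1, n_f2_transcriptomic=0)
            )


class TestGeneticMap:
    def test_total_map_length_matches_closed_form_integral(self):
        geom = simcross.MapGeometry(
            chrom_length=370_600_000, distal_p_length=25_600_000,
            distal_q_length=15_000_000, rate_distal=2.0, rate_center=0.0,
        )
        assert simcross.map_cm_at(geom, geom.chrom_length) == pytest.approx(81.2)

    def test_linear_segment_cm_difference(self):
        geom = simcross.MapGeometry(rate_distal=2.0, rate_center=0.0)
        cm = simcross.map_cm_at(geom, np.array([0, 10_000_000]))
        assert cm[1] - cm[0] == pytest.approx(20.0)  # 2 cM/Mb over 10 Mb

    def test_suppressed_center_markers_share_cm_without_noise(self):
        cfg = simcross.SimConfig(
            map_geometry=simcross.MapGeometry(rate_center=0.0, cm_noise_sd=0.0)
        )
        sim = simcross.simulate_genetic_map(cfg, cfg.rng())
        b1, b2 = cfg.map_geometry.boundaries
        center = sim.markers[
            (sim.truth["true_pos"] >= b1) & (sim.truth["true_pos"] < b2)
        ]
        assert center["cm_female"].nunique() == 1

    def test_markers_denser_in_recombining_regions(self):
        cfg = simcross.SimConfig()
        sim = simcross.simulate_genetic_map(cfg, cfg.rng())
        g = cfg.map_geometry
        b1, b2 = g.boundaries
        distal_len = (g.distal_p_length + g.distal_q_length) / 1e6
        center_len = (b2 - b1) / 1e6
        pos = sim.truth["true_pos"]
        distal_density = ((pos < b1) | (pos >= b2)).sum() / distal_len
        center_density = ((pos >= b1) & (pos < b2)).sum() / center_len
        assert distal_density > 3 * center_density

    def test_too_few_markers_rejected(self):
        with pytest.raises(simcross.ConfigurationError):
            simcross.SimConfig(
                map_geometry=simcross.MapGeometry(n_markers=5)
            ).validate()


class TestExpression:
    def test_mean_structure_and_log2_ratio(self):
        """y_degeneration delta=0.5 -> log2(F/M) -> log2(2/1.5) ~ 0.415."""
        cfg = simcross.SimConfig(
            n_genes_per_region={"Xpr": 30},
            codons_per_gene=10,
            cross=simcross.CrossConfig(n_f1_genomic=2, n_f2_transcriptomic=50),
        )
        cfg.expression.y_degeneration["Xpr"] = 0.5
        cfg.expression.dispersion = 0.05
        gene_df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(30)], "region": "Xpr"}
        )
        rec = simcross.simulate_expression(cfg, gene_df, np.random.default_rng(2))
        assert (rec.loc[rec["sex"] == "F", "counts_y"] == 0).all()
        f = rec[rec["sex"] == "F"].groupby("gene_id")[["counts_x", "counts_y"]].sum().sum(axis=1)
        m = rec[rec["sex"] == "M"].groupby("gene_id")[["counts_x", "counts_y"]].sum().sum(axis=1)
        assert np.log2(f.sum() / m.sum()) == pytest.approx(np.log2(2 / 1.5), abs=0.1)

    def test_symmetric_means_when_no_degeneration(self):
        cfg = simcross.SimConfig()
        cfg.expression.y_degeneration = {"Xpr": 1.0}
        gene_df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(40)], "region": "Xpr"})
        rec = simcross.simulate_expression(cfg, gene_df, np.random.default_rng(3))
        male = rec.loc[rec["sex"] == "M", ["counts_x", "counts_y"]].sum(axis=1).mean()
        female = rec.loc[rec["sex"] == "F", ["counts_x", "counts_y"]].sum(axis=1).mean()
        assert male == pytest.approx(female, rel=0.05)

    def test_zero_dispersion_is_poisson_limit(self):
        cfg = simcross.SimConfig()
        cfg.expression.dispersion = 0.0
        gene_df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(200)], "region": "PAR"})
        rec = simcross.simulate_expression(cfg, gene_df, np.random.default_rng(4))
        males = rec.loc[rec["sex"] == "M", "counts_x"]
        assert males.var() == pytest.approx(males.mean(), rel=0.15)


def test_config_yaml_roundtrip(tmp_path):
    cfg = simcross.SimConfig(seed=42, codons_per_gene=77)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = simcross.SimConfig.from_yaml(path)
    assert back == cfg
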