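"""Y-diagnostic SNP classification, read partitioning and consensus building."""

import numpy as np
import pandas as pd
import pytest

from sexchrom import simcross, ygametolog


def _pedigree(n_sons=5, n_daughters=5, datatype="genomic"):
    rows = [
        {"sample_id": "father", "family": "fam1", "sex": "M", "role": "father",
         "generation": "P", "datatype": "genomic"},
        {"sample_id": "mother", "family": "fam1", "sex": "F", "role": "mother",
         "generation": "P", "datatype": "genomic"},
    ]
    for i in range(n_sons):
        rows.append({"sample_id": f"son{i}", "family": "fam1", "sex": "M",
                     "role": "offspring", "generation": "F1", "datatype": datatype})
    for i in range(n_daughters):
        rows.append({"sample_id": f"dau{i}", "family": "fam1", "sex": "F",
                     "role": "offspring", "generation": "F1", "datatype": datatype})
    return pd.DataFrame(rows)


def _obs(depths: dict[str, dict[str, int]], pos=10):
    rows = []
    for sid, d in depths.items():
        rows.append({"chrom": "g1", "pos": pos, "sample_id": sid,
                     "A": d.get("A", 0), "C": d.get("C", 0),
                     "G": d.get("G", 0), "T": d.get("T", 0)})
    return pd.DataFrame(rows)


class TestClassifySites:
    def test_canonical_y_linked_site(self):
        """Father het A/G, all sons carry G, no daughter does: Y-linked."""
        depths = {"father": {"A": 11, "G": 9}, "mother": {"A": 20}}
        for i in range(5):
            depths[f"son{i}"] = {"A": 6, "G": 6}
            depths[f"dau{i}"] = {"A": 12}
        out = ygametolog.classify_sites(_obs(depths), _pedigree())
        assert out.iloc[0]["status"] == "Y_linked"
        assert out.iloc[0]["y_allele"] == "G"
        assert out.iloc[0]["x_allele"] == "A"
        assert out.iloc[0]["n_sons_support"] == 5

    def test_daughter_carrying_y_allele_is_hard_reject(self):
        depths = {"father": {"A": 11, "G": 9}, "mother": {"A": 20}}
        for i in range(5):
            depths[f"son{i}"] = {"A": 6, "G": 6}
            depths[f"dau{i}"] = {"A": 12}
        depths["dau0"] = {"A": 8, "G": 4}
        out = ygametolog.classify_sites(_obs(depths), _pedigree())
        assert out.iloc[0]["status"] == "rejected"
        assert out.iloc[0]["reject_reason"] == "daughter_carries_y"

    def test_heterozygous_mother_rejected(self):
        depths = {"father": {"A": 11, "G": 9}, "mother": {"A": 10, "G": 10}}
        for i in range(5):
            depths[f"son{i}"] = {"A": 6, "G": 6}
            depths[f"dau{i}"] = {"A": 12}
        out = ygametolog.classify_sites(_obs(depths), _pedigree())
        assert out.iloc[0]["reject_reason"] == "mother_heterozygous"

    def test_son_missing_y_allele_rejected(self):
        depths = {"father": {"A": 11, "G": 9}, "mother": {"A": 20}}
        for i in range(5):
            depths[f"son{i}"] = {"A": 6, "G": 6}
            depths[f"dau{i}"] = {"A": 12}
        depths["son3"] = {"A": 14}
        out = ygametolog.classify_sites(_obs(depths), _pedigree())
        assert out.iloc[0]["reject_reason"] == "son_missing_y"

    def test_rna_sons_tolerate_bounded_dropout(self):
        """One of five RNA sons missing the Y allele stays within tolerance."""
        depths = {"father": {"A": 11, "G": 9}, "mother": {"A": 20}}
        for i in range(5):
            depths[f"son{i}"] = {"A": 6, "G": 6}
            depths[f"dau{i}"] = {"A": 12}
        depths["son4"] = {"A": 14}  # Y copy silenced in this son's transcriptome
        ped = _pedigree(datatype="rna")
        out = ygametolog.classify_sites(_obs(depths), ped)
        assert out.iloc[0]["status"] == "Y_linked"
        depths["son3"] = {"A": 14}  # two of five: beyond the 20% tolerance
        out = ygametolog.classify_sites(_obs(depths), ped)
        assert out.iloc[0]["reject_reason"] == "rna_son_dropout"

    def test_zero_depth_site_skipped(self):
        obs = _obs({"father": {}, "mother": {}})
        out = ygametolog.classify_sites(obs, _pedigree())
        assert out.empty

    def test_raising_min_depth_never_increases_calls_on_simulated_data(
        self, small_cross
    ):
        counts = []
        for md in (5, 8, 12):
            sites = ygametolog.classify_sites(
                small_cross.observations, small_cross.pedigree, min_depth=md
            )
            counts.append((sites["status"] == "Y_linked").sum())
        assert counts[0] >= counts[1] >= counts[2]


class TestPartitionReads:
    def _sites(self):
        return pd.DataFrame(
            {"chrom": ["g1", "g1"], "pos": [10, 40], "x_allele": ["A", "C"],
             "y_allele": ["G", "T"], "status": ["Y_linked", "Y_linked"]}
        )

    def test_spec_hand_cases(self):
        overlap = pd.DataFrame(
            {
                "read_id": ["r1", "r2", "r2", "r3"],
                "chrom": "g1",
                "pos": [10, 10, 40, 10],
                "base": ["G", "G", "C", "A"],
            }
        )
        out = ygametolog.partition_reads(
            overlap, self._sites(), all_read_ids=["r1", "r2", "r3", "r4"]
        ).set_index("read_id")
        assert out.loc["r1", "bin"] == "Y"  # one y allele, mate covers nothing
        assert out.loc["r2", "bin"] == "ambiguous"  # y at one site, x at another
        assert out.loc["r3", "bin"] == "X"
        assert out.loc["r4", "bin"] == "uninformative"

    def test_third_allele_is_ambiguous(self):
        overlap = pd.DataFrame(
            {"read_id": ["r1"], "chrom": "g1", "pos": [10], "base": ["T"]}
        )
        out = ygametolog.partition_reads(overlap, self._sites())
        assert out.iloc[0]["bin"] == "ambiguous"

    def test_partition_is_exhaustive_and_exclusive(self, small_cross):
        sites = ygametolog.classify_sites(small_cross.observations, small_cross.pedigree)
        universe = small_cross.read_ids()
        out = ygametolog.partition_reads(small_cross.overlap, sites, all_read_ids=universe)
        assert len(out) == len(universe)
        assert out["read_id"].is_unique
        assert set(out["bin"]) <= {"Y", "X", "ambiguous", "uninformative"}
        assert (out.loc[out["bin"].isin(["Y", "X"]), "supporting_sites"] >= 1).all()


class TestConsensus:
    def test_majority_depth_and_tie_rules(self):
        pile = np.zeros((4, 4), dtype=int)
        pile[0, 0] = 5  # A:5 -> A
        pile[1, 1] = 2  # C:2 -> below min_depth
        pile[2, 0] = 3  # A:3, G:3 -> tie
        pile[2, 2] = 3
        cons = ygametolog.build_consensus(pile, min_depth=3)
        assert cons.sequence == "ANNN"
        assert cons.fraction_called == 0.25

    def test_empty_pileup_all_n_with_zero_fraction(self):
        cons = ygametolog.build_consensus(np.zeros((6, 4)), min_depth=3)
        assert cons.sequence == "N" * 6 and cons.fraction_called == 0.0

    def test_error_free_consensus_equals_true_y_haplotype(self):
        cfg = simcross.SimConfig(
            seed=9, codons_per_gene=100, n_genes_per_region={"qXdr": 4},
            cross=simcross.CrossConfig(
                n_f1_genomic=6, n_f2_transcriptomic=0,
                coverage_genomic=30.0, read_length=50, error_rate=0.0,
            ),
        )
        rng = cfg.rng()
        genes = simcross.simulate_gametolog_triplets(cfg, "qXdr", rng, n_genes=4)
        cross = simcross.simulate_cross(cfg, genes, rng)
        sites = ygametolog.classify_sites(cross.observations, cross.pedigree)
        assign = ygametolog.partition_reads(cross.overlap, sites)
        for g in genes:
            cons = ygametolog.consensus_from_cross(cross, assign, g.gene_id)
            for got, want in zip(cons.sequence, g.y_cds):
                if got != "N":
                    assert got == want

    def test_no_y_linked_site_and_daughter_invariant(self, small_cross):
        """No Y_linked call may coincide with a daughter carrying that allele."""
        sites = ygametolog.classify_sites(small_cross.observations, small_cross.pedigree)
        called = sites[sites["status"] == "Y_linked"]
        ped = small_cross.pedigree
        daughters = set(
            ped.loc[(ped["role"] == "offspring") & (ped["sex"] == "F"), "sample_id"]
        )
        obs = small_cross.observations.set_index(["chrom", "pos", "sample_id"])
        for _, site in called.iterrows():
            for d in daughters:
                try:
                    row = obs.loc[(site["chrom"], site["pos"], d)]
                except KeyError:
                    continue
                depth = row[list("ACGT")].sum()
                if depth >= 5:
                    frac = row[site["y_allele"]] / depth
                    assert row[site["y_allele"]] < 2 or frac < 0.05


class TestValidation:
    def test_identity_gives_perfect_scores(self):
        sites = pd.DataFrame(
            {"chrom": ["g1"], "pos": [3], "x_allele": ["A"], "y_allele": ["G"],
             "status": ["Y_linked"]}
        )
        truth = pd.DataFrame(
            {"chrom": ["g1"], "pos": [3], "x_allele": ["A"], "y_allele": ["G"]}
        )
        rep = ygametolog.validate_against_truth(sites, truth)
        assert rep["site_precision"] == 1.0 and rep["site_recall"] == 1.0

    def test_no_calls_gives_zero_recall(self):
        sites = pd.DataFrame(
            columns=["chrom", "pos", "x_allele", "y_allele", "status"]
        )
        truth = pd.DataFrame(
            {"chrom": ["g1"], "pos": [3], "x_allele": ["A"], "y_allele": ["G"]}
        )
        rep = ygametolog.validate_against_truth(sites, truth)
        assert rep["site_recall"] == 0.0
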