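"""Orthogroups, occurrence dedup, core/pan genome, rarefaction, UpSet."""

import random

import numpy as np
import pandas as pd
import pytest

from jumboclade import pangenome
from jumboclade.aai import AAIMatrix
from jumboclade.pangenome import OccurrenceMatrix, Orthogroup
from jumboclade.records import GeneRecord


def _gene(genome, gid, protein):
    return GeneRecord(genome, gid, 1, 3 * len(protein) + 3, "+", protein)


def _random_protein(rng, length=60):
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))


class TestInferOrthogroups:
    def test_two_identical_genomes_pair_every_gene(self):
        rng = random.Random(0)
        prots = [_random_protein(rng) for _ in range(5)]
        proteomes = {
            "g1": [_gene("g1", f"g1_{i}", p) for i, p in enumerate(prots)],
            "g2": [_gene("g2", f"g2_{i}", p) for i, p in enumerate(prots)],
        }
        ogs = pangenome.infer_orthogroups(proteomes)
        assert len(ogs) == 5
        assert all(len(og) == 2 for og in ogs)

    def test_og_ids_ranked_by_size(self, small_clade):
        ogs = pangenome.infer_orthogroups(small_clade.genes)
        sizes = [len(og) for og in ogs]
        assert sizes == sorted(sizes, reverse=True)
        assert ogs[0].og_id == "OG0000000"
        assert all(og.og_id == f"OG{i:07d}" for i, og in enumerate(ogs))

    def test_partition_covers_every_gene_once(self, small_clade):
        ogs = pangenome.infer_orthogroups(small_clade.genes)
        seen = [gid for og in ogs for _, gid in og.members]
        expected = [g.gene_id for gl in small_clade.genes.values() for g in gl]
        assert sorted(seen) == sorted(expected)

    def test_single_genome_gives_singletons(self):
        rng = random.Random(1)
        proteome = [_gene("g1", f"g1_{i}", _random_protein(rng))
                    for i in range(4)]
        ogs = pangenome.infer_orthogroups({"g1": proteome})
        assert len(ogs) == 4
        assert all(len(og) == 1 for og in ogs)


def _aai_matrix(ids, merged_groups=(), base=50.0, high=99.5):
    n = len(ids)
    vals = np.full((n, n), base)
    np.fill_diagonal(vals, 100.0)
    idx = {g: i for i, g in enumerate(ids)}
    for group in merged_groups:
        for a in group:
            for b in group:
                if a != b:
                    vals[idx[a], idx[b]] = high
    return AAIMatrix(list(ids), vals, np.zeros((n, n), dtype=int))


class TestDedupUnits:
    def test_28_genomes_with_triplet_collapse_to_26(self):
        ids = [f"p{i:02d}" for i in range(28)]
        mat = _aai_matrix(ids, merged_groups=[("p00", "p01", "p02")])
        unit_map = pangenome.dedup_occurrence_units(ids, mat, dedup_aai=99)
        assert len(set(unit_map.values())) == 26
        assert unit_map["p00"] == unit_map["p01"] == unit_map["p02"]

    def test_impossible_threshold_keeps_all_units(self):
        ids = ["a", "b", "c"]
        mat = _aai_matrix(ids, merged_groups=[tuple(ids)], high=100.0)
        unit_map = pangenome.dedup_occurrence_units(ids, mat, dedup_aai=101)
        assert len(set(unit_map.values())) == 3

    def test_all_identical_single_unit(self):
        ids = ["a", "b", "c"]
        mat = _aai_matrix(ids, merged_groups=[tuple(ids)], high=100.0)
        unit_map = pangenome.dedup_occurrence_units(ids, mat)
        assert len(set(unit_map.values())) == 1

    def test_lowering_threshold_never_increases_units(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(10)]
        vals = rng.uniform(40, 100, size=(10, 10))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 100.0)
        mat = AAIMatrix(ids, vals, np.zeros((10, 10), dtype=int))
        counts = [len(set(pangenome.dedup_occurrence_units(
            ids, mat, dedup_aai=thr).values()))
            for thr in (100, 95, 90, 70, 50)]
        assert counts == sorted(counts, reverse=True)


def _occ(df):
    return OccurrenceMatrix(df, {c: c for c in df.columns})


class TestCoreGenome:
    def test_80_percent_cutoff_on_26_units(self):
        units = [f"u{i:02d}" for i in range(26)]
        df = pd.DataFrame(0, index=["og_21", "og_20", "og_26"], columns=units)
        df.loc["og_21", units[:21]] = 1  # 21/26 = 0.808 -> core
        df.loc["og_20", units[:20]] = 1  # 20/26 = 0.769 -> not core
        df.loc["og_26", :] = 1
        soft, strict = pangenome.core_genome(_occ(df), cutoff=0.80)
        assert "og_21" in soft and "og_20" not in soft
        assert strict == ["og_26"]

    def test_core_nesting(self, small_clade):
        ids = list(small_clade.truth.occurrence.columns)
        occ = _occ(small_clade.truth.occurrence)
        soft, strict = pangenome.core_genome(occ, cutoff=0.80)
        assert set(strict) <= set(soft) <= set(occ.table.index)

    def test_planted_borderline_family_joins_core(self):
        """26 always-present families plus one planted in 21/26 genomes:
        the 0.80 cutoff admits all 27."""
        from jumboclade import sim
        cfg = sim.CladeSimConfig(
            n_genomes=26, core_n=26, accessory_pool=0, host_implants=(),
            dtr_fraction=0.0, occurrence_overrides={"fam_border": tuple(range(21))},
            seed=2)
        clade = sim.simulate_clade(cfg)
        occ = _occ(clade.truth.occurrence)
        soft, strict = pangenome.core_genome(occ, cutoff=0.80)
        assert len(soft) == 27
        assert len(strict) == 26

    def test_invalid_cutoff_rejected(self):
        df = pd.DataFrame(1, index=["og"], columns=["u1"])
        with pytest.raises(ValueError):
            pangenome.core_genome(_occ(df), cutoff=0.0)


class TestOccurrenceCollapsing:
    def test_within_genome_duplicate_changes_no_cell(self):
        og_dup = Orthogroup("OG0000000",
                            (("g1", "a1"), ("g1", "a2"), ("g2", "b1")))
        og_single = Orthogroup("OG0000000", (("g1", "a1"), ("g2", "b1")))
        unit_map = {"g1": "g1", "g2": "g2"}
        m_dup = pangenome.occurrence_matrix([og_dup], unit_map)
        m_single = pangenome.occurrence_matrix([og_single], unit_map)
        pd.testing.assert_frame_equal(m_dup.table, m_single.table)
        assert set(np.unique(m_dup.table.to_numpy())) <= {0, 1}


class TestRarefaction:
    def test_identical_genomes_flat_pan(self):
        df = pd.DataFrame(1, index=[f"og{i}" for i in range(7)],
                          columns=["u1", "u2", "u3"])
        table = pangenome.rarefaction(_occ(df), n_perm=5, seed=0)
        assert (table["pan_mean"] == 7).all()
        assert (table["core_mean"] == 7).all()

    def test_disjoint_proteomes(self):
        df = pd.DataFrame(np.eye(3, dtype=int),
                          index=["og1", "og2", "og3"],
                          columns=["u1", "u2", "u3"])
        table = pangenome.rarefaction(_occ(df), n_perm=4, seed=1)
        assert list(table["pan_mean"]) == [1, 2, 3]
        assert list(table["core_mean"])[1:] == [0, 0]

    def test_deterministic_under_seed(self, small_clade):
        occ = _occ(small_clade.truth.occurrence)
        t1 = pangenome.rarefaction(occ, n_perm=3, seed=9)
        t2 = pangenome.rarefaction(occ, n_perm=3, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_monotone_within_any_run(self, small_clade):
        occ = _occ(small_clade.truth.occurrence)
        table = pangenome.rarefaction(occ, n_perm=20, seed=2)
        assert table["pan_mean"].is_monotonic_increasing
        assert (table["core_mean"].diff().dropna() <= 0).all()


class TestSharedOGCounts:
    def test_two_identical_genomes_single_intersection(self):
        df = pd.DataFrame(1, index=[f"og{i}" for i in range(4)],
                          columns=["u1", "u2"])
        table = pangenome.shared_og_counts(_occ(df))
        assert len(table) == 1
        assert table.loc[0, "units"] == "u1,u2"
        assert table.loc[0, "n_ogs"] == 4

    def test_counts_partition_the_pangenome(self, small_clade):
        occ = _occ(small_clade.truth.occurrence)
        table = pangenome.shared_og_counts(occ)
        assert table["n_ogs"].sum() == len(occ.table)

    def test_full_intersection_at_least_planted_core(self, small_clade):
        occ = _occ(small_clade.truth.occurrence)
        table = pangenome.shared_og_counts(occ)
        all_units = ",".join(sorted(occ.table.columns))
        full = table[table["units"] == all_units]["n_ogs"].sum()
        assert full >= small_clade.config.core_n


class TestMembershipTSV:
    def test_round_trip(self, tmp_path, small_clade):
        ogs = [Orthogroup("OG0000000", (("g1", "a1"), ("g2", "b1"))),
               Orthogroup("OG0000001", (("g1", "a2"),))]
        path = tmp_path / "ogs.tsv"
        pangenome.write_og_membership_tsv(ogs, path)
        assert pangenome.read_og_membership_tsv(path) == ogs
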