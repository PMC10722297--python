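"""Properties of the synthetic allotetraploid generator."""

import numpy as np
import pandas as pd
import pytest

from allohe import simulate as sim
from allohe.sequences import decode


def tiny_config(**kw):
    defaults = dict(seed=5, n_chromosomes=1, chromosome_length=200_000,
                    he_segments=[("a", 0, 50_000, 100_000)], coverage=3.0,
                    gene_spacing=10_000, gene_length=1_000,
                    ltr_spec=[
                        {"genome": "hybrid_a", "chromosome": "chr1",
                         "position": 10_000, "family": "Gypsy_G1",
                         "identity": 0.9984, "pair": "p1"},
                        {"genome": sim.ANCESTOR_A_ID, "chromosome": "chr1",
                         "position": 12_000, "family": "Gypsy_G1",
                         "identity": 0.9984, "pair": "p1"},
                    ])
    defaults.update(kw)
    return sim.SimConfig(**defaults)


class TestAncestors:
    def test_zero_divergence_identical(self):
        cfg = tiny_config(ancestor_divergence=0.0)
        a, f = sim.simulate_ancestors(cfg)
        np.testing.assert_array_equal(a["chr1"], f["chr1"])

    def test_mismatch_fraction_within_three_sd(self):
        cfg = tiny_config(chromosome_length=1_000_000, he_segments=[])
        a, f = sim.simulate_ancestors(cfg)
        observed = float((a["chr1"] != f["chr1"]).mean())
        p = sim.expected_pairwise_mismatch(cfg.ancestor_divergence)
        sd = np.sqrt(p * (1 - p) / cfg.chromosome_length)
        assert abs(observed - p) < 3 * sd

    def test_same_seed_identical_fasta(self, tmp_path):
        cfg = tiny_config()
        for run in ("x", "y"):
            a, _ = sim.simulate_ancestors(cfg)
            a.to_fasta(tmp_path / f"{run}.fasta")
        assert (tmp_path / "x.fasta").read_bytes() == (
            tmp_path / "y.fasta").read_bytes()

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            tiny_config(ancestor_divergence=0.6)


class TestHybrid:
    def test_no_he_no_drift_equals_ancestors(self):
        cfg = tiny_config(he_segments=[], subgenome_drift=0.0)
        a, f = sim.simulate_ancestors(cfg)
        hyb, truth = sim.simulate_hybrid(a, f, cfg)
        np.testing.assert_array_equal(hyb["chr1_a"], a["chr1"])
        np.testing.assert_array_equal(hyb["chr1_f"], f["chr1"])
        assert truth.he_intervals == []

    def test_planted_segment_is_donor_sequence(self):
        cfg = tiny_config(subgenome_drift=0.0)
        a, f = sim.simulate_ancestors(cfg)
        hyb, truth = sim.simulate_hybrid(a, f, cfg)
        (chrom, s, e), = truth.he_intervals
        np.testing.assert_array_equal(hyb["chr1_a"][s:e], f["chr1"][s:e])
        np.testing.assert_array_equal(hyb["chr1_a"][:s], a["chr1"][:s])

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(he_segments=[("a", 0, 0, 100_000),
                                     ("a", 0, 50_000, 150_000)])


class TestReads:
    def test_total_bases_near_target_coverage(self):
        cfg = tiny_config(he_segments=[], coverage=20.0,
                          chromosome_length=1_000_000)
        a, f = sim.simulate_ancestors(cfg)
        hyb, _ = sim.simulate_hybrid(a, f, cfg)
        reads = sim.simulate_reads(hyb, cfg)
        total = 2 * reads.n_pairs * reads.read_length
        expected = cfg.coverage * hyb.layout().total_length
        assert abs(total - expected) / expected < 0.05

    def test_reads_are_exact_substrings_of_source(self):
        cfg = tiny_config(he_segments=[])
        a, f = sim.simulate_ancestors(cfg)
        hyb, _ = sim.simulate_hybrid(a, f, cfg)
        reads = sim.simulate_reads(hyb, cfg)
        texts = {i: decode(hyb[n]) for i, n in enumerate(hyb.names)}
        rng = np.random.default_rng(0)
        from allohe.sequences import revcomp
        for i in rng.integers(0, reads.n_pairs, 25):
            text = texts[int(reads.truth_chrom[i])]
            r1 = decode(reads.r1[i])
            assert r1 in text or decode(revcomp(reads.r1[i])) in text

    def test_same_seed_identical_fastq(self, tmp_path):
        cfg = tiny_config()
        a, f = sim.simulate_ancestors(cfg)
        hyb, _ = sim.simulate_hybrid(a, f, cfg)
        for run in ("x", "y"):
            sim.simulate_reads(hyb, cfg).to_fastq(
                tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq")
        assert (tmp_path / "x_1.fq").read_bytes() == (
            tmp_path / "y_1.fq").read_bytes()
        assert (tmp_path / "x_2.fq").read_bytes() == (
            tmp_path / "y_2.fq").read_bytes()

    def test_chromosome_shorter_than_insert_rejected(self):
        cfg = tiny_config(he_segments=[], chromosome_length=200)
        a, f = sim.simulate_ancestors(cfg)
        hyb, _ = sim.simulate_hybrid(a, f, cfg)
        with pytest.raises(ValueError):
            sim.simulate_reads(hyb, cfg)


@pytest.fixture(scope="module")
def universe():
    cfg = tiny_config()
    a, f = sim.simulate_ancestors(cfg)
    hyb, truth = sim.simulate_hybrid(a, f, cfg)
    proteins, genes = sim.simulate_proteins(a, f, hyb, cfg, truth)
    return cfg, truth, proteins, genes


class TestProteins:
    def test_identity_direction_outside_he(self, universe):
        cfg, truth, proteins, genes = universe
        merged = proteins.merge(genes, left_on="protein_id", right_on="gene_id")
        out_a = merged[(merged["chromosome_x"] == "chr1_a") & ~merged["in_he"]]
        assert (out_a["iaa_a"] > out_a["iaa_f"]).mean() > 0.9

    def test_identity_direction_inside_he(self, universe):
        cfg, truth, proteins, genes = universe
        merged = proteins.merge(genes, left_on="protein_id", right_on="gene_id")
        in_he = merged[merged["in_he"]]
        assert len(in_he) >= 3
        assert (in_he["iaa_f"] > in_he["iaa_a"]).all()

    def test_no_divergence_all_identical(self):
        cfg = tiny_config(ancestor_divergence=0.0, subgenome_drift=0.0,
                          he_segments=[])
        a, f = sim.simulate_ancestors(cfg)
        hyb, truth = sim.simulate_hybrid(a, f, cfg)
        proteins, _ = sim.simulate_proteins(a, f, hyb, cfg, truth)
        assert (proteins["iaa_a"] == 100.0).all()
        assert (proteins["iaa_f"] == 100.0).all()


class TestRnaTracks:
    def test_origin_routing_and_empty_windows(self):
        cfg = tiny_config(expressed_fraction=1.0, accession_capture=1.0)
        a, f = sim.simulate_ancestors(cfg)
        hyb, truth = sim.simulate_hybrid(a, f, cfg)
        _, genes = sim.simulate_proteins(a, f, hyb, cfg, truth)
        tracks = sim.simulate_rna_tracks(hyb, genes, cfg)
        # HE genes on chr1_a are F-origin: covered by the F ancestor set only
        he_genes = genes[genes["in_he"]]
        anchors = set(he_genes["anchor"])
        f_starts = set(tracks["ancestor_f_rna"]["chr1_a"][:, 0])
        a_starts = set(tracks["ancestor_a_rna"]["chr1_a"][:, 0])
        assert anchors <= f_starts
        assert not (anchors & a_starts)
        # no gene anchors before the first spacing -> zero coverage there
        for t in tracks.values():
            for iv in t.values():
                assert (iv[:, 0] >= cfg.gene_spacing).all()


class TestLtrSpec:
    def test_planted_pair_recovered(self):
        cfg = tiny_config()
        elements, truth = sim.simulate_ltrs(cfg)
        from allohe.ltr import match_shared_ltrs

        m = match_shared_ltrs(
            elements["hybrid_a"], elements[sim.ANCESTOR_A_ID],
            chromosome_pairs=[("chr1_a", "chr1")])
        assert len(m) == 1
        assert m[0].element_1.identity == 0.9984

    def test_default_spec_round_numbers(self):
        elements, _ = sim.simulate_ltrs(sim.default_config(0))
        assert set(elements) == {"hybrid_a", "hybrid_f",
                                 sim.ANCESTOR_A_ID, sim.ANCESTOR_F_ID}

    def test_overlap_rejected(self):
        cfg = tiny_config()
        cfg.ltr_spec = [
            {"genome": "hybrid_a", "chromosome": "chr1", "position": 1_000,
             "family": "X", "identity": 0.99, "pair": None},
            {"genome": "hybrid_a", "chromosome": "chr1", "position": 2_000,
             "family": "X", "identity": 0.99, "pair": None},
        ]
        with pytest.raises(ValueError):
            sim.simulate_ltrs(cfg)


class TestWriteUniverse:
    def test_determinism_and_manifest(self, tmp_path):
        import json

        cfg = tiny_config(coverage=2.0)
        p1 = sim.write_universe(tmp_path / "run1", cfg)
        p2 = sim.write_universe(tmp_path / "run2", cfg)
        m1 = json.loads((tmp_path / "run1" / "manifest.json").read_text())
        m2 = json.loads((tmp_path / "run2" / "manifest.json").read_text())
        assert m1["checksums"] == m2["checksums"]
        assert (tmp_path / "run1" / "he_truth.bed").exists()
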