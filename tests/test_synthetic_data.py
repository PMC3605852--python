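import json

import numpy as np
import pytest

from divsel.alleles_qc import pooled_error_rate
from divsel.codon_selection import CODON_INDEX, N_STATES, LabeledTree
from divsel.indel_analysis import extract_indels
from divsel.io import fasta_string
from divsel.repeat_architecture import extract_repeat_copies
from divsel.synthetic_data import (
    SimConfig,
    TruthTable,
    fixtures_roundtrip,
    simulate_codon_alignment,
    simulate_dataset,
    simulate_genealogy,
    worked_example_fixtures,
)


def small_config(seed, **kw):
    defaults = dict(
        seed=seed,
        n_individuals=(4, 4),
        n_codons=420,
        intron_length=250,
        target_tree_length=1.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenealogy:
    def test_reproducible_and_labeled(self):
        cfg = small_config(7)
        t1, m1 = simulate_genealogy(cfg)
        t2, m2 = simulate_genealogy(cfg)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        assert m1 == m2
        pops = {p for _, p in m1.values()}
        assert pops == {"bamfield", "sandspit"}
        # two gene copies per diploid individual
        assert len(m1) == 2 * (4 + 4)

    def test_old_split_no_migration_is_reciprocally_monophyletic(self):
        mono = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = SimConfig(
                seed=1000 + seed,
                n_individuals=(3, 3),
                migration_rate=0.0,
                split_generations=500_000.0,
                ne_focal=5_000.0,
                ne_other=5_000.0,
            )
            tree, meta = simulate_genealogy(cfg)
            focal = {a for a, (_, p) in meta.items() if p == "bamfield"}
            taxa = [t for t in tree.taxon_namespace if t.label in focal]
            mrca = tree.mrca(taxa=taxa)
            clade = {l.taxon.label for l in mrca.leaf_iter()}
            if clade == focal:
                mono += 1
        assert mono >= 95

    def test_high_migration_breaks_monophyly(self):
        mono = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = SimConfig(
                seed=2000 + seed,
                n_individuals=(3, 3),
                migration_rate=0.01,  # ~4Nm >> 1: effectively panmictic
                split_generations=500_000.0,
                ne_focal=5_000.0,
                ne_other=5_000.0,
            )
            tree, meta = simulate_genealogy(cfg)
            focal = {a for a, (_, p) in meta.items() if p == "bamfield"}
            taxa = [t for t in tree.taxon_namespace if t.label in focal]
            clade = {l.taxon.label for l in tree.mrca(taxa=taxa).leaf_iter()}
            mono += clade == focal
        assert mono < 10

    def test_small_tree_shape(self):
        cfg = SimConfig(seed=5, n_individuals=(1, 1))
        tree, meta = simulate_genealogy(cfg)
        tips = list(tree.leaf_node_iter())
        assert len(tips) == 4
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
        assert len(edges) == 6  # rooted binary, 4 tips

    def test_target_length_respected(self):
        cfg = small_config(9, target_tree_length=2.5)
        tree, _ = simulate_genealogy(cfg)
        total = sum(
            e.length for e in tree.preorder_edge_iter() if e.length is not None
        )
        assert total == pytest.approx(2.5, rel=1e-9)


class TestCodonSimulation:
    def test_no_stop_codons_and_truth_classes(self, rng):
        cfg = small_config(11)
        tree, meta = simulate_genealogy(cfg)
        from divsel.codon_selection import label_foreground

        lt = label_foreground(tree, meta, "bamfield")
        seqs, classes = simulate_codon_alignment(lt, cfg, rng)
        assert classes.shape == (cfg.n_codons,)
        from divsel.codon_selection import STOP_CODONS

        for s in seqs.values():
            codons = {s[i : i + 3] for i in range(0, len(s), 3)}
            assert not (codons & STOP_CODONS)

    def test_null_config_has_no_selected_class_effect(self, rng):
        # with omega2 = 1 classes 2a/2b evolve exactly like 0/1
        cfg = small_config(12, omega2=1.0)
        tree, meta = simulate_genealogy(cfg)
        from divsel.codon_selection import label_foreground

        lt = label_foreground(tree, meta, "bamfield")
        seqs, _ = simulate_codon_alignment(lt, cfg, rng)
        assert len(next(iter(seqs.values()))) == 3 * cfg.n_codons

    def test_stationary_frequencies_preserved(self):
        # long alignment on a 2-tip tree: tip codon frequencies stay near
        # the generator's stationary (uniform) distribution
        lt = LabeledTree(["t0", "t1"], [[(0, 0.2, False), (1, 0.2, False)]], "x")
        cfg = SimConfig(seed=3, n_codons=100_000, intron_length=0)
        rng = np.random.default_rng(3)
        seqs, _ = simulate_codon_alignment(lt, cfg, rng)
        s = seqs["t0"]
        counts = np.zeros(N_STATES)
        for i in range(0, len(s), 3):
            counts[CODON_INDEX[s[i : i + 3]]] += 1
        freqs = counts / counts.sum()
        # 5 sigma binomial band around 1/61
        p = 1.0 / N_STATES
        se = np.sqrt(p * (1 - p) / cfg.n_codons)
        assert np.abs(freqs - p).max() < 5 * se


class TestStructuralVariation:
    def test_no_indels_when_rates_off(self):
        cfg = small_config(
            13,
            collagen_probs_focal={4: 1.0},
            collagen_probs_other={4: 1.0},
            tandem_probs_focal={9: 1.0},
            tandem_probs_other={9: 1.0},
            n_coding_point_indels=0,
            n_intron_indels=0,
        )
        ds = simulate_dataset(cfg)
        assert all("-" not in s for s in ds.aln.alleles.values())
        assert ds.truth.coding_indel_types == []
        assert ds.truth.intron_indel_types == []

    def test_planted_indel_types_recovered_exactly(self):
        ds = simulate_dataset(small_config(14))
        catalog = extract_indels(ds.aln)
        got_coding = {(e.start, e.end) for e in catalog.events if e.region == "coding"}
        got_intron = {(e.start, e.end) for e in catalog.events if e.region == "intron"}
        assert got_coding == set(ds.truth.coding_indel_types)
        assert got_intron == set(ds.truth.intron_indel_types)

    def test_copy_numbers_recovered_exactly(self):
        ds = simulate_dataset(small_config(15))
        ann = extract_repeat_copies(ds.aln, ds.domain_spans)
        for allele, domains in ds.truth.copy_numbers.items():
            for domain, n in domains.items():
                assert ann.copy_number[(allele, domain)] == n

    def test_copy_variation_concentrated_in_focal_population(self):
        cfg = SimConfig(seed=16, n_individuals=(12, 12), n_codons=420,
                        intron_length=100, target_tree_length=1.0)
        ds = simulate_dataset(cfg)
        variants = {"bamfield": 0, "sandspit": 0}
        for allele, domains in ds.truth.copy_numbers.items():
            pop = ds.aln.meta[allele][1]
            variants[pop] += domains["collagen"] != 3
        assert variants["bamfield"] > variants["sandspit"]


class TestCloneReads:
    def test_zero_rate_gives_identical_clones(self):
        cfg = small_config(17, clone_error_rate=0.0)
        ds = simulate_dataset(cfg, with_clones=True)
        for cs in ds.clone_sets:
            for cid, seq in cs.clones:
                allele = f"{cs.individual_id}_a{cs.allele_assignment[cid]}"
                assert seq == ds.aln.alleles[allele]

    def test_error_rate_round_trip(self):
        cfg = SimConfig(
            seed=18,
            n_individuals=(5, 5),
            n_codons=700,
            intron_length=300,
            target_tree_length=1.0,
        )
        ds = simulate_dataset(cfg, with_clones=True)
        n_bases = sum(
            sum(c != "-" for c in seq)
            for cs in ds.clone_sets
            for _, seq in cs.clones
        )
        assert n_bases >= 1e5
        rate = pooled_error_rate(ds.clone_sets)
        assert abs(rate - 0.00128) / 0.00128 < 0.2
        # consensus recovers the true alleles nearly perfectly
        from divsel.alleles_qc import build_consensus

        errors = compared = 0
        for cs in ds.clone_sets:
            cons, _ = build_consensus(cs)
            for name, seq in cons.items():
                truth = ds.aln.alleles[name]
                for a, b in zip(seq, truth):
                    compared += 1
                    errors += a != b
        assert errors / compared < 1e-4

    def test_clone_depth_range(self):
        ds = simulate_dataset(small_config(19), with_clones=True)
        for cs in ds.clone_sets:
            assert 6 <= len(cs.clones) <= 10
            assert set(cs.allele_assignment.values()) <= {1, 2}


class TestDatasetContract:
    def test_byte_identical_reproducibility(self):
        d1 = simulate_dataset(small_config(20))
        d2 = simulate_dataset(small_config(20))
        assert fasta_string(d1.aln.alleles) == fasta_string(d2.aln.alleles)
        assert d1.truth.to_json() == d2.truth.to_json()

    def test_different_seeds_differ(self):
        d1 = simulate_dataset(small_config(21))
        d2 = simulate_dataset(small_config(22))
        assert fasta_string(d1.aln.alleles) != fasta_string(d2.aln.alleles)

    def test_dataset_passes_input_validation(self):
        ds = simulate_dataset(small_config(23))
        ds.aln.validate(focal_populations=("bamfield", "sandspit"))

    def test_truth_table_roundtrip(self):
        ds = simulate_dataset(small_config(24))
        back = TruthTable.from_json(ds.truth.to_json())
        assert back == ds.truth

    def test_seed_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            SimConfig(seed=None).validate()


class TestWorkedExampleFixtures:
    def test_fixture_contents_consistent(self):
        fx = worked_example_fixtures()
        table = fx["selected_sites_table"]
        assert len(table) == 11
        sandspit = {r["codon"] for r in table if r["p_sandspit"] > 0.95}
        bamfield = {r["codon"] for r in table if r["p_bamfield"] > 0.95}
        assert len(sandspit) == 4
        assert sandspit & bamfield == {842}
        row842 = next(r for r in table if r["codon"] == 842)
        assert row842["p_sandspit"] == row842["p_bamfield"] == 0.999
        assert fx["indel_density"]["n_coding"] == 22
        assert fx["repeat_copy_numbers"]["collagen"]["mode"] == 3
        assert fx["repeat_copy_numbers"]["tandem"]["mode"] == 8

    def test_fixtures_serialize_losslessly(self):
        fx = worked_example_fixtures()
        assert fixtures_roundtrip(fx) == fx
        assert json.loads(json.dumps(fx)) == fx
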