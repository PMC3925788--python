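"""Generator contracts: determinism, recombination algebra, planted truth."""

import numpy as np
import pytest

from mitomosaic import (
    PlacementError,
    SimulationConfig,
    apply_recombination,
    fragment_to_contigs,
    generate_master_circle,
    plant_gene_tail_fusion,
    simulate_all,
    simulate_pileups,
)
from mitomosaic.core import revcomp


class TestGenerateMasterCircle:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(rng_seed=17)
        g1, t1 = generate_master_circle(cfg)
        g2, t2 = generate_master_circle(cfg)
        assert g1.sequence == g2.sequence
        assert t1.planted_repeats == t2.planted_repeats
        assert t1.genes == t2.genes

    def test_empty_spec_gives_empty_truth(self):
        cfg = SimulationConfig(genome_length=1000, repeat_spec=(), n_genes=0)
        genome, truth = generate_master_circle(cfg)
        assert len(genome) == 1000
        assert truth.planted_repeats == []
        assert truth.genes == []

    def test_planted_copies_match_their_orientation(self):
        cfg = SimulationConfig(
            genome_length=5000,
            repeat_spec=((101, "direct", 1), (80, "inverted", 0)),
            n_genes=2, gene_length_range=(200, 400), rng_seed=3,
        )
        genome, truth = generate_master_circle(cfg)
        s = genome.sequence
        for p in truth.planted_repeats:
            c1 = s[p.start1 - 1 : p.start1 - 1 + p.length]
            c2 = s[p.start2 - 1 : p.start2 - 1 + p.length]
            expected = c1 if p.orientation == "direct" else revcomp(c1)
            assert sum(a != b for a, b in zip(c2, expected)) == p.mismatches

    def test_genes_are_orfs(self):
        from mitomosaic.core import translate

        cfg = SimulationConfig(genome_length=5000, repeat_spec=(), n_genes=4,
                               gene_length_range=(150, 300), rng_seed=1)
        genome, truth = generate_master_circle(cfg)
        for g in truth.genes:
            pep = translate(g.cds(genome))
            assert pep.startswith("M")
            assert pep.endswith("*")
            assert "*" not in pep[:-1]

    def test_infeasible_config_raises_placement_error(self):
        cfg = SimulationConfig(genome_length=2100, repeat_spec=((1000, "direct", 0),),
                               n_genes=5, gene_length_range=(900, 999))
        with pytest.raises(PlacementError):
            generate_master_circle(cfg)


class TestApplyRecombination:
    @pytest.fixture
    def inv_sim(self):
        cfg = SimulationConfig(genome_length=4000, repeat_spec=((60, "inverted", 0),),
                               n_genes=0, rng_seed=8)
        return cfg, *generate_master_circle(cfg)

    def test_inverted_recombination_preserves_length_and_inverts_between(self, inv_sim):
        """Independent string surgery: u R v R' w -> u R rc(v) R' w."""
        _, genome, truth = inv_sim
        rep = truth.planted_repeats[0]
        res = apply_recombination(genome, rep, truth)
        (product,) = res.genomes
        s, t = genome.sequence, product.sequence
        assert len(t) == len(s)
        a, b = rep.start1 - 1, rep.start2 - 1
        L = rep.length
        assert t[: a + L] == s[: a + L]
        assert t[b:] == s[b:]
        assert t[a + L : b] == revcomp(s[a + L : b])

    def test_inverted_recombination_is_an_involution(self, inv_sim):
        _, genome, truth = inv_sim
        rep = truth.planted_repeats[0]
        once = apply_recombination(genome, rep, truth).genomes[0]
        twice = apply_recombination(once, rep, truth).genomes[0]
        assert twice.sequence == genome.sequence

    def test_junction_footprints_recorded(self, inv_sim):
        _, genome, truth = inv_sim
        rep = truth.planted_repeats[0]
        res = apply_recombination(genome, rep, truth)
        assert len(res.truth.planted_junctions) == 2
        for positions, footprint in res.truth.planted_junctions:
            assert footprint == rep.length
            assert all(1 <= p <= len(genome) for p in positions)

    def test_direct_recombination_splits_circle_into_two(self):
        cfg = SimulationConfig(genome_length=3000, repeat_spec=((40, "direct", 0),),
                               n_genes=0, rng_seed=2)
        genome, truth = generate_master_circle(cfg)
        rep = truth.planted_repeats[0]
        res = apply_recombination(genome, rep, truth)
        c1, c2 = res.genomes
        assert len(c1) + len(c2) == len(genome)
        # lengths follow from the copy positions by plain arithmetic
        assert len(c1) == rep.start2 - rep.start1
        # each product keeps one full repeat copy
        unit = genome.sequence[rep.start1 - 1 : rep.start1 - 1 + rep.length]
        assert unit in c1.sequence + c1.sequence
        assert unit in c2.sequence + c2.sequence

    def test_overlapping_copies_rejected(self):
        from mitomosaic import CircularGenome, RepeatPair, TruthSet

        genome = CircularGenome(id="g", sequence="ACGT" * 100)
        rep = RepeatPair(start1=10, start2=30, length=40, orientation="direct")
        with pytest.raises(ValueError, match="overlap"):
            apply_recombination(genome, rep, TruthSet())

    def test_absent_repeat_rejected(self):
        from mitomosaic import CircularGenome, RepeatPair, TruthSet

        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        genome = CircularGenome(id="g", sequence=seq)
        rep = RepeatPair(start1=10, start2=200, length=50, orientation="direct")
        with pytest.raises(ValueError, match="not present"):
            apply_recombination(genome, rep, TruthSet())


class TestFragmentToContigs:
    def test_contigs_tile_the_circle(self, small_sim):
        cfg, genome, truth = small_sim
        contigs, links, depths, ftruth = fragment_to_contigs(
            genome, cfg, rng=np.random.default_rng(1), truth=truth)
        seqs = dict(contigs)
        mito = {cid: o for cid, (o, cls) in ftruth.contig_origins.items() if cls == "mito"}
        total = sum(len(seqs[cid]) for cid in mito)
        assert total == len(genome)
        # links form a single cycle over the mito contigs
        assert len(links) == len(mito)

    def test_no_decoys_when_fraction_zero(self, small_sim):
        cfg, genome, truth = small_sim
        cfg = SimulationConfig(**{**cfg.__dict__, "nuclear_copy_fraction": 0.0})
        contigs, _, _, ftruth = fragment_to_contigs(genome, cfg,
                                                    rng=np.random.default_rng(2))
        assert all(cls == "mito" for _, cls in ftruth.contig_origins.values())

    def test_decoy_depths_below_ratio_of_true_median(self, small_sim):
        cfg, genome, truth = small_sim
        contigs, _, depths, ftruth = fragment_to_contigs(
            genome, cfg, rng=np.random.default_rng(3), truth=truth)
        true_depths = sorted(
            depths[cid] for cid, (_, cls) in ftruth.contig_origins.items()
            if cls == "mito")
        med = true_depths[len(true_depths) // 2]
        decoys = [depths[cid] for cid, (_, cls) in ftruth.contig_origins.items()
                  if cls == "nuclear_copy"]
        assert decoys  # default fraction plants some
        for d in decoys:
            assert d / med < cfg.nuclear_depth_ratio + 0.01


class TestSimulatePileups:
    def test_full_editing_no_error_gives_pure_T(self):
        cfg = SimulationConfig(genome_length=3000, repeat_spec=(), n_genes=3,
                               gene_length_range=(200, 400), editing_sites=10,
                               editing_fraction=1.0, n_rna_samples=2, rng_seed=6)
        genome, truth = generate_master_circle(cfg)
        gdna, rna, truth = simulate_pileups(genome, truth.genes, cfg, truth=truth)
        for site in truth.planted_editing:
            i = site["position"] - 1
            gene = next(g for g in truth.genes if g.gene_id == site["gene_id"])
            edited_base = "T" if gene.strand == "+" else "A"
            ref_base = "C" if gene.strand == "+" else "G"
            for df in rna.values():
                assert df.loc[i, edited_base] > 0
                assert df.loc[i, ref_base] == 0

    def test_codon_consequence_truth_for_stop_creation(self):
        """C at codon position 1 of CAA edits to UAA: Q -> stop."""
        cfg = SimulationConfig(genome_length=3000, repeat_spec=(), n_genes=3,
                               gene_length_range=(300, 600), editing_sites=60,
                               rng_seed=11)
        genome, truth = generate_master_circle(cfg)
        _, _, truth = simulate_pileups(genome, truth.genes, cfg, truth=truth)
        for site in truth.planted_editing:
            if site["ref_aa"] == "Q" and site["codon_pos"] == 1:
                assert site["edited_aa"] == "*"

    def test_sample_specific_omission_recorded(self):
        cfg = SimulationConfig(genome_length=3000, repeat_spec=(), n_genes=3,
                               gene_length_range=(200, 400), editing_sites=10,
                               n_rna_samples=3, differential_omissions={"s2": 2},
                               rng_seed=4)
        genome, truth = generate_master_circle(cfg)
        _, _, truth = simulate_pileups(genome, truth.genes, cfg, truth=truth)
        omitted = [s for s in truth.planted_editing if "s2" not in s["samples"]]
        assert len(omitted) == 2

    def test_too_many_sites_requested_raises(self):
        cfg = SimulationConfig(genome_length=2000, repeat_spec=(), n_genes=1,
                               gene_length_range=(150, 200), editing_sites=500,
                               rng_seed=0)
        genome, truth = generate_master_circle(cfg)
        with pytest.raises(ValueError, match="editing sites"):
            simulate_pileups(genome, truth.genes, cfg)


class TestFusionScenario:
    def test_fused_orf_design(self):
        genome, truth = plant_gene_tail_fusion(seed=1)
        fus = truth.planted_fusion
        assert fus["retained_tail_aa"] == 33
        assert fus["fused_orf_aa"] == 51
        rep = truth.planted_repeats[0]
        assert rep.orientation == "inverted"
        # the junction sits at the end of the first repeat copy
        assert fus["junction"] == rep.start1 + rep.length - 1


def test_simulate_all_is_deterministic():
    cfg = SimulationConfig(genome_length=4000, n_genes=3,
                           gene_length_range=(200, 400), editing_sites=8,
                           repeat_spec=((80, "inverted", 0),), rng_seed=23)
    r1 = simulate_all(cfg)
    r2 = simulate_all(cfg)
    assert r1["genome"].sequence == r2["genome"].sequence
    assert r1["contigs"] == r2["contigs"]
    assert r1["depths"] == r2["depths"]
    assert r1["genomic_pileup"].equals(r2["genomic_pileup"])
    for s in r1["rna_pileups"]:
        assert r1["rna_pileups"][s].equals(r2["rna_pileups"][s])
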