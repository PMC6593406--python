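import numpy as np
import pytest

from abscreen._codon import revcomp
from abscreen.panels import PanelMember
from abscreen.search import six_frame_translate
from abscreen.simulate import (Placement, back_translate,
                               build_screen_scenario, generate_reads,
                               implant_genes, make_demo_panels,
                               simulate_community, write_fastq)
from abscreen.search import ReadLibrary


class TestSimulateCommunity:
    def test_realized_gc_tracks_targets(self):
        com = simulate_community([50_000, 50_000], [0.40, 0.60], [0.5, 0.5],
                                 seed=11)
        for genome, target in zip(com.genomes, (0.40, 0.60)):
            gc = sum(genome.sequence.count(b) for b in "GC") / 50_000
            assert abs(gc - target) < 0.02

    def test_same_seed_reproduces_sequences(self):
        a = simulate_community([5000], [0.5], [1.0], seed=3)
        b = simulate_community([5000], [0.5], [1.0], seed=3)
        assert a.genomes[0].sequence == b.genomes[0].sequence

    def test_zero_genomes_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_community([], [], [], seed=0)

    def test_non_normalizable_abundances_are_an_error(self):
        with pytest.raises(ValueError, match="abundances"):
            simulate_community([1000], [0.5], [-1.0], seed=0)

    def test_abundances_are_normalised(self):
        com = simulate_community([1000, 1000], [0.5, 0.5], [2.0, 6.0], seed=0)
        assert com.abundances().sum() == pytest.approx(1.0)
        assert com.genomes[1].relative_abundance == pytest.approx(0.75)


PEPTIDE = "MKVADEWQRNSTLYHGFCIP" * 5  # 100 aa


class TestImplantGenes:
    def members(self):
        return [PanelMember("pep1", PEPTIDE)]

    def test_contaminant_only_placement_leaves_focal_clean(self):
        com = simulate_community([5000, 5000], [0.5, 0.5], [0.9, 0.1], seed=1,
                                 genome_ids=["focal", "contam"])
        truth = implant_genes(com, self.members(),
                              [Placement("pep1", "contam", 100)])
        assert truth.copies_in("pep1", "focal") == 0
        assert truth.copies_in("pep1", "contam") == 1

    def test_two_placements_give_two_copies(self):
        com = simulate_community([5000], [0.5], [1.0], seed=1,
                                 genome_ids=["g"])
        truth = implant_genes(com, self.members(),
                              [Placement("pep1", "g", 100),
                               Placement("pep1", "g", 2000)])
        assert truth.copies_in("pep1", "g") == 2

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_implanted_locus_translates_back_to_the_peptide(self, strand):
        com = simulate_community([5000], [0.5], [1.0], seed=2,
                                 genome_ids=["g"])
        implant_genes(com, self.members(),
                      [Placement("pep1", "g", 99, strand)])
        locus = com.genomes[0].sequence[99 : 99 + 3 * len(PEPTIDE)]
        frames = six_frame_translate(locus)
        frame = 1 if strand == "+" else -1
        assert frames[frame] == PEPTIDE

    def test_implant_length_is_three_times_peptide_length(self):
        com = simulate_community([5000], [0.5], [1.0], seed=2,
                                 genome_ids=["g"])
        truth = implant_genes(com, self.members(),
                              [Placement("pep1", "g", 0)])
        assert truth.implants[0].length_nt == 3 * len(PEPTIDE)

    def test_overlapping_placements_are_rejected(self):
        com = simulate_community([5000], [0.5], [1.0], seed=1,
                                 genome_ids=["g"])
        with pytest.raises(ValueError, match="overlap"):
            implant_genes(com, self.members(),
                          [Placement("pep1", "g", 100),
                           Placement("pep1", "g", 150)])

    def test_out_of_bounds_placement_is_rejected(self):
        com = simulate_community([200], [0.5], [1.0], seed=1,
                                 genome_ids=["g"])
        with pytest.raises(ValueError, match="bounds"):
            implant_genes(com, self.members(), [Placement("pep1", "g", 100)])

    def test_back_translation_randomises_codons_but_not_peptide(self):
        rng = np.random.default_rng(0)
        a = back_translate(PEPTIDE, rng)
        b = back_translate(PEPTIDE, rng)
        assert a != b  # synonymous wobble
        assert six_frame_translate(a)[1] == six_frame_translate(b)[1] == PEPTIDE


class TestGenerateReads:
    def community(self, seed=5):
        return simulate_community([20_000, 20_000], [0.5, 0.5], [0.9, 0.1],
                                  seed=seed, genome_ids=["a", "b"])

    def test_error_free_reads_are_exact_substrings(self):
        com = self.community()
        lib, truth = generate_reads(com, n_reads=200, read_length=80, seed=1)
        seqs = {g.genome_id: g.sequence for g in com.genomes}
        for rec, row in zip(lib, truth.itertuples()):
            source = seqs[row.genome_id][row.start : row.start + 80]
            expected = source if row.strand == "+" else revcomp(source)
            assert rec.sequence == expected

    def test_read_counts_split_by_abundance_within_3_sigma(self):
        com = self.community()
        lib, truth = generate_reads(com, n_reads=100_000, read_length=80,
                                    seed=2)
        n_a = (truth["genome_id"] == "a").sum()
        sigma = np.sqrt(100_000 * 0.9 * 0.1)
        assert abs(n_a - 90_000) < 3 * sigma

    def test_errors_change_about_the_requested_fraction_of_bases(self):
        com = self.community()
        clean, truth = generate_reads(com, 500, read_length=100, seed=3)
        noisy, _ = generate_reads(com, 500, read_length=100, error_rate=0.05,
                                  seed=3)
        diffs = sum(
            sum(a != b for a, b in zip(x.sequence, y.sequence))
            for x, y in zip(clean, noisy)
        )
        rate = diffs / (500 * 100)
        assert 0.03 < rate < 0.07

    def test_paired_layout_produces_inward_mates(self):
        com = self.community()
        lib, truth = generate_reads(com, n_reads=20, read_length=50,
                                    paired=True, insert_size=200, seed=4)
        assert lib.layout == "paired"
        assert lib.total_reads == 20
        seqs = {g.genome_id: g.sequence for g in com.genomes}
        row1, row2 = truth.iloc[0], truth.iloc[1]
        assert row1.read_id.endswith("/1") and row2.read_id.endswith("/2")
        frag = seqs[row1.genome_id][row1.start : row1.start + 200]
        if row1.strand == "-":
            frag = revcomp(frag)
        reads = {r.read_id: r.sequence for r in lib}
        assert reads[row1.read_id] == frag[:50]
        assert reads[row2.read_id] == revcomp(frag[-50:])

    def test_nonpositive_read_count_is_an_error(self):
        with pytest.raises(ValueError):
            generate_reads(self.community(), 0)

    def test_read_longer_than_genome_is_an_error(self):
        com = simulate_community([50], [0.5], [1.0], seed=0)
        with pytest.raises(ValueError, match="read_length"):
            generate_reads(com, 10, read_length=100)


def test_fastq_round_trip(tmp_path):
    com = simulate_community([2000], [0.5], [1.0], seed=8, genome_ids=["g"])
    lib, _ = generate_reads(com, 25, read_length=60, seed=9)
    path = tmp_path / "reads.fastq"
    write_fastq(lib, path)
    reloaded = ReadLibrary.from_fastq(path)
    assert [r.sequence for r in reloaded] == [r.sequence for r in lib]
    assert [r.read_id for r in reloaded] == [r.read_id for r in lib]


class TestScenarios:
    def test_expected_relative_coverage_of_focal_single_copy_is_one(self):
        sc = build_screen_scenario("target_in_focal", seed=0, n_reads=100)
        rel = sc.truth.expected_relative_coverage(sc.community, sc.panels)
        assert rel["RuBisCO_proxy"] == pytest.approx(1.0)
        assert rel["AcsB_proxy"] == 0.0

    def test_contaminant_scenario_predicts_subunity_coverage(self):
        sc = build_screen_scenario("target_in_contaminant", seed=0,
                                   n_reads=100)
        rel = sc.truth.expected_relative_coverage(sc.community, sc.panels)
        assert 1 / 50 < rel["RuBisCO_proxy"] < 0.5

    def test_demo_panels_are_valid(self):
        from abscreen.panels import validate_panels
        assert validate_panels(make_demo_panels(seed=1)) == []

    def test_unknown_scenario_kind_raises(self):
        with pytest.raises(ValueError):
            build_screen_scenario("nope", seed=0)

    def test_scenario_config_round_trip(self, tmp_path):
        from abscreen.simulate import scenario_from_config
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text("kind: target_in_focal\nseed: 4\nn_reads: 100\n"
                       "genome_length: 20000\n")
        sc = scenario_from_config(cfg)
        assert sc.library.total_reads == 100
        assert sc.truth.copies_in("RuBisCO_proxy_1", "focal") == 1

    def test_scenario_config_requires_a_seed(self, tmp_path):
        from abscreen.simulate import scenario_from_config
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text("kind: targets_absent\n")
        with pytest.raises(ValueError, match="seed"):
            scenario_from_config(cfg)
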