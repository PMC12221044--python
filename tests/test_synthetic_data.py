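"""Generators: genome model, meiosis, panels, drift, depth, COPAS, CHEF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdnapanel import chef_sizer, competition
from rdnapanel import synthetic_data as sd
from rdnapanel.stability import DriftParams


class TestGenomeModel:
    def test_landmark_constants(self, genome):
        chrom, start, units, unit_len = genome.rdna_locus
        assert unit_len == 7200
        assert chrom == "I"
        assert start + units * unit_len == genome.chrom_lengths["I"]
        assert genome.incompatibility_locus == ("I", 2_300_000)
        tg_chrom, tg_pos = genome.transgene_locus
        assert tg_chrom == "I" and tg_pos > 13_500_000
        assert all(len(genome.markers[c]) >= 500 for c in genome.chromosomes)
        assert sum(genome.chrom_lengths.values()) == pytest.approx(1e8, rel=0.01)

    def test_invalid_models_rejected(self, genome):
        with pytest.raises(ValueError, match="terminal"):
            sd.GenomeModel(
                chrom_lengths=genome.chrom_lengths,
                markers=genome.markers,
                marker_cm=genome.marker_cm,
                rdna_locus=("I", 1_000_000, 1, 7200),
                incompatibility_locus=genome.incompatibility_locus,
                transgene_locus=genome.transgene_locus,
            )
        bad_markers = dict(genome.markers)
        bad_markers["II"] = np.array([10, 10, 20])
        with pytest.raises(ValueError, match="strictly increasing"):
            sd.GenomeModel(
                chrom_lengths=genome.chrom_lengths,
                markers=bad_markers,
                marker_cm={**genome.marker_cm, "II": np.array([0.0, 1.0, 2.0])},
                rdna_locus=genome.rdna_locus,
                incompatibility_locus=genome.incompatibility_locus,
                transgene_locus=genome.transgene_locus,
            )


def _f1(genome, copies=(417, 130)):
    return sd.LineState.make(
        (sd.Haplotype.uniform(genome, sd.HIGH), sd.Haplotype.uniform(genome, sd.LOW)),
        copies,
        sd.HIGH,
        genome,
    )


class TestMeiosis:
    def test_homozygous_parent_gamete_identity(self, small_genome, rng):
        parent = sd.LineState.make(
            (sd.Haplotype.uniform(small_genome, sd.LOW),
             sd.Haplotype.uniform(small_genome, sd.LOW)),
            (130, 130), sd.HIGH, small_genome,
        )
        hap, copies = sd.simulate_gamete(parent, small_genome, rng)
        assert copies == 130
        for chrom, L in small_genome.chrom_lengths.items():
            assert hap.segments[chrom] == [(L, sd.LOW)]

    def test_no_recombination_yields_parental_haplotype(self, rng):
        # zero map length and no obligate crossover: gametes are unrecombined
        genome = sd.build_default_genome(markers_per_chrom=50, map_length_cm=0.0)
        parent = _f1(genome)
        picks = []
        for _ in range(400):
            hap, copies = sd.simulate_gamete(
                parent, genome, rng, obligate_crossover=False
            )
            labels = {segs[0][1] for segs in hap.segments.values()}
            assert len({len(s) for s in hap.segments.values()}) == 1
            assert all(len(s) == 1 for s in hap.segments.values())
            picks.append(copies)
        frac_high = np.mean([c == 417 for c in picks])
        assert abs(frac_high - 0.5) < 3 * np.sqrt(0.25 / 400) + 0.02

    def test_rdna_transmission_is_mendelian(self, small_genome, rng):
        parent = _f1(small_genome)
        n = 10_000
        high = sum(
            sd.simulate_gamete(parent, small_genome, rng)[1] == 417
            for _ in range(n)
        )
        assert abs(high / n - 0.5) < 0.015  # 3 binomial SE

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_haplotype_tiling_invariant_after_meiosis(self, seed):
        genome = sd.build_default_genome(markers_per_chrom=20)
        rng = np.random.default_rng(seed)
        line = _f1(genome)
        for _ in range(3):
            line = sd.self_offspring(line, genome, rng)
        for hap in line.haplotypes:
            hap.validate(genome)


class TestPanel:
    def test_panel_split_and_mito(self, small_genome):
        cfg = sd.PanelConfig(n_lines=120, f2_split=0.5, selfing_generations=3, seed=7)
        panel = sd.simulate_ril_panel(cfg, small_genome)
        doses = [line.transgene_genotype for line in panel]
        assert doses.count(2) == 60 and doses.count(0) == 60
        assert all(line.mito == sd.HIGH for line in panel)

    def test_heterozygosity_halves_per_selfing_generation(self, small_genome, rng):
        g = 2
        hets = []
        for _ in range(300):
            line = _f1(small_genome)
            for _ in range(g):
                line = sd.self_offspring(line, small_genome, rng)
            hets.append(sd.heterozygosity(line, small_genome))
        assert abs(np.mean(hets) - 0.5**g) < 0.04

    def test_incompatibility_selection_depletes_high_allele(self, small_genome):
        # direction of distortion at the toxin-antitoxin locus: LOW favored
        chrom, pos = small_genome.incompatibility_locus
        freqs = []
        for rep in range(20):
            cfg = sd.PanelConfig(n_lines=40, selfing_generations=4, seed=1000 + rep)
            panel = sd.simulate_ril_panel(cfg, small_genome)
            low = sum(
                line.genotype_at(chrom, pos).count(sd.LOW) for line in panel
            ) / (2 * len(panel))
            freqs.append(low)
        assert np.mean(np.array(freqs) > 0.5) > 0.9  # sign test: nearly all panels

    def test_transgene_rdna_cosegregation_at_zero_distance(self):
        genome = sd.build_default_genome(
            markers_per_chrom=50, transgene_pos=15_065_233  # adjacent to the array
        )
        cfg = sd.PanelConfig(n_lines=30, selfing_generations=4, seed=11)
        panel = sd.simulate_ril_panel(cfg, genome)
        for line in panel:
            allele = line.rdna_allele_label(genome)
            if line.transgene_genotype == 2:
                assert allele == sd.LOW
            elif line.transgene_genotype == 0:
                assert allele == sd.HIGH

    def test_sampling_exhausted(self, small_genome):
        cfg = sd.PanelConfig(
            n_lines=10, f2_split=1.0, selfing_generations=0, seed=3,
            max_draws_per_line=1,
        )
        with pytest.raises(sd.SamplingExhaustedError):
            sd.simulate_ril_panel(cfg, small_genome)

    def test_bit_reproducibility(self, small_genome):
        cfg = sd.PanelConfig(n_lines=12, selfing_generations=3, seed=42)
        a = sd.simulate_ril_panel(cfg, small_genome)
        b = sd.simulate_ril_panel(cfg, small_genome)
        for la, lb in zip(a, b):
            assert la.rdna_copies == lb.rdna_copies
            assert la.transgene_genotype == lb.transgene_genotype
            assert la.haplotypes[0].segments == lb.haplotypes[0].segments


class TestDrift:
    def test_zero_rates_identity(self, rng):
        p = DriftParams(loss_rate=0.0, gain_rate=0.0, generations=20)
        assert sd.drift_copy_number(130, p, rng) == 130

    def test_floor_at_zero(self, rng):
        p = DriftParams(loss_rate=50.0, generations=20)
        assert sd.drift_copy_number(1, p, rng) == 0

    def test_mean_loss_matches_poisson_expectation(self, rng):
        p = DriftParams(loss_rate=1 / 120, divisions_per_generation=15, generations=20)
        losses = [417 - sd.drift_copy_number(417, p, rng) for _ in range(10_000)]
        assert abs(np.mean(losses) - 2.5) < 0.05

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            DriftParams(loss_rate=-0.1)


def _homozygous_line(genome, copies, label=sd.LOW):
    hap = sd.Haplotype.uniform(genome, label)
    return sd.LineState.make((hap, hap), (copies, copies), sd.HIGH, genome)


class TestDepthProfile:
    def test_zero_depth_all_zero(self, genome, rng):
        line = _homozygous_line(genome, 130)
        prof = sd.simulate_depth_profile(line, genome, 0.0, rng=rng, chromosomes=["I"])
        assert (prof.bins["count"] == 0).all()

    def test_rdna_rate_scales_with_copies(self, genome, rng):
        line = _homozygous_line(genome, 130)
        prof = sd.simulate_depth_profile(line, genome, 30.0, rng=rng, chromosomes=["I"])
        rd = prof.bins[prof.bins.region_class == "rdna"]
        total = rd["count"].sum()
        span = (rd["end"] - rd["start"]).sum()
        expected = 30.0 * 130 * span / prof.bin_size  # u = 1
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_copies_equal_reference_is_identity(self, genome, rng):
        line = _homozygous_line(genome, 1)  # haploid copies == reference unit count
        prof = sd.simulate_depth_profile(line, genome, 200.0, rng=rng, chromosomes=["I"])
        rd = prof.bins[prof.bins.region_class == "rdna"]
        sc = prof.bins[prof.bins.region_class == "single_copy"]
        rate_rd = rd["count"].sum() / (rd["end"] - rd["start"]).sum()
        rate_sc = sc["count"].sum() / (sc["end"] - sc["start"]).sum()
        assert rate_rd == pytest.approx(rate_sc, rel=0.1)

    def test_blacklist_flagging(self, genome, rng):
        line = _homozygous_line(genome, 130)
        prof = sd.simulate_depth_profile(
            line, genome, 5.0, blacklist_fraction=0.1, rng=rng, chromosomes=["II"]
        )
        frac = (prof.bins.region_class == "blacklist").mean()
        assert 0.08 < frac < 0.12

    def test_invalid_bin_size(self, genome, rng):
        line = _homozygous_line(genome, 130)
        with pytest.raises(ValueError):
            sd.simulate_depth_profile(line, genome, 30.0, bin_size=0, rng=rng)


class TestCopas:
    def test_pure_population_all_above_gate(self, rng):
        params = sd.CopasFluorParams(ambiguous_fraction=0.0)
        ev = sd.simulate_copas_run(1.0, 2000, params, rng)
        assert (ev["green_peak_height"] > 50_000).all()

    def test_gated_proportion_recovers_truth(self, rng):
        ev = sd.simulate_copas_run(0.5, 10_000, rng=rng)
        *_, prop = competition.gate_copas(ev)
        assert abs(prop - 0.5) < 0.015

    def test_few_ambiguous_events_at_defaults(self, rng):
        ev = sd.simulate_copas_run(0.5, 10_000, rng=rng)
        _, _, n_amb, _ = competition.gate_copas(ev)
        assert n_amb <= 30  # <= 3 per 1000 on average

    def test_invalid_proportion(self, rng):
        with pytest.raises(ValueError):
            sd.simulate_copas_run(1.5, 100, rng=rng)


class TestChefRun:
    def test_ladder_node_identity_zero_noise(self, rng):
        ladder = chef_sizer.ChefLadder.from_log_linear([720_000, 849_600, 1_008_000])
        run = sd.simulate_chef_run([118], ladder, 0.0, rng, mode="interp")
        idx = list(ladder.sizes_bp).index(849_600)
        assert run["distance_mm"].iloc[0] == pytest.approx(
            ladder.distances_mm[idx], abs=1e-9
        )

    def test_near_comigration_of_adjacent_copy_numbers(self, rng):
        ladder = chef_sizer.ChefLadder.from_log_linear(chef_sizer.YEAST_PFG_SIZES_BP)
        run = sd.simulate_chef_run([118, 119], ladder, 0.0, rng)
        step = np.min(np.abs(np.diff(np.sort(ladder.distances_mm))))
        gap = abs(run["distance_mm"].iloc[0] - run["distance_mm"].iloc[1])
        assert gap < step

    def test_out_of_range_flagged(self, rng):
        ladder = chef_sizer.ChefLadder.from_log_linear(chef_sizer.YEAST_PFG_SIZES_BP)
        run = sd.simulate_chef_run([10, 418], ladder, 0.0, rng)
        assert run["out_of_range"].tolist() == [True, True]
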