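import numpy as np
import pytest

from bacmap.simulate import (LibrarySpec, SimulationConfig, fingerprint_clone,
                             generate_dataset, inject_artifacts,
                             polymorphic_prob, sample_markers, simulate_genome)

from conftest import small_config


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            small_config(het_fraction=1.5)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            small_config(band_window_bp=(650.0, 100.0))

    def test_genome_too_short(self):
        with pytest.raises(ValueError):
            small_config(genome_length_bp=1000, mean_fragment_bp=3477.0)

    def test_bad_digestion_mode(self):
        with pytest.raises(ValueError):
            LibrarySpec("X", "nebulised", 100.0, 10.0, 10)


class TestSimulateGenome:
    def test_homozygous_limit_haplotypes_identical(self):
        genome = simulate_genome(small_config(het_fraction=0.0, n_markers=0))
        assert all(not fr.specific for fr in genome.fragments)
        assert genome.n_fragments(0) == genome.n_fragments(1) == len(genome.fragments)

    def test_deterministic(self):
        cfg = small_config()
        g1, g2 = simulate_genome(cfg), simulate_genome(cfg)
        assert [
            (f.chrom, f.start, f.length, f.mobility_bp, f.hap, f.tag)
            for f in g1.fragments
        ] == [
            (f.chrom, f.start, f.length, f.mobility_bp, f.hap, f.tag)
            for f in g2.fragments
        ]

    def test_fragment_count_matches_mean(self):
        cfg = small_config(genome_length_bp=10_000_000, het_fraction=0.0, n_markers=0)
        genome = simulate_genome(cfg)
        expected = 10_000_000 / 3477
        assert genome.n_fragments(0) == pytest.approx(expected, rel=0.05)

    def test_specific_fraction_near_het_fraction(self):
        # ~10^4 fragments; specific fraction within a generous 99% interval
        cfg = small_config(
            genome_length_bp=26_000_000, het_fraction=0.54, n_markers=0
        )
        genome = simulate_genome(cfg)
        assert len(genome.fragments) > 8000
        frac = genome.tag_heterozygosity()
        assert frac == pytest.approx(0.54, abs=0.02)

    def test_polymorphic_prob_identity(self):
        for h in (0.0, 0.3, 0.54, 0.8):
            p = polymorphic_prob(h)
            assert 2 * p / (1 + p) == pytest.approx(h)

    def test_lengths_right_skewed(self):
        from scipy.stats import skew

        genome = simulate_genome(small_config(genome_length_bp=10_000_000))
        lengths = [f.length for f in genome.fragments if not f.specific]
        assert skew(lengths) > 0

    def test_fragments_tile_without_overlap(self):
        genome = simulate_genome(small_config())
        for chrom in range(genome.config.n_chromosomes):
            pos = 0
            seen = set()
            for fr in genome._by_chrom[chrom]:
                if fr.start in seen:  # allelic pair shares the position
                    continue
                seen.add(fr.start)
                assert fr.start == pos
                pos += fr.length
            assert pos == genome.chrom_lengths[chrom]


class TestBACLibrary:
    def test_zero_clones(self):
        ds = generate_dataset(small_config(
            clone_libraries=[LibrarySpec("LA", "sheared", 100.0, 10.0, 0)],
            n_markers=0,
        ))
        assert ds.clones == [] and ds.layout == {}

    def test_coverage_identity_exact(self, tiny_dataset):
        total = sum(c.length for c in tiny_dataset.clones)
        assert tiny_dataset.coverage_ge() == total / tiny_dataset.config.genome_length_bp

    def test_coverage_near_requested(self):
        # 770 clones of ~130 kb over a 10 Mb genome is ~10 genome equivalents
        cfg = small_config(
            genome_length_bp=10_000_000,
            clone_libraries=[LibrarySpec("LA", "partial_digest", 130.0, 10.0, 770)],
            n_markers=0,
        )
        ds = generate_dataset(cfg)
        assert ds.coverage_ge() == pytest.approx(10.0, rel=0.05)

    def test_plate_layout_full_plate(self):
        cfg = small_config(
            genome_length_bp=4_000_000,
            clone_libraries=[LibrarySpec("LA", "sheared", 100.0, 5.0, 385)],
            n_markers=0,
        )
        ds = generate_dataset(cfg)
        plates = [c.plate for c in ds.clones]
        assert plates.count(1) == 384 and plates.count(2) == 1
        assert ds.clones[0].well == "A01"
        assert ds.clones[23].well == "A24"
        assert ds.clones[24].well == "B01"
        assert ds.clones[383].well == "P24"
        assert ds.clones[384].well == "A01"

    def test_partial_digest_ends_on_boundaries(self, tiny_dataset):
        genome = tiny_dataset.genome
        starts = {
            chrom: {fr.start for fr in genome._by_chrom[chrom]}
            | {genome.chrom_lengths[chrom]}
            for chrom in range(genome.config.n_chromosomes)
        }
        for clone in tiny_dataset.clones:
            assert clone.start in starts[clone.chrom]
            assert clone.end in starts[clone.chrom]

    def test_truth_unique(self, tiny_dataset):
        ids = [c.clone_id for c in tiny_dataset.clones]
        assert len(ids) == len(set(ids))


class TestFingerprintClone:
    def test_no_contained_fragment_empty(self):
        cfg = small_config(n_markers=0)
        genome = simulate_genome(cfg)
        from bacmap.simulate import Clone

        fr = genome._by_chrom[0][5]
        clone = Clone("c", "LA", 0, 0, fr.start + 1, fr.start + 2, 1, "A01")
        fp, tags = fingerprint_clone(clone, genome, cfg)
        assert fp.bands == [] and tags == set()

    def test_zero_noise_identical_intervals(self):
        cfg = small_config(sizing_noise_sd_bp=0.0, n_markers=0)
        genome = simulate_genome(cfg)
        from bacmap.simulate import Clone

        a = Clone("a", "LA", 0, 0, 10_000, 150_000, 1, "A01")
        b = Clone("b", "LA", 0, 0, 10_000, 150_000, 1, "A02")
        fa, ta = fingerprint_clone(a, genome, cfg)
        fb, tb = fingerprint_clone(b, genome, cfg)
        assert fa.bands == fb.bands and ta == tb

    def test_expected_band_count(self, tiny_dataset):
        # 130 kb clone over 3477 bp spacing carries about 37 fragments
        counts = [
            tiny_dataset.clean_fingerprints[c.clone_id].n_bands
            for c in tiny_dataset.clones
        ]
        assert np.mean(counts) == pytest.approx(130_000 / 3477, rel=0.15)

    def test_repetitive_fragments_drop_tags(self):
        cfg = small_config(repeat_fragment_fraction=1.0, n_markers=0)
        ds = generate_dataset(cfg)
        assert all(len(t) == 0 for t in ds.tag_sets.values())


class TestInjectArtifacts:
    def test_zero_rates_identity(self, tiny_dataset):
        fps, flags = inject_artifacts(
            tiny_dataset.clean_fingerprints,
            tiny_dataset.layout,
            small_config(contamination=(0.0, 0.0, 0.0)),
        )
        assert flags == {}
        assert all(
            fps[c].bands == tiny_dataset.clean_fingerprints[c].bands for c in fps
        )

    def test_chloroplast_rate(self):
        cfg = small_config(
            genome_length_bp=4_000_000,
            clone_libraries=[LibrarySpec("LA", "sheared", 100.0, 5.0, 1000)],
            contamination=(0.038, 0.0, 0.0),
            n_markers=0,
        )
        ds = generate_dataset(cfg)
        n_chl = sum(1 for f in ds.contamination_flags.values() if f == "chloroplast")
        # binomial(1000, 0.038): 99.9% of draws fall well inside 20..60
        assert 20 <= n_chl <= 60

    def test_neighbour_mix_is_union(self):
        cfg = small_config(contamination=(0.0, 0.0, 0.3))
        ds = generate_dataset(cfg)
        mixed = [c for c, f in ds.contamination_flags.items() if f == "contaminated"]
        assert mixed
        for cid in mixed:
            own = set(ds.clean_fingerprints[cid].bands)
            assert own <= set(ds.fingerprints[cid].bands)


class TestSampleMarkers:
    def test_homozygous_genome_errors(self):
        cfg = small_config(het_fraction=0.0, n_markers=5)
        genome = simulate_genome(cfg)
        with pytest.raises(ValueError):
            sample_markers(genome, cfg)

    def test_markers_unique_with_phases(self):
        cfg = small_config(n_markers=100)
        genome = simulate_genome(cfg)
        markers, truth = sample_markers(genome, cfg)
        assert len(markers) == 100
        assert len({m.marker_id for m in markers}) == 100
        assert len({truth[m.marker_id].tag for m in markers}) == 100
        assert set(m.phase for m in markers) <= {0, 1}
        for m in markers:
            lo, hi = m.capillary_interval
            assert lo < m.capillary_avg_bp < hi

    def test_expected_copies_at_ten_ge(self):
        from bacmap.anchoring import expected_marker_copies

        assert expected_marker_copies(10.0) == 5.0


class TestDatasetIO:
    def test_write_dataset(self, tiny_dataset, tmp_path):
        from bacmap.simulate import write_dataset

        write_dataset(tiny_dataset, tmp_path)
        for name in ("fingerprints.bands", "wgp_tags.tsv", "markers.tsv",
                     "layout.tsv", "truth_clones.tsv"):
            assert (tmp_path / name).exists()

    def test_config_round_trip(self, tmp_path):
        import yaml

        raw = {
            "genome_length_bp": 2_000_000,
            "n_chromosomes": 3,
            "het_fraction": 0.6,
            "clone_libraries": [
                {"name": "LA", "digestion_mode": "sheared",
                 "clone_size_mean_kb": 90.0, "clone_size_sd_kb": 10.0,
                 "n_clones": 100}
            ],
            "contamination": [0.01, 0.02, 0.03],
            "rng_seed": 42,
        }
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(raw))
        from bacmap.simulate import load_config

        cfg = load_config(path)
        assert cfg.n_chromosomes == 3
        assert cfg.clone_libraries[0].digestion_mode == "sheared"
        assert cfg.contamination == (0.01, 0.02, 0.03)
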