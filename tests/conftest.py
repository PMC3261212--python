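import numpy as np
import pytest

from bacmap.assembly import (AssemblyParams, build_contigs, calibrate_bp_per_band,
                             dq_resplit, end_merge)
from bacmap.bands import preprocess
from bacmap.simulate import LibrarySpec, SimulationConfig, generate_dataset


def small_config(**overrides):
    defaults = dict(
        genome_length_bp=1_200_000,
        n_chromosomes=2,
        het_fraction=0.54,
        clone_libraries=[LibrarySpec("LA", "partial_digest", 130.0, 15.0, 90)],
        n_markers=20,
        rng_seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def tiny_map(tiny_dataset):
    ds = tiny_dataset
    kept, _ = preprocess([ds.fingerprints[c] for c in sorted(ds.fingerprints)])
    avg_clone = sum(c.length for c in ds.clones) / len(ds.clones)
    avg_bands = sum(f.n_bands for f in kept) / len(kept)
    params = AssemblyParams.aflp(
        haploid_genome_mb=ds.config.genome_length_bp / 1e6,
        bp_per_band=calibrate_bp_per_band(avg_clone, avg_bands),
    )
    return end_merge(dq_resplit(build_contigs(kept, params)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def screened():
    """Heterozygous screen: assembled map plus pooled-deconvolution anchors.

    High heterozygosity and sparse fingerprints keep allelic band sharing
    below the alignment cutoff, so haplotypes separate into distinct contigs
    and the anchor phases carry a measurable separation signal.
    """
    from helpers import screen_markers

    cfg = small_config(
        genome_length_bp=20_000_000,
        n_chromosomes=10,
        het_fraction=0.85,
        mean_fragment_bp=8000.0,
        mobility_decay_bp=2000.0,
        clone_libraries=[LibrarySpec("LA", "partial_digest", 130.0, 12.0, 1536)],
        n_markers=250,
        rng_seed=22,
    )
    ds = generate_dataset(cfg)
    kept, _ = preprocess([ds.fingerprints[c] for c in sorted(ds.fingerprints)])
    avg_clone = sum(c.length for c in ds.clones) / len(ds.clones)
    avg_bands = sum(f.n_bands for f in kept) / len(kept)
    params = AssemblyParams.aflp(
        haploid_genome_mb=cfg.genome_length_bp / 1e6,
        bp_per_band=calibrate_bp_per_band(avg_clone, avg_bands),
    )
    pmap = dq_resplit(build_contigs(kept, params))
    anchors = screen_markers(ds, pmap, seed=22)
    return ds, pmap, anchors
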