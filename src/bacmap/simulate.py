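"""Synthetic diploid genome, BAC libraries, fingerprints and markers.

The model is deliberately abstract: a haploid chromosome is tiled by
restriction-fragment positions whose genomic lengths are right-skewed
(truncated geometric shape, rescaled to the requested mean spacing) and
whose gel mobilities are drawn independently from the same skewed shape
within the sizing range of the electrophoresis.  The two haplotypes share
position coordinates; a position is either monomorphic (one fragment, same
band and sequence tag in both haplotypes) or polymorphic (an allelic pair of
haplotype-specific fragments with independent mobilities and tags, each
present in exactly one haplotype).  A dominant marker is one allele of a
polymorphic position.  The per-position polymorphism probability is chosen
so that ``het_fraction`` of all fragments (equivalently, of all tags) are
haplotype-specific.

All randomness flows from one ``numpy`` generator seeded by the config, with
draws in a fixed documented order: genome, libraries, fingerprints,
artifacts, markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .anchoring import Marker, radioactive_from_capillary
from .bands import BandFingerprint
from .pooling import WELL_COLS, WELL_ROWS, clone_to_qpp

MOBILITY_MIN_BP = 60.0
MOBILITY_MAX_BP = 900.0

#: fixed contaminant band profiles (0.1-bp units), used verbatim by the
#: artifact injector and usable as QC reference profiles
CHLOROPLAST_PROFILE = [round((103.7 + 13.9 * i) * 10) for i in range(40)]
ARTEFACT_BANDS = [round((117.3 + 41.1 * i) * 10) for i in range(12)]


@dataclass
class LibrarySpec:
    name: str
    digestion_mode: str  # partial_digest | sheared
    clone_size_mean_kb: float
    clone_size_sd_kb: float
    n_clones: int

    def __post_init__(self) -> None:
        if self.digestion_mode not in ("partial_digest", "sheared"):
            raise ValueError(f"unknown digestion mode {self.digestion_mode!r}")
        if self.clone_size_mean_kb <= 0 or self.clone_size_sd_kb < 0:
            raise ValueError("clone sizes must be positive")


@dataclass
class SimulationConfig:
    genome_length_bp: int = 10_000_000
    n_chromosomes: int = 2
    het_fraction: float = 0.54
    mean_fragment_bp: float = 3477.0
    clone_libraries: list[LibrarySpec] = field(
        default_factory=lambda: [
            LibrarySpec("LIBA", "partial_digest", 130.0, 20.0, 768)
        ]
    )
    wells_per_plate: int = 384
    quarter_size: int = 96
    sizing_noise_sd_bp: float = 0.15
    band_window_bp: tuple[float, float] = (100.0, 650.0)
    mobility_decay_bp: float = 190.0
    repeat_fragment_fraction: float = 0.05
    contamination: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_markers: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.het_fraction, self.repeat_fragment_fraction, *self.contamination):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if self.band_window_bp[0] >= self.band_window_bp[1]:
            raise ValueError("band window min must be < max")
        if self.genome_length_bp < self.mean_fragment_bp:
            raise ValueError("genome too short for requested fragment size")


@dataclass
class Fragment:
    index: int
    chrom: int
    start: int
    length: int
    mobility_bp: float
    specific: bool
    hap: int  # -1 = shared, else owning haplotype
    repetitive: bool
    tag: str

    @property
    def end(self) -> int:
        return self.start + self.length

    def present_in(self, hap: int) -> bool:
        return not self.specific or self.hap == hap


def polymorphic_prob(het_fraction: float) -> float:
    """Per-position polymorphism probability giving the requested fraction
    of haplotype-specific fragments.

    A polymorphic position contributes two specific fragments, a monomorphic
    one a single shared fragment, so with per-position probability
    p = h/(2-h) the specific-fragment fraction 2p/(1+p) equals h.
    """
    return het_fraction / (2.0 - het_fraction)


@dataclass
class DiploidGenomeModel:
    config: SimulationConfig
    chrom_lengths: list[int]
    fragments: list[Fragment]
    _by_chrom: dict[int, list[Fragment]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_chrom:
            for fr in self.fragments:
                self._by_chrom.setdefault(fr.chrom, []).append(fr)

    def fragments_in(self, chrom: int, start: int, end: int, hap: int) -> list[Fragment]:
        """Fragments fully contained in [start, end) and present in ``hap``."""
        return [
            fr
            for fr in self._by_chrom.get(chrom, [])
            if fr.start >= start and fr.end <= end and fr.present_in(hap)
        ]

    def n_fragments(self, hap: int) -> int:
        return sum(1 for fr in self.fragments if fr.present_in(hap))

    def tag_heterozygosity(self) -> float:
        """Fraction of tags present in exactly one haplotype."""
        return sum(fr.specific for fr in self.fragments) / len(self.fragments)


def _truncated_geometric_bp(rng: np.random.Generator, n: int, decay: float) -> np.ndarray:
    """Right-skewed mobilities on [MOBILITY_MIN_BP, MOBILITY_MAX_BP]."""
    span = MOBILITY_MAX_BP - MOBILITY_MIN_BP
    u = rng.random(n)
    x = -decay * np.log1p(-u * (1.0 - np.exp(-span / decay)))
    return MOBILITY_MIN_BP + x


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> DiploidGenomeModel:
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    chrom_lengths = [config.genome_length_bp // config.n_chromosomes] * config.n_chromosomes
    chrom_lengths[-1] += config.genome_length_bp - sum(chrom_lengths)
    n_est = int(config.genome_length_bp / config.mean_fragment_bp * 1.4) + 64
    shape = _truncated_geometric_bp(rng, n_est, config.mobility_decay_bp)
    lengths = np.maximum(
        1, np.round(shape * (config.mean_fragment_bp / shape.mean())).astype(int)
    )
    mobilities = _truncated_geometric_bp(rng, 2 * n_est, config.mobility_decay_bp)
    poly = rng.random(n_est) < polymorphic_prob(config.het_fraction)
    repetitive = rng.random(2 * n_est) < config.repeat_fragment_fraction

    fragments: list[Fragment] = []
    cursor = 0
    for chrom, clen in enumerate(chrom_lengths):
        pos = 0
        while pos < clen:
            if cursor >= n_est:
                raise RuntimeError("fragment budget exhausted; genome sizing error")
            flen = int(min(lengths[cursor], clen - pos))
            variants = ((0,), (1,)) if poly[cursor] else ((-1,),)
            for v, (hap,) in enumerate(variants):
                idx = len(fragments)
                fragments.append(
                    Fragment(
                        index=idx,
                        chrom=chrom,
                        start=pos,
                        length=flen,
                        mobility_bp=round(float(mobilities[2 * cursor + v]), 1),
                        specific=hap >= 0,
                        hap=hap,
                        repetitive=bool(repetitive[2 * cursor + v]),
                        tag=f"T{idx:07d}",
                    )
                )
            pos += flen
            cursor += 1
    return DiploidGenomeModel(config, chrom_lengths, fragments)


@dataclass
class Clone:
    clone_id: str
    library: str
    hap: int
    chrom: int
    start: int
    end: int
    plate: int
    well: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def qpp(self) -> str:
        return clone_to_qpp(self.plate, self.well)


def _well_name(index_in_plate: int) -> str:
    row, col = divmod(index_in_plate, WELL_COLS)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def simulate_bac_library(
    genome: DiploidGenomeModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Clone], dict[str, tuple[int, str]]]:
    """Draw clones for every configured library and lay them out on plates.

    Clones fill 384-well plates sequentially, row-major, plates numbered
    from 1 across libraries.  Partial-digest clone ends snap to fragment
    boundaries; sheared clone starts are uniform.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    clones: list[Clone] = []
    layout: dict[str, tuple[int, str]] = {}
    chrom_lengths = np.array(genome.chrom_lengths, dtype=float)
    weights = chrom_lengths / chrom_lengths.sum()
    counter = 0
    for lib in config.clone_libraries:
        boundaries = {
            chrom: np.array(sorted({fr.start for fr in genome._by_chrom[chrom]} | {genome.chrom_lengths[chrom]}))
            for chrom in range(config.n_chromosomes)
        }
        for _ in range(lib.n_clones):
            for _attempt in range(100):
                hap = int(rng.integers(0, 2))
                chrom = int(rng.choice(config.n_chromosomes, p=weights))
                size = int(round(rng.normal(lib.clone_size_mean_kb, lib.clone_size_sd_kb) * 1000))
                if size <= 0 or size > genome.chrom_lengths[chrom]:
                    continue
                if lib.digestion_mode == "sheared":
                    start = int(rng.integers(0, genome.chrom_lengths[chrom] - size + 1))
                    end = start + size
                else:
                    bnds = boundaries[chrom]
                    eligible = bnds[bnds + size <= genome.chrom_lengths[chrom]]
                    if eligible.size == 0:
                        continue
                    start = int(rng.choice(eligible))
                    end = int(bnds[np.argmin(np.abs(bnds - (start + size)))])
                    if end <= start:
                        continue
                break
            else:
                raise RuntimeError(f"{lib.name}: could not place clone after 100 tries")
            plate = counter // config.wells_per_plate + 1
            well = _well_name(counter % config.wells_per_plate)
            clone_id = f"{lib.name}{plate:03d}{well}"
            clones.append(Clone(clone_id, lib.name, hap, chrom, start, end, plate, well))
            layout[clone_id] = (plate, well)
            counter += 1
    return clones, layout


def fingerprint_clone(
    clone: Clone,
    genome: DiploidGenomeModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[BandFingerprint, set[str]]:
    """AFLP bands and WGP tags of one clone.

    Bands are the mobilities of fully contained fragments of the clone's
    haplotype, plus Gaussian sizing noise; tags are those fragments' tag ids,
    with repetitive fragments dropping their tags entirely.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    frags = genome.fragments_in(clone.chrom, clone.start, clone.end, clone.hap)
    bands, heights = [], []
    tags: set[str] = set()
    for fr in frags:
        size = fr.mobility_bp + rng.normal(0.0, config.sizing_noise_sd_bp)
        mob = round(size * 10)
        if mob > 0:
            bands.append(mob)
            heights.append(int(rng.integers(500, 5000)))
        if not fr.repetitive:
            tags.add(fr.tag)
    order = sorted(range(len(bands)), key=bands.__getitem__)
    fp = BandFingerprint(
        clone.clone_id,
        [bands[i] for i in order],
        heights=[heights[i] for i in order],
        source_library=clone.library,
    )
    return fp, tags


def inject_artifacts(
    fingerprints: dict[str, BandFingerprint],
    layout: dict[str, tuple[int, str]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, BandFingerprint], dict[str, str]]:
    """Contaminate a copy of the fingerprint set; returns (fps, truth flags).

    Chloroplast clones are replaced by a fixed reference profile, artefact
    clones gain a fixed extra band set, and neighbour-mixed clones receive
    the union of their own and an adjacent well's bands.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    chl_rate, art_rate, mix_rate = config.contamination
    out = dict(fingerprints)
    flags: dict[str, str] = {}
    by_pos = {}
    for cid, (plate, well) in layout.items():
        row = ord(well[0]) - ord("A")
        col = int(well[1:]) - 1
        by_pos[(plate, row, col)] = cid
    for cid in sorted(fingerprints):
        r = rng.random(3)
        if r[0] < chl_rate:
            out[cid] = replace(out[cid], bands=list(CHLOROPLAST_PROFILE), heights=None)
            flags[cid] = "chloroplast"
        elif r[1] < art_rate:
            merged = sorted(set(out[cid].bands) | set(ARTEFACT_BANDS))
            out[cid] = replace(out[cid], bands=merged, heights=None)
            flags[cid] = "artefact"
        elif r[2] < mix_rate:
            plate, well = layout[cid]
            row = ord(well[0]) - ord("A")
            col = int(well[1:]) - 1
            nb = by_pos.get((plate, row, col + 1)) or by_pos.get((plate, row, col - 1))
            if nb is not None and nb in out:
                merged = sorted(set(out[cid].bands) | set(fingerprints[nb].bands))
                out[cid] = replace(out[cid], bands=merged, heights=None)
                flags[cid] = "contaminated"
    return out, flags


def sample_markers(
    genome: DiploidGenomeModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_bins: int = 100,
) -> tuple[list[Marker], dict[str, Fragment]]:
    """Pick haplotype-specific fragments as dominant mapped markers."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    eligible = [fr for fr in genome.fragments if fr.specific]
    if config.n_markers > len(eligible):
        raise ValueError(
            f"n_markers={config.n_markers} exceeds the {len(eligible)} "
            "haplotype-specific fragments available"
        )
    chosen_idx = rng.choice(len(eligible), size=config.n_markers, replace=False)
    markers: list[Marker] = []
    truth: dict[str, Fragment] = {}
    for i, k in enumerate(sorted(int(j) for j in chosen_idx)):
        fr = eligible[k]
        cap = round(fr.mobility_bp, 1)
        mk = Marker(
            marker_id=f"M{i:04d}",
            primer_combination="E00M00",
            radioactive_size_bp=round(radioactive_from_capillary(cap), 1),
            capillary_interval=(round(cap - 0.15, 2), round(cap + 0.15, 2)),
            capillary_avg_bp=cap,
            chromosome=fr.chrom,
            bin=int(fr.start / genome.chrom_lengths[fr.chrom] * n_bins),
            phase=fr.hap,
        )
        markers.append(mk)
        truth[mk.marker_id] = fr
    return markers, truth


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: DiploidGenomeModel
    clones: list[Clone]
    layout: dict[str, tuple[int, str]]
    fingerprints: dict[str, BandFingerprint]
    clean_fingerprints: dict[str, BandFingerprint]
    tag_sets: dict[str, set[str]]
    contamination_flags: dict[str, str]
    markers: list[Marker]
    marker_truth: dict[str, Fragment]

    def clone_by_id(self) -> dict[str, Clone]:
        return {c.clone_id: c for c in self.clones}

    def coverage_ge(self) -> float:
        """Exact coverage identity: summed clone length over genome length."""
        return sum(c.length for c in self.clones) / self.genome.config.genome_length_bp

    def true_marker_clones(self, marker_id: str) -> set[str]:
        fr = self.marker_truth[marker_id]
        return {
            c.clone_id
            for c in self.clones
            if c.chrom == fr.chrom
            and c.hap == fr.hap
            and c.start <= fr.start
            and fr.end <= c.end
        }


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the whole simulation under one seeded stream."""
    rng = np.random.default_rng(config.rng_seed)
    genome = simulate_genome(config, rng)
    clones, layout = simulate_bac_library(genome, config, rng)
    clean: dict[str, BandFingerprint] = {}
    tag_sets: dict[str, set[str]] = {}
    for clone in clones:
        fp, tags = fingerprint_clone(clone, genome, config, rng)
        clean[clone.clone_id] = fp
        tag_sets[clone.clone_id] = tags
    contaminated, flags = inject_artifacts(clean, layout, config, rng)
    markers, marker_truth = sample_markers(genome, config, rng)
    return SyntheticDataset(
        config=config,
        genome=genome,
        clones=clones,
        layout=layout,
        fingerprints=contaminated,
        clean_fingerprints=clean,
        tag_sets=tag_sets,
        contamination_flags=flags,
        markers=markers,
        marker_truth=marker_truth,
    )


def truth_physical_map(ds: SyntheticDataset):
    """Ground-truth contigs: connected components of genuinely overlapping
    clones within one haplotype of one chromosome.

    Useful as a reference map for screening experiments where the contig
    *assembly* is not the quantity under study.
    """
    from .assembly import AssemblyParams, Contig, PhysicalMap

    groups: dict[tuple[int, int], list[Clone]] = {}
    for c in ds.clones:
        groups.setdefault((c.chrom, c.hap), []).append(c)
    contigs: list[Contig] = []
    singletons: list[str] = []
    next_id = 1
    for key in sorted(groups):
        clones = sorted(groups[key], key=lambda c: (c.start, c.clone_id))
        component: list[Clone] = []
        reach = -1
        for c in clones + [None]:
            if c is not None and (not component or c.start < reach):
                component.append(c)
                reach = max(reach, c.end)
                continue
            if len(component) == 1:
                singletons.append(component[0].clone_id)
            elif component:
                contigs.append(
                    Contig(next_id, [(x.clone_id, x.start) for x in component])
                )
                next_id += 1
            if c is not None:
                component, reach = [c], c.end
    return PhysicalMap(
        contigs, sorted(singletons), AssemblyParams.aflp(),
        dict(ds.clean_fingerprints),
    )


# ---------------------------------------------------------------------------
# dataset writers


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    import os

    from .anchoring import write_marker_table
    from .bands import write_bands_file
    from .wgp import write_tag_table

    os.makedirs(outdir, exist_ok=True)
    write_bands_file(
        [ds.fingerprints[c] for c in sorted(ds.fingerprints)],
        os.path.join(outdir, "fingerprints.bands"),
    )
    write_tag_table(ds.tag_sets, os.path.join(outdir, "wgp_tags.tsv"))
    write_marker_table(ds.markers, os.path.join(outdir, "markers.tsv"))
    with open(os.path.join(outdir, "layout.tsv"), "w") as fh:
        fh.write("clone_id\tplate\twell\tqpp\n")
        for c in ds.clones:
            fh.write(f"{c.clone_id}\t{c.plate}\t{c.well}\t{c.qpp}\n")
    with open(os.path.join(outdir, "truth_clones.tsv"), "w") as fh:
        fh.write("clone_id\tlibrary\thaplotype\tchrom\tstart\tend\tflag\n")
        for c in ds.clones:
            flag = ds.contamination_flags.get(c.clone_id, "")
            fh.write(
                f"{c.clone_id}\t{c.library}\t{c.hap}\t{c.chrom}\t{c.start}\t{c.end}\t{flag}\n"
            )


def load_config(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    libs = [LibrarySpec(**spec) for spec in raw.pop("clone_libraries", [])]
    if "contamination" in raw:
        raw["contamination"] = tuple(raw["contamination"])
    if "band_window_bp" in raw:
        raw["band_window_bp"] = tuple(raw["band_window_bp"])
    cfg = SimulationConfig(**raw)
    if libs:
        cfg.clone_libraries = libs
    return cfg
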