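"""Sequence-tag (WGP) fingerprint handling.

Tags are opaque identifiers read from restriction-site ends of BAC inserts.
For alignment they are converted to pseudo band mobility values: random
integer IDs in a 16-bit range, each ID shared by at most ``tags_per_id``
tags.  Tag copy-number spectra are modelled by a mixture of two Poisson
distributions (heterozygous tags at half the template depth of homozygous
ones), truncated at copy number >= 2 because single-clone tags are not
retained in tag datasets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import poisson

from .bands import BandFingerprint

DEFAULT_ID_RANGE = (1000, 54705)
DEFAULT_TAGS_PER_ID = 6
PMF_SUPPORT_CAP = 200


@dataclass
class TagUniverse:
    tag_to_id: dict[str, int]
    id_range: tuple[int, int] = DEFAULT_ID_RANGE
    tags_per_id: int = DEFAULT_TAGS_PER_ID
    overflow_ids: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        counts = Counter(self.tag_to_id.values())
        bad = [i for i, c in counts.items() if c > self.tags_per_id]
        if bad:
            raise ValueError(f"IDs over capacity: {bad[:5]}")


def assign_pseudo_ids(
    tags: Sequence[str],
    id_range: tuple[int, int] = DEFAULT_ID_RANGE,
    tags_per_id: int = DEFAULT_TAGS_PER_ID,
    seed: int = 0,
) -> TagUniverse:
    """Randomly map tags to pseudo-mobility IDs, at most ``tags_per_id``
    tags per ID.  Tags beyond the range capacity get IDs past the range end;
    these overflow IDs are reported, not dropped."""
    lo, hi = id_range
    capacity = (hi - lo + 1) * tags_per_id
    rng = np.random.default_rng(seed)
    tags = list(tags)
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate tag sequences")
    order = rng.permutation(len(tags))
    ids = np.arange(lo, hi + 1)
    rng.shuffle(ids)
    mapping: dict[str, int] = {}
    overflow: set[int] = set()
    next_overflow = hi + 1
    n_ids = ids.size
    for slot, idx in enumerate(order):
        if slot < capacity:
            # round-robin across the whole range so IDs are only shared
            # once every ID is in use
            mapping[tags[idx]] = int(ids[slot % n_ids])
        else:
            oid = next_overflow + (slot - capacity) // tags_per_id
            mapping[tags[idx]] = oid
            overflow.add(oid)
    return TagUniverse(mapping, id_range, tags_per_id, overflow)


def tags_to_fingerprints(
    clone_tag_sets: Mapping[str, Iterable[str]], universe: TagUniverse
) -> list[BandFingerprint]:
    """Pseudo-bands fingerprints: sorted unique IDs of each clone's tags."""
    out = []
    for clone_id in sorted(clone_tag_sets):
        ids = set()
        for tag in clone_tag_sets[clone_id]:
            if tag not in universe.tag_to_id:
                raise KeyError(f"unknown tag {tag!r} for clone {clone_id}")
            ids.add(universe.tag_to_id[tag])
        out.append(BandFingerprint(clone_id, sorted(ids), source_library="wgp"))
    return out


def detect_chimeras(pmap, min_component: int = 3, max_cross: float = 0.10) -> set[str]:
    """Flag clones that artificially bridge two contig halves.

    A clone is a chimera candidate when it is an articulation point of its
    contig's overlap graph whose removal leaves >= 2 components of at least
    ``min_component`` clones, and its own band set splits between those
    components with less than ``max_cross`` of its matched bands shared by
    both sides.
    """
    import networkx as nx

    from .assembly import _score_edges, match_bands

    params = pmap.params
    flagged: set[str] = set()
    for ctg in pmap.contigs:
        members = ctg.clone_ids
        if len(members) < 2 * min_component + 1:
            continue
        fps = [pmap.fingerprints[c] for c in members]
        edges = _score_edges(fps, params, params.build_cutoff)
        g = nx.Graph()
        g.add_nodes_from(members)
        g.add_edges_from(edges.keys())
        for clone in list(nx.articulation_points(g)):
            h = g.copy()
            h.remove_node(clone)
            comps = [c for c in nx.connected_components(h)]
            big = [c for c in comps if len(c) >= min_component]
            if len(big) < 2:
                continue
            fp = pmap.fingerprints[clone]
            side_hits = []
            for comp in big[:2]:
                hit = set()
                for other in comp:
                    for i, _ in match_bands(
                        fp.bands, pmap.fingerprints[other].bands, params.tolerance
                    ):
                        hit.add(i)
                side_hits.append(hit)
            matched = side_hits[0] | side_hits[1]
            if not matched:
                continue
            cross = len(side_hits[0] & side_hits[1]) / len(matched)
            if cross < max_cross and side_hits[0] and side_hits[1]:
                flagged.add(clone)
    return flagged


def tag_spectrum(clone_tag_sets: Mapping[str, Iterable[str]]) -> dict[int, int]:
    """Copy-number histogram: number of tags found in exactly k clones, for
    k >= 2 (single-clone tags are excluded)."""
    per_tag = Counter()
    for tags in clone_tag_sets.values():
        for tag in set(tags):
            per_tag[tag] += 1
    spectrum = Counter(k for k in per_tag.values() if k >= 2)
    return dict(sorted(spectrum.items()))


@dataclass
class MixtureModel:
    """Truncated mixture of two Poissons over tag copy number.

    Heterozygous tags occur at rate G/2 (one haplotype), homozygous ones at
    rate G, with w the heterozygous fraction; support truncated at k >= 2.
    """

    genome_equivalents: float
    het_fraction: float
    truncation_min: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.het_fraction <= 1):
            raise ValueError("het_fraction must be in [0, 1]")
        if self.genome_equivalents <= 0:
            raise ValueError("genome_equivalents must be positive")

    @property
    def lam_het(self) -> float:
        return self.genome_equivalents / 2.0

    @property
    def lam_hom(self) -> float:
        return self.genome_equivalents

    def _raw(self, k) -> np.ndarray:
        w = self.het_fraction
        return w * poisson.pmf(k, self.lam_het) + (1 - w) * poisson.pmf(k, self.lam_hom)

    def _norm(self) -> float:
        ks = np.arange(self.truncation_min, PMF_SUPPORT_CAP + 1)
        return float(self._raw(ks).sum())

    def pmf(self, k) -> np.ndarray | float:
        k = np.asarray(k)
        if np.any(k < self.truncation_min):
            raise ValueError(f"support starts at k={self.truncation_min}")
        out = self._raw(k) / self._norm()
        return float(out) if out.ndim == 0 else out

    def mode(self) -> int:
        ks = np.arange(self.truncation_min, PMF_SUPPORT_CAP + 1)
        return int(ks[np.argmax(self.pmf(ks))])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n truncated copy numbers (rejection from the mixture)."""
        out = np.empty(0, dtype=int)
        while out.size < n:
            het = rng.random(2 * n) < self.het_fraction
            draws = np.where(
                het,
                rng.poisson(self.lam_het, 2 * n),
                rng.poisson(self.lam_hom, 2 * n),
            )
            out = np.concatenate([out, draws[draws >= self.truncation_min]])
        return out[:n]


def het_fraction_from_ratio(ratio: float) -> float:
    """Heterozygous fraction w = r/(1+r) from a het:hom ratio r."""
    return ratio / (1.0 + ratio)


def mean_tag_spacing_bp(genome_bp: float, n_tags: int) -> int:
    """Average genomic distance between unique tags, integer bp."""
    return round(genome_bp / n_tags)


def fit_mixture(
    spectrum: Mapping[int, int], truncation_min: int = 2
) -> tuple[float, float]:
    """Maximum-likelihood (G, w) on the truncated support.

    The likelihood is multinomial over the histogram, so the fit is invariant
    to rescaling all counts.
    """
    ks = np.array(sorted(spectrum))
    counts = np.array([spectrum[int(k)] for k in ks], dtype=float)
    if ks.size == 0 or counts.sum() <= 0:
        raise ValueError("empty spectrum")
    mean_k = float((ks * counts).sum() / counts.sum())

    def nll(theta):
        g, logit_w = theta
        w = 1.0 / (1.0 + np.exp(-logit_w))
        model = MixtureModel(g, w, truncation_min)
        p = np.clip(model.pmf(ks), 1e-300, None)
        return -float((counts * np.log(p)).sum())

    best = None
    for w0 in (0.25, 0.5, 0.75):
        res = minimize(
            nll,
            x0=np.array([max(mean_k, truncation_min + 0.5), np.log(w0 / (1 - w0))]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not best.success:
        raise RuntimeError(f"mixture fit did not converge: {best}")
    g = float(best.x[0])
    w = float(1.0 / (1.0 + np.exp(-best.x[1])))
    return g, w


# --------------------------------------------------------------------------
# tag table I/O (TSV: clone_id <tab> comma-joined tags)

def write_tag_table(clone_tag_sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for clone_id in sorted(clone_tag_sets):
            tags = ",".join(sorted(set(clone_tag_sets[clone_id])))
            fh.write(f"{clone_id}\t{tags}\n")


def read_tag_table(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            clone_id, _, tags = line.partition("\t")
            out[clone_id] = set(t for t in tags.split(",") if t)
    return out
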