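"""Fingerprint-overlap contig assembly.

Overlap significance between two fingerprints uses the Sulston probability
score: bands are matched greedily one-to-one within a mobility tolerance, and
the score is the binomial tail probability of observing at least that many
chance matches.  Clones are joined into contigs by single linkage below a
cutoff, ordered by greedy seriation, and summarized by a consensus band (CB)
set built from the transitive closure of matched bands.

Two parameter presets exist: tolerance mode for sizing-gel fingerprints
(tolerance 5 units = 0.5 bp) and exact-match mode for sequence-tag
pseudo-mobility fingerprints (tolerance 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import binom

from .bands import BandFingerprint


@dataclass
class AssemblyParams:
    tolerance: int = 5
    gel_length: int = 5501
    build_cutoff: float = 1e-9
    dq_cutoffs: tuple[float, ...] = (1e-10, 1e-11, 1e-12)
    dq_max_q: int = 5
    merge_cutoffs: tuple[float, ...] = (1e-8, 1e-7)
    min_merge_shared: int = 2
    bp_per_band: float = 3477.0
    haploid_genome_mb: float = 850.0
    q_threshold: float = 0.5
    #: tolerance for coalescing matched bands into one consensus band; kept
    #: tighter than the alignment tolerance so that chance mobility
    #: collisions within a contig do not deflate the consensus band count
    cb_tolerance: int | None = None

    def __post_init__(self) -> None:
        if any(c >= self.build_cutoff for c in self.dq_cutoffs):
            raise ValueError("dq_cutoffs must be stricter than build_cutoff")
        if any(c < self.build_cutoff for c in self.merge_cutoffs):
            raise ValueError("merge_cutoffs must not be stricter than build_cutoff")
        if self.bp_per_band <= 0:
            raise ValueError("bp_per_band must be positive")
        if self.cb_tolerance is None:
            self.cb_tolerance = min(self.tolerance, 3)

    @classmethod
    def aflp(cls, **kw) -> "AssemblyParams":
        return cls(**kw)

    @classmethod
    def wgp(cls, id_range: tuple[int, int] = (1000, 54705), **kw) -> "AssemblyParams":
        defaults = dict(
            tolerance=0,
            gel_length=id_range[1] - id_range[0] + 1,
            build_cutoff=1e-21,
            dq_cutoffs=(1e-24, 1e-27, 1e-30),
            merge_cutoffs=(1e-21, 1e-18),
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class OverlapResult:
    m: int
    n_low: int
    n_high: int
    p: float
    q: float
    score: float


def match_bands(b1: Sequence[int], b2: Sequence[int], tol: int) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest matching of two sorted band lists.

    Returns matched index pairs (i in b1, j in b2).  Candidate pairs within
    +-tol are taken in order of increasing distance, ties broken toward the
    lower mobility, each band used at most once.  With tol=0 this reduces to
    the shared-value count.
    """
    if not b1 or not b2:
        return []
    if tol == 0:
        s2: dict[int, list[int]] = {}
        for j, v in enumerate(b2):
            s2.setdefault(v, []).append(j)
        pairs = []
        used: dict[int, int] = {}
        for i, v in enumerate(b1):
            js = s2.get(v)
            if js:
                k = used.get(v, 0)
                if k < len(js):
                    pairs.append((i, js[k]))
                    used[v] = k + 1
        return pairs
    cands: list[tuple[int, int, int, int]] = []
    j0 = 0
    for i, v in enumerate(b1):
        while j0 < len(b2) and b2[j0] < v - tol:
            j0 += 1
        j = j0
        while j < len(b2) and b2[j] <= v + tol:
            cands.append((abs(b2[j] - v), v, b2[j], i * len(b2) + j))
            j += 1
    cands.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, key in cands:
        i, j = divmod(key, len(b2))
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append((i, j))
    pairs.sort()
    return pairs


def sulston_score(
    f1: BandFingerprint, f2: BandFingerprint, params: AssemblyParams
) -> OverlapResult:
    """Probability of >= m chance band matches between two fingerprints.

    p = (2t+1)/GL is the per-band chance-match probability, q = 1-(1-p)^nH
    the probability that a band of the smaller fingerprint matches any band
    of the larger, and the score is the binomial upper tail P(X >= m) with
    X ~ Binomial(nL, q).  An empty fingerprint scores 1 (no evidence).
    """
    b1, b2 = f1.bands, f2.bands
    if len(b1) > len(b2):
        b1, b2 = b2, b1
    n_low, n_high = len(b1), len(b2)
    p = (2 * params.tolerance + 1) / params.gel_length
    if n_low == 0:
        return OverlapResult(0, n_low, n_high, p, 0.0, 1.0)
    q = 1.0 - (1.0 - p) ** n_high
    m = len(match_bands(b1, b2, params.tolerance))
    score = float(binom.sf(m - 1, n_low, q)) if m > 0 else 1.0
    score = min(1.0, max(0.0, score))
    return OverlapResult(m, n_low, n_high, p, q, score)


@dataclass
class Contig:
    contig_id: int
    members: list[tuple[str, int]]  # (clone_id, offset in band units)
    cb_support: list[int] = field(default_factory=list)
    cb_mobility: list[float] = field(default_factory=list)
    q_clones: set[str] = field(default_factory=set)
    clone_cb_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def clone_ids(self) -> list[str]:
        return [c for c, _ in self.members]

    @property
    def cb_length(self) -> int:
        return len(self.cb_support)

    @property
    def n_clones(self) -> int:
        return len(self.members)


@dataclass
class PhysicalMap:
    contigs: list[Contig]
    singletons: list[str]
    params: AssemblyParams
    fingerprints: dict[str, BandFingerprint] = field(default_factory=dict)

    def clone_to_contig(self) -> dict[str, int]:
        out = {}
        for ctg in self.contigs:
            for cid in ctg.clone_ids:
                out[cid] = ctg.contig_id
        return out

    def all_clones(self) -> list[str]:
        out = list(self.singletons)
        for ctg in self.contigs:
            out.extend(ctg.clone_ids)
        return out


class _BandUnion:
    """Union-find over (clone, band index) refusing merges that would place
    two bands of one clone in the same consensus band."""

    def __init__(self) -> None:
        self.parent: dict[tuple[str, int], tuple[str, int]] = {}
        self.clones: dict[tuple[str, int], set[str]] = {}

    def add(self, x: tuple[str, int]) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.clones[x] = {x[0]}

    def find(self, x: tuple[str, int]) -> tuple[str, int]:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: tuple[str, int], b: tuple[str, int]) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.clones[ra] & self.clones[rb]:
            return  # would merge two bands of one clone
        self.parent[rb] = ra
        self.clones[ra] |= self.clones[rb]
        del self.clones[rb]


def _score_edges(
    fps: Sequence[BandFingerprint], params: AssemblyParams, cutoff: float
) -> dict[tuple[str, str], OverlapResult]:
    edges = {}
    ordered = sorted(fps, key=lambda f: f.clone_id)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            r = sulston_score(ordered[i], ordered[j], params)
            if r.score <= cutoff and r.m > 0:
                edges[(ordered[i].clone_id, ordered[j].clone_id)] = r
    return edges


def _seriate(
    members: list[str],
    edges: Mapping[tuple[str, str], OverlapResult],
) -> list[tuple[str, int]]:
    """Greedy seriation: seed with the best-scoring pair, then repeatedly
    attach the strongest remaining clone at offset(anchor) +- (nL - m)."""
    if len(members) == 1:
        return [(members[0], 0)]
    adj: dict[str, dict[str, OverlapResult]] = {m: {} for m in members}
    for (a, b), r in edges.items():
        adj[a][b] = r
        adj[b][a] = r
    seed = min(edges.items(), key=lambda kv: (kv[1].score, kv[0]))
    (a, b), r = seed
    offsets = {a: 0, b: r.n_low - r.m}
    placed = [a, b]
    remaining = set(members) - {a, b}
    while remaining:
        best = None
        for c in sorted(remaining):
            for p in placed:
                r = adj[c].get(p)
                if r is None:
                    continue
                if best is None or (r.score, c, p) < (best[0].score, best[1], best[2]):
                    best = (r, c, p)
        if best is None:  # disconnected under these edges; append arbitrarily
            c = sorted(remaining)[0]
            offsets[c] = max(offsets.values()) + 1
            placed.append(c)
            remaining.remove(c)
            continue
        r, c, anchor = best
        step = max(r.n_low - r.m, 1)
        # choose the side of the anchor by attraction to already-placed clones
        right_pull = sum(
            adj[c][k].m for k in placed if k in adj[c] and offsets[k] > offsets[anchor]
        )
        left_pull = sum(
            adj[c][k].m for k in placed if k in adj[c] and offsets[k] < offsets[anchor]
        )
        if right_pull > left_pull:
            offsets[c] = offsets[anchor] + step
        elif left_pull > right_pull:
            offsets[c] = offsets[anchor] - step
        else:
            n_right = sum(1 for k in placed if offsets[k] > offsets[anchor])
            n_left = sum(1 for k in placed if offsets[k] < offsets[anchor])
            offsets[c] = offsets[anchor] + (step if n_right <= n_left else -step)
        placed.append(c)
        remaining.remove(c)
    base = min(offsets.values())
    out = [(c, offsets[c] - base) for c in members]
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def _build_contig(
    contig_id: int,
    fps: Mapping[str, BandFingerprint],
    members: list[str],
    edges: Mapping[tuple[str, str], OverlapResult],
    params: AssemblyParams,
) -> Contig:
    sub_edges = {
        (a, b): r for (a, b), r in edges.items() if a in members and b in members
    }
    ordered = _seriate(sorted(members), sub_edges)
    uf = _BandUnion()
    for cid in members:
        for i in range(fps[cid].n_bands):
            uf.add((cid, i))
    for (a, b), _ in sorted(sub_edges.items()):
        for i, j in match_bands(fps[a].bands, fps[b].bands, params.cb_tolerance):
            uf.union((a, i), (b, j))
    comp_members: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for cid in members:
        for i in range(fps[cid].n_bands):
            comp_members.setdefault(uf.find((cid, i)), []).append((cid, i))
    support, mobility = [], []
    clone_shared: dict[str, int] = {c: 0 for c in members}
    for elems in comp_members.values():
        support.append(len(elems))
        mobility.append(
            sum(fps[c].bands[i] for c, i in elems) / len(elems)
        )
        if len(elems) >= 2:
            for c, _ in elems:
                clone_shared[c] += 1
    ctg = Contig(
        contig_id=contig_id,
        members=ordered,
        cb_support=support,
        cb_mobility=mobility,
        clone_cb_fraction={
            c: (clone_shared[c] / fps[c].n_bands if fps[c].n_bands else 0.0)
            for c in members
        },
    )
    ctg.q_clones = identify_questionable(ctg, params)
    return ctg


def identify_questionable(contig: Contig, params: AssemblyParams) -> set[str]:
    """Clones whose bands agree with the shared consensus for less than
    ``q_threshold`` of their bands."""
    return {
        c
        for c, frac in contig.clone_cb_fraction.items()
        if frac < params.q_threshold
    }


def _components(
    members: Sequence[str], edges: Mapping[tuple[str, str], OverlapResult]
) -> list[list[str]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(members)
    g.add_edges_from(edges.keys())
    return [sorted(c) for c in nx.connected_components(g)]


def build_contigs(
    fps: Sequence[BandFingerprint], params: AssemblyParams | None = None
) -> PhysicalMap:
    """Single-linkage contig build at ``build_cutoff``."""
    params = params or AssemblyParams()
    fmap = {f.clone_id: f for f in fps}
    if len(fmap) != len(fps):
        raise ValueError("duplicate clone ids in fingerprint set")
    edges = _score_edges(fps, params, params.build_cutoff)
    contigs: list[Contig] = []
    singletons: list[str] = []
    next_id = 1
    for comp in sorted(_components(list(fmap), edges)):
        if len(comp) < 2:
            singletons.extend(comp)
            continue
        contigs.append(_build_contig(next_id, fmap, comp, edges, params))
        next_id += 1
    return PhysicalMap(contigs, sorted(singletons), params, fmap)


def dq_resplit(pmap: PhysicalMap, params: AssemblyParams | None = None) -> PhysicalMap:
    """Dissolve contigs with more than ``dq_max_q`` questionable clones and
    rebuild their members at successively stricter cutoffs; contigs that keep
    failing at the strictest cutoff are left as they were."""
    params = params or pmap.params
    fps = pmap.fingerprints
    out_contigs: list[Contig] = []
    singletons = list(pmap.singletons)

    def rebuild(members: list[str], level: int) -> list[Contig] | None:
        if level >= len(params.dq_cutoffs):
            return None
        cutoff = params.dq_cutoffs[level]
        sub_fps = [fps[c] for c in members]
        edges = _score_edges(sub_fps, params, cutoff)
        result: list[Contig] = []
        for comp in _components(members, edges):
            if len(comp) < 2:
                singletons.extend(comp)
                continue
            ctg = _build_contig(0, fps, comp, edges, params)
            if len(ctg.q_clones) > params.dq_max_q:
                deeper = rebuild(comp, level + 1)
                if deeper is None:
                    result.append(ctg)
                else:
                    result.extend(deeper)
            else:
                result.append(ctg)
        return result

    for ctg in pmap.contigs:
        if len(ctg.q_clones) <= params.dq_max_q:
            out_contigs.append(ctg)
            continue
        rebuilt = rebuild(ctg.clone_ids, 0)
        if rebuilt is None:
            out_contigs.append(ctg)  # persistent Q contig, kept as-is
        else:
            out_contigs.extend(rebuilt)
    for i, ctg in enumerate(out_contigs, start=1):
        ctg.contig_id = i
    return PhysicalMap(out_contigs, sorted(singletons), params, fps)


def end_merge(pmap: PhysicalMap, params: AssemblyParams | None = None) -> PhysicalMap:
    """End-to-end merging: contigs linked by >= ``min_merge_shared`` clone
    pairs under a relaxed cutoff are merged, transitively per round."""
    import networkx as nx

    params = params or pmap.params
    fps = pmap.fingerprints
    contigs = list(pmap.contigs)
    for cutoff in params.merge_cutoffs:
        g = nx.Graph()
        g.add_nodes_from(range(len(contigs)))
        for i in range(len(contigs)):
            for j in range(i + 1, len(contigs)):
                n_pairs = 0
                for a in contigs[i].clone_ids:
                    for b in contigs[j].clone_ids:
                        r = sulston_score(fps[a], fps[b], params)
                        if r.score <= cutoff and r.m > 0:
                            n_pairs += 1
                            if n_pairs >= params.min_merge_shared:
                                break
                    if n_pairs >= params.min_merge_shared:
                        break
                if n_pairs >= params.min_merge_shared:
                    g.add_edge(i, j)
        merged: list[Contig] = []
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            if len(comp) == 1:
                merged.append(contigs[comp[0]])
                continue
            members = sorted(
                cid for k in comp for cid in contigs[k].clone_ids
            )
            sub_fps = [fps[c] for c in members]
            edges = _score_edges(sub_fps, params, cutoff)
            merged.append(_build_contig(0, fps, members, edges, params))
        contigs = merged
    contigs.sort(key=lambda c: c.clone_ids[0])
    for i, ctg in enumerate(contigs, start=1):
        ctg.contig_id = i
    return PhysicalMap(contigs, list(pmap.singletons), params, fps)


# ---------------------------------------------------------------------------
# length statistics

SIZE_CLASS_EDGES = (
    ("INF-400", 400, math.inf),
    ("399-200", 200, 399),
    ("199-100", 100, 199),
    ("99-50", 50, 99),
    ("49-25", 25, 49),
    ("24-10", 10, 24),
    ("9-3", 3, 9),
    ("2", 2, 2),
)


def n50(values: Sequence[float]) -> float:
    """Value in the descending-sorted list at which the cumulative sum
    reaches 50% of the total."""
    if not values:
        return 0.0
    vals = sorted(values, reverse=True)
    half = sum(vals) / 2
    acc = 0.0
    for v in vals:
        acc += v
        if acc >= half:
            return v
    return vals[-1]


def map_length_mb(total_bands: int, bp_per_band: float) -> int:
    """Total map length in integer Mb from aligned band count."""
    return round(total_bands * bp_per_band / 1e6)


def inflation_ratio(total_mb: float, haploid_genome_mb: float) -> float:
    return round(total_mb / haploid_genome_mb, 2)


def genome_equivalents(n_clones: int, clone_kb: float, genome_mb: float) -> float:
    """Haploid genome equivalents of a clone set, to one decimal."""
    return round(n_clones * clone_kb / 1000.0 / genome_mb, 1)


def singleton_pct(n_singletons: int, n_total: int) -> float:
    return round(100.0 * n_singletons / n_total, 1)


def calibrate_bp_per_band(avg_clone_bp: float, avg_bands_per_clone: float) -> float:
    """Sequence represented per retained fingerprint band, from the average
    clone size and the average band count of the filtered fingerprints."""
    return avg_clone_bp / avg_bands_per_clone


def map_stats(pmap: PhysicalMap, params: AssemblyParams | None = None) -> dict:
    params = params or pmap.params
    c = params.bp_per_band
    lengths_kb = [ctg.cb_length * c / 1000.0 for ctg in pmap.contigs]
    total_bands = sum(ctg.cb_length for ctg in pmap.contigs)
    n_in_contigs = sum(ctg.n_clones for ctg in pmap.contigs)
    n_total = n_in_contigs + len(pmap.singletons)
    hist = {}
    for label, lo, hi in SIZE_CLASS_EDGES:
        hist[label] = sum(1 for ctg in pmap.contigs if lo <= ctg.n_clones <= hi)
    total_mb_exact = total_bands * c / 1e6
    return {
        "n_contigs": len(pmap.contigs),
        "n_clones_in_contigs": n_in_contigs,
        "n_singletons": len(pmap.singletons),
        "n_clones_total": n_total,
        "singleton_pct": singleton_pct(len(pmap.singletons), n_total) if n_total else 0.0,
        "total_bands": total_bands,
        "avg_kb": round(sum(lengths_kb) / len(lengths_kb), 1) if lengths_kb else 0.0,
        "n50_kb": round(n50(lengths_kb), 1),
        "total_mb": map_length_mb(total_bands, c),
        "total_mb_exact": total_mb_exact,
        "ge": round(total_mb_exact / params.haploid_genome_mb, 1),
        "inflation": inflation_ratio(total_mb_exact, params.haploid_genome_mb),
        "size_classes": hist,
        "n_q_clones": sum(len(ctg.q_clones) for ctg in pmap.contigs),
    }
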