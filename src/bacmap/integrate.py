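"""Hybrid-map integration, haplotype-mixing analysis and pipeline driver.

Contigs of two physical maps built from overlapping clone sets are linked
when they share at least ``min_shared_clones`` clones; connected components
of these links form contig groups, and each group counts as a single contig
in the group-enhanced statistics.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .assembly import PhysicalMap, map_stats


@dataclass
class ContigGroup:
    group_id: int
    members: list[tuple[str, int]]  # (map label, contig_id)

    def contigs_of(self, label: str) -> list[int]:
        return [cid for lab, cid in self.members if lab == label]


def expected_two_haplotype_pct(n_markers: int) -> float:
    """Chance that a contig with n independent markers mixes both phases,
    as a percentage: 100 * (1 - 0.5^(n-1))."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return 100.0 * (1.0 - 0.5 ** (n_markers - 1))


def link_and_group(
    map_a: PhysicalMap,
    map_b: PhysicalMap,
    min_shared_clones: int = 2,
    labels: tuple[str, str] = ("AFLP", "WGP"),
) -> tuple[list[ContigGroup], dict]:
    """Group contigs of two maps connected by shared-clone links (chains
    allowed).  Returns the groups plus group-enhanced contig counts."""
    la, lb = labels
    clones_a = {ctg.contig_id: set(ctg.clone_ids) for ctg in map_a.contigs}
    clones_b = {ctg.contig_id: set(ctg.clone_ids) for ctg in map_b.contigs}
    by_clone_b: dict[str, int] = {}
    for cid, cset in clones_b.items():
        for clone in cset:
            by_clone_b[clone] = cid
    g = nx.Graph()
    for cid, cset in clones_a.items():
        shared: dict[int, int] = {}
        for clone in cset:
            if clone in by_clone_b:
                shared[by_clone_b[clone]] = shared.get(by_clone_b[clone], 0) + 1
        for bid, n in shared.items():
            if n >= min_shared_clones:
                g.add_edge((la, cid), (lb, bid), shared=n)
    groups = []
    for i, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)), start=1
    ):
        groups.append(ContigGroup(i, sorted(comp)))
    grouped_a = {cid for grp in groups for cid in grp.contigs_of(la)}
    grouped_b = {cid for grp in groups for cid in grp.contigs_of(lb)}
    counts = {
        "n_groups": len(groups),
        "n_pair_groups": sum(1 for grp in groups if len(grp.members) == 2),
        "n_multi_groups": sum(1 for grp in groups if len(grp.members) >= 3),
        f"enhanced_{la}": len(groups) + (len(map_a.contigs) - len(grouped_a)),
        f"enhanced_{lb}": len(groups) + (len(map_b.contigs) - len(grouped_b)),
        f"raw_{la}": len(map_a.contigs),
        f"raw_{lb}": len(map_b.contigs),
    }
    return groups, counts


def haplotype_mixing_table(contig_phases: Mapping[int, Sequence[int]],
                           contig_length_kb: Mapping[int, float] | None = None) -> pd.DataFrame:
    """Observed vs expected haplotype mixing by marker count per contig.

    ``contig_phases`` maps contig_id to the phases (0/1) of its anchored
    markers; a contig is two-haplotype iff both phases occur.
    """
    contig_length_kb = contig_length_kb or {}
    rows = []
    by_n: dict[int, list[int]] = {}
    for cid, phases in contig_phases.items():
        by_n.setdefault(len(phases), []).append(cid)
    for n in sorted(by_n):
        cids = by_n[n]
        two = [c for c in cids if len(set(contig_phases[c])) == 2]
        one = [c for c in cids if c not in two]
        total = len(cids)
        rows.append(
            {
                "n_markers": n,
                "n_one_haplotype": len(one),
                "avg_kb_one": round(
                    sum(contig_length_kb.get(c, 0.0) for c in one) / len(one), 1
                ) if one else 0.0,
                "n_two_haplotypes": len(two),
                "avg_kb_two": round(
                    sum(contig_length_kb.get(c, 0.0) for c in two) / len(two), 1
                ) if two else 0.0,
                "observed_pct_two": round(100.0 * len(two) / total, 1) if total else 0.0,
                "expected_pct_two": round(expected_two_haplotype_pct(n), 1),
            }
        )
    return pd.DataFrame(rows)


def write_hybrid_table(
    map_a: PhysicalMap,
    map_b: PhysicalMap,
    groups: Sequence[ContigGroup],
    path,
    anchors: Sequence | None = None,
    labels: tuple[str, str] = ("AFLP", "WGP"),
) -> pd.DataFrame:
    """One row per clone with its contig/offset in each map, its contig
    group, and any anchor markers.  Rows sorted by clone id."""
    la, lb = labels
    group_of: dict[tuple[str, int], int] = {}
    for grp in groups:
        for member in grp.members:
            group_of[member] = grp.group_id
    pos_a = {
        cid: (ctg.contig_id, off)
        for ctg in map_a.contigs
        for cid, off in ctg.members
    }
    pos_b = {
        cid: (ctg.contig_id, off)
        for ctg in map_b.contigs
        for cid, off in ctg.members
    }
    anchors_by_clone: dict[str, list[str]] = {}
    for a in anchors or []:
        for clone in a.positive_clones:
            anchors_by_clone.setdefault(clone, []).append(a.marker_id)
    all_clones = sorted(set(map_a.all_clones()) | set(map_b.all_clones()))
    rows = []
    for clone in all_clones:
        ca, oa = pos_a.get(clone, (None, None))
        cb, ob = pos_b.get(clone, (None, None))
        gid = None
        if ca is not None and (la, ca) in group_of:
            gid = group_of[(la, ca)]
        elif cb is not None and (lb, cb) in group_of:
            gid = group_of[(lb, cb)]
        rows.append(
            {
                "clone_id": clone,
                f"{la}_contig": ca if ca is not None else "singleton"
                if clone in map_a.fingerprints else "",
                f"{la}_offset": oa if oa is not None else "",
                f"{lb}_contig": cb if cb is not None else "singleton"
                if clone in map_b.fingerprints else "",
                f"{lb}_offset": ob if ob is not None else "",
                "group_id": gid if gid is not None else "",
                "anchor_markers": ",".join(sorted(anchors_by_clone.get(clone, []))),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_hybrid_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# full synthetic pipeline


def run_pipeline(config, outdir=None, min_shared_clones: int = 2) -> dict:
    """simulate -> qc -> assemble (tolerance + exact modes) -> pool/anchor ->
    integrate -> stats.  Returns a JSON-serializable report."""
    from . import anchoring, pooling, wgp
    from .assembly import AssemblyParams, build_contigs, dq_resplit, end_merge
    from .bands import QCParams, preprocess
    from .simulate import SimulationConfig, generate_dataset, load_config

    if isinstance(config, (str, bytes)):
        config = load_config(config)
    if not isinstance(config, SimulationConfig):
        raise TypeError("config must be a SimulationConfig or a path to one")

    report: dict = {"seed": config.rng_seed, "timings_s": {}}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                report["timings_s"][name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("simulate"):
        ds = generate_dataset(config)
        genome_mb = config.genome_length_bp / 1e6
        report["truth"] = {
            "n_clones": len(ds.clones),
            "coverage_ge": round(ds.coverage_ge(), 1),
            "tag_heterozygosity": round(ds.genome.tag_heterozygosity(), 3),
        }

    with stage("qc"):
        qc = QCParams(window_bp=config.band_window_bp)
        kept, exclusions = preprocess(
            [ds.fingerprints[c] for c in sorted(ds.fingerprints)], qc
        )
        report["qc"] = {"n_input": len(ds.fingerprints), "n_kept": len(kept),
                        "exclusions": exclusions}

    with stage("assemble_aflp"):
        from .assembly import calibrate_bp_per_band

        avg_clone_bp = sum(c.length for c in ds.clones) / len(ds.clones)
        avg_bands = sum(fp.n_bands for fp in kept) / len(kept)
        params_a = AssemblyParams.aflp(
            haploid_genome_mb=genome_mb,
            bp_per_band=calibrate_bp_per_band(avg_clone_bp, avg_bands),
        )
        pmap_a = end_merge(dq_resplit(build_contigs(kept, params_a)))
        report["aflp_map"] = map_stats(pmap_a)
        report["aflp_map"]["bp_per_band"] = round(params_a.bp_per_band, 1)

    with stage("wgp_map"):
        all_tags = sorted({t for ts in ds.tag_sets.values() for t in ts})
        universe = wgp.assign_pseudo_ids(all_tags, seed=config.rng_seed)
        wgp_fps = wgp.tags_to_fingerprints(
            {c: ts for c, ts in ds.tag_sets.items() if ts}, universe
        )
        avg_tags = sum(fp.n_bands for fp in wgp_fps) / len(wgp_fps)
        params_w = AssemblyParams.wgp(
            haploid_genome_mb=genome_mb,
            bp_per_band=calibrate_bp_per_band(avg_clone_bp, avg_tags),
        )
        pmap_w = end_merge(dq_resplit(build_contigs(wgp_fps, params_w)))
        report["wgp_map"] = map_stats(pmap_w)
        spectrum = wgp.tag_spectrum(ds.tag_sets)
        report["tag_spectrum_mode"] = (
            max(spectrum, key=lambda k: spectrum[k]) if spectrum else None
        )

    with stage("anchor"):
        n_plates = max(c.plate for c in ds.clones)
        design = pooling.generate_design(
            n_qpp=n_plates * 4, v=pooling.DEFAULT_V, k=pooling.DEFAULT_K,
            seed=config.rng_seed,
        )
        clone_ids_by_qpp: dict[str, list[str]] = {}
        for c in ds.clones:
            clone_ids_by_qpp.setdefault(c.qpp, []).append(c.clone_id)
        anchors = []
        for mk in ds.markers:
            true_clones = ds.true_marker_clones(mk.marker_id)
            pos_qpps = {
                q for q, members in clone_ids_by_qpp.items()
                if any(c in true_clones for c in members)
            }
            pos_sps = set()
            for q in pos_qpps:
                if q in design.assignment:
                    pos_sps |= design.assignment[q]
            deconv = pooling.deconvolute(pos_sps, design)
            anchors.append(
                anchoring.keymaps_anchor(mk, deconv, pmap_a, ds.layout)
            )
        marker_map = {m.marker_id: m for m in ds.markers}
        table, invalid, rates = anchoring.validate_and_summarize(anchors, marker_map)
        report["anchoring"] = rates
        report["anchoring"]["per_chromosome"] = table.to_dict(orient="records")

    with stage("integrate"):
        groups, counts = link_and_group(pmap_a, pmap_w, min_shared_clones)
        report["integration"] = counts
        contig_phases: dict[int, list[int]] = {}
        for a in anchors:
            if a.status in ("anchored", "ambiguous") and a.contig_id is not None:
                contig_phases.setdefault(a.contig_id, []).append(
                    marker_map[a.marker_id].phase
                )
        mix = haplotype_mixing_table(contig_phases)
        report["haplotype_mixing"] = mix.to_dict(orient="records")
        if outdir is not None:
            import os

            os.makedirs(outdir, exist_ok=True)
            write_hybrid_table(
                pmap_a, pmap_w, groups, os.path.join(outdir, "hybrid_map.tsv"),
                anchors=anchors,
            )

    report["inflation"] = report["aflp_map"]["inflation"]
    return report
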