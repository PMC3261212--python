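"""In-silico anchoring of genetic markers onto physical-map contigs.

A marker screened on the superpools yields a set of positive superpools;
deconvolution turns those into candidate quarter-plate pools, and the marker
is anchored to the contig holding at least ``min_clones`` clones that both
reside in candidate QPPs and carry a fingerprint band within a small mobility
distance of the marker size.

Marker sizes from historical sizing gels shift systematically relative to
capillary sizes; a monotone piecewise-linear calibration with a knot at
450 bp converts between the two systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assembly import PhysicalMap, sulston_score
from .bands import BandFingerprint
from .pooling import DeconvolutionResult, clone_to_qpp

SHIFT_KNOT_BP = 450.0
MAX_SHIFT_BP = 20.0  # at the 600 bp end of the sizing-gel range
BAND_MATCH_TOL_BP = 0.4


@dataclass
class Marker:
    marker_id: str
    primer_combination: str = ""
    radioactive_size_bp: float | None = None
    capillary_interval: tuple[float, float] | None = None
    capillary_avg_bp: float | None = None
    chromosome: str | int | None = None
    bin: int | None = None
    phase: int | None = None

    def __post_init__(self) -> None:
        if self.capillary_interval is not None:
            lo, hi = self.capillary_interval
            if lo >= hi:
                raise ValueError(f"{self.marker_id}: interval low >= high")


@dataclass
class AnchorRecord:
    marker_id: str
    contig_id: int | None
    positive_clones: list[str]
    n_candidate_qpps: int
    n_matched_qpps: int
    status: str  # anchored | ambiguous | omitted_single_qpp | failed
    invalid: bool = False


# ---------------------------------------------------------------------------
# size conversion


def reference_shift_bp(radioactive_bp) -> np.ndarray | float:
    """Canonical shift model: no shift up to the knot, rising linearly to
    +20 bp at 600 bp.  capillary = radioactive + shift."""
    x = np.asarray(radioactive_bp, dtype=float)
    shift = np.where(
        x <= SHIFT_KNOT_BP,
        0.0,
        (x - SHIFT_KNOT_BP) * MAX_SHIFT_BP / (600.0 - SHIFT_KNOT_BP),
    )
    return float(shift) if shift.ndim == 0 else shift


def radioactive_from_capillary(capillary_bp: float) -> float:
    """Invert the canonical shift model."""
    if capillary_bp <= SHIFT_KNOT_BP:
        return capillary_bp
    slope = MAX_SHIFT_BP / (600.0 - SHIFT_KNOT_BP)
    return (capillary_bp + SHIFT_KNOT_BP * slope) / (1.0 + slope)


@dataclass
class SizeCalibration:
    intercept: float
    slope: float
    knot_slope: float  # extra slope beyond the knot
    residual_sd: float
    knot_bp: float = SHIFT_KNOT_BP

    def shift(self, radioactive_bp) -> np.ndarray | float:
        x = np.asarray(radioactive_bp, dtype=float)
        s = self.intercept + self.slope * x + self.knot_slope * np.maximum(
            0.0, x - self.knot_bp
        )
        return float(s) if s.ndim == 0 else s

    def predict_capillary(self, radioactive_bp) -> np.ndarray | float:
        return np.asarray(radioactive_bp, dtype=float) + self.shift(radioactive_bp)

    def interval_half_width(self) -> float:
        """Scoring-interval half width, clamped so widths stay in 0.2-0.4 bp."""
        return float(np.clip(2.0 * self.residual_sd, 0.1, 0.2))

    def scoring_interval(self, radioactive_bp: float) -> tuple[float, float]:
        c = float(self.predict_capillary(radioactive_bp))
        h = self.interval_half_width()
        return (c - h, c + h)


def fit_size_conversion(pairs: Sequence[tuple[float, float]]) -> SizeCalibration:
    """Least-squares piecewise-linear fit of capillary - radioactive shift.

    ``pairs`` are (radioactive_bp, capillary_bp) observations.  The fitted
    predicted capillary size must be monotone non-decreasing in the
    radioactive size.
    """
    if len(pairs) < 4:
        raise ValueError("need at least 4 calibration pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] - p[0] for p in pairs], dtype=float)
    design = np.column_stack(
        [np.ones_like(x), x, np.maximum(0.0, x - SHIFT_KNOT_BP)]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sd = float(np.sqrt(np.mean(resid**2)))
    cal = SizeCalibration(float(coef[0]), float(coef[1]), float(coef[2]), sd)
    if 1.0 + cal.slope < -1e-9 or 1.0 + cal.slope + cal.knot_slope < -1e-9:
        raise ValueError("degenerate calibration: fitted conversion not monotone")
    return cal


# ---------------------------------------------------------------------------
# marker scoring in superpool fingerprints


def score_marker_in_superpools(
    superpool_bands: Mapping[int, BandFingerprint], marker: Marker
) -> tuple[set[int], float | None, str]:
    """Score one marker's size interval across the superpool bands files.

    Returns (positive superpools, mean in-interval size in bp, status).  The
    interval is closed at both ends.  If more than half of the positive
    superpools hold >= 2 distinct band values in the interval, the marker
    interferes with a neighbouring band and is flagged unusable.
    """
    if marker.capillary_interval is None:
        raise ValueError(f"{marker.marker_id}: no capillary interval set")
    lo = round(marker.capillary_interval[0] * 10)
    hi = round(marker.capillary_interval[1] * 10)
    positives: set[int] = set()
    sizes: list[float] = []
    crowded = 0
    for sp, fp in superpool_bands.items():
        in_win = [b for b in fp.all_bands() if lo <= b <= hi]
        if in_win:
            positives.add(sp)
            sizes.extend(b / 10.0 for b in in_win)
            if len(set(in_win)) >= 2:
                crowded += 1
    if not positives:
        return set(), None, "failed"
    status = "unusable" if crowded > len(positives) / 2 else "ok"
    return positives, float(np.mean(sizes)), status


def superpool_fingerprints(
    fps: Mapping[str, BandFingerprint],
    layout: Mapping[str, tuple[int, str]],
    design,
) -> dict[int, BandFingerprint]:
    """Pooled band profiles: each superpool's bands are the union of the
    bands of every clone whose QPP was pipetted into it."""
    bands: dict[int, set[int]] = {s: set() for s in range(1, design.v + 1)}
    for clone_id, fp in fps.items():
        plate, well = layout[clone_id]
        qpp = clone_to_qpp(plate, well)
        if qpp not in design.assignment:
            continue
        for s in design.assignment[qpp]:
            bands[s].update(fp.all_bands())
    return {
        s: BandFingerprint(f"SP{s:02d}", sorted(b)) for s, b in bands.items()
    }


# ---------------------------------------------------------------------------
# pooled-screen anchoring


def _clone_band_match(fp: BandFingerprint, size_bp: float, tol_bp: float) -> bool:
    target = size_bp * 10
    tol = tol_bp * 10
    return any(abs(b - target) <= tol for b in fp.all_bands())


def keymaps_anchor(
    marker: Marker,
    deconv: DeconvolutionResult,
    pmap: PhysicalMap,
    layout: Mapping[str, tuple[int, str]],
    band_tol_bp: float = BAND_MATCH_TOL_BP,
    min_clones: int = 2,
) -> AnchorRecord:
    """Place one marker on the physical map from its deconvoluted QPP list.

    Markers with at most one candidate QPP are omitted.  A clone supports the
    marker when its QPP is a candidate and its (unclipped) fingerprint has a
    band within ``band_tol_bp`` of the measured marker size.  The marker
    anchors to the unique contig with >= ``min_clones`` supporting clones;
    several qualifying contigs give status ``ambiguous``.  When the anchored
    contig has fewer supporting clones than candidate QPPs, matching
    singleton clones that overlap the contig are added.
    """
    if marker.capillary_avg_bp is None:
        raise ValueError(f"{marker.marker_id}: no measured capillary size")
    n_cand = len(deconv.candidates)
    if n_cand <= 1:
        return AnchorRecord(marker.marker_id, None, [], n_cand, 0, "omitted_single_qpp")

    def supports(clone_id: str) -> bool:
        plate, well = layout[clone_id]
        if clone_to_qpp(plate, well) not in deconv.candidates:
            return False
        return _clone_band_match(
            pmap.fingerprints[clone_id], marker.capillary_avg_bp, band_tol_bp
        )

    per_contig: dict[int, list[str]] = {}
    for ctg in pmap.contigs:
        hits = [c for c in ctg.clone_ids if supports(c)]
        if hits:
            per_contig[ctg.contig_id] = hits
    qualifying = [cid for cid, hits in per_contig.items() if len(hits) >= min_clones]
    if not qualifying:
        return AnchorRecord(marker.marker_id, None, [], n_cand, 0, "failed")
    if len(qualifying) > 1:
        best = max(qualifying, key=lambda cid: (len(per_contig[cid]), -cid))
        clones = sorted(per_contig[best])
        qpps = {clone_to_qpp(*layout[c]) for c in clones}
        return AnchorRecord(
            marker.marker_id, best, clones, n_cand, len(qpps), "ambiguous"
        )
    cid = qualifying[0]
    clones = sorted(per_contig[cid])
    if len(clones) < n_cand:  # look for extra positives in overlapping singletons
        ctg = next(c for c in pmap.contigs if c.contig_id == cid)
        member_fps = [pmap.fingerprints[c] for c in ctg.clone_ids]
        for s in pmap.singletons:
            if not supports(s):
                continue
            fp = pmap.fingerprints[s]
            if any(
                sulston_score(fp, mf, pmap.params).score <= pmap.params.build_cutoff
                for mf in member_fps
            ):
                clones.append(s)
        clones = sorted(set(clones))
    qpps = {clone_to_qpp(*layout[c]) for c in clones}
    return AnchorRecord(marker.marker_id, cid, clones, n_cand, len(qpps), "anchored")


# ---------------------------------------------------------------------------
# validation and summary


def expected_marker_copies(genome_equivalents: float, heterozygous: bool = True) -> float:
    """Expected clone copies of a marker in a pool of given depth; a marker
    on one of the two haplotypes is present in half the clones covering its
    locus."""
    return genome_equivalents / 2.0 if heterozygous else float(genome_equivalents)


def error_rate_pct(n_invalid: int, n_anchored: int) -> float:
    return round(100.0 * n_invalid / n_anchored, 1)


def validate_and_summarize(
    anchors: Sequence[AnchorRecord],
    markers: Mapping[str, Marker],
    max_bin_distance: int = 10,
):
    """Flag conflicting anchors and tabulate anchoring per chromosome.

    Within a contig, anchors on a minority chromosome (fewer than the most
    frequent one) are invalid; on the majority chromosome, anchors more than
    ``max_bin_distance`` bins from the median bin are invalid.
    """
    import pandas as pd

    anchored = [a for a in anchors if a.status in ("anchored", "ambiguous")]
    by_contig: dict[int, list[AnchorRecord]] = {}
    for a in anchored:
        by_contig.setdefault(a.contig_id, []).append(a)
    invalid: list[str] = []
    for recs in by_contig.values():
        if len(recs) < 2:
            continue
        chroms = [markers[a.marker_id].chromosome for a in recs]
        counts = {c: chroms.count(c) for c in set(chroms)}
        majority = max(sorted(counts), key=lambda c: counts[c])
        major_bins = [
            markers[a.marker_id].bin
            for a in recs
            if markers[a.marker_id].chromosome == majority
            and markers[a.marker_id].bin is not None
        ]
        med = float(np.median(major_bins)) if major_bins else None
        for a in recs:
            mk = markers[a.marker_id]
            if mk.chromosome != majority:
                a.invalid = True
                invalid.append(a.marker_id)
            elif (
                med is not None
                and mk.bin is not None
                and abs(mk.bin - med) > max_bin_distance
            ):
                a.invalid = True
                invalid.append(a.marker_id)
    rows = []
    chrom_keys = sorted(
        {markers[a.marker_id].chromosome for a in anchored}, key=str
    )
    for chrom in chrom_keys:
        recs = [a for a in anchored if markers[a.marker_id].chromosome == chrom]
        rows.append(
            {
                "chromosome": chrom,
                "anchor_markers": len(recs),
                "anchored_contigs": len({a.contig_id for a in recs}),
                "anchored_clones": len({c for a in recs for c in a.positive_clones}),
            }
        )
    table = pd.DataFrame(
        rows, columns=["chromosome", "anchor_markers", "anchored_contigs", "anchored_clones"]
    )
    attempted = sum(1 for a in anchors if a.status != "omitted_single_qpp")
    rates = {
        "n_attempted": attempted,
        "n_anchored": len(anchored),
        "n_invalid": len(invalid),
        "success_rate_pct": round(100.0 * len(anchored) / attempted, 1) if attempted else 0.0,
        "error_rate_pct": error_rate_pct(len(invalid), len(anchored)) if anchored else 0.0,
    }
    return table, invalid, rates


# ---------------------------------------------------------------------------
# marker table I/O


MARKER_COLUMNS = [
    "marker_id",
    "primer_combination",
    "radioactive_size_bp",
    "interval_low",
    "interval_high",
    "capillary_avg_bp",
    "chromosome",
    "bin",
    "phase",
]


def write_marker_table(markers: Sequence[Marker], path) -> None:
    import pandas as pd

    rows = []
    for m in markers:
        lo, hi = m.capillary_interval or (None, None)
        rows.append(
            [
                m.marker_id,
                m.primer_combination,
                m.radioactive_size_bp,
                lo,
                hi,
                m.capillary_avg_bp,
                m.chromosome,
                m.bin,
                m.phase,
            ]
        )
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_marker_table(path) -> list[Marker]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        interval = None
        if pd.notna(r["interval_low"]) and pd.notna(r["interval_high"]):
            interval = (float(r["interval_low"]), float(r["interval_high"]))
        out.append(
            Marker(
                marker_id=str(r["marker_id"]),
                primer_combination=str(r["primer_combination"]),
                radioactive_size_bp=float(r["radioactive_size_bp"])
                if pd.notna(r["radioactive_size_bp"])
                else None,
                capillary_interval=interval,
                capillary_avg_bp=float(r["capillary_avg_bp"])
                if pd.notna(r["capillary_avg_bp"])
                else None,
                chromosome=r["chromosome"] if pd.notna(r["chromosome"]) else None,
                bin=int(r["bin"]) if pd.notna(r["bin"]) else None,
                phase=int(r["phase"]) if pd.notna(r["phase"]) else None,
            )
        )
    return out
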