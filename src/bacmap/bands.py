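"""Fingerprint band file I/O and fingerprint quality control.

Band mobilities are stored internally as positive integers: decimal base-pair
sizes from capillary electrophoresis are multiplied by 10 on read (so 324.1 bp
becomes 3241) and divided by 10 on write.  Sequence-tag ("pseudo-mobility")
fingerprints use their integer IDs unchanged.  All mobilities must fit in an
unsigned 16-bit integer.

The *extended bands file* dialect used here is plain text::

    >CLONE_ID<TAB>N_BANDS
    324.1<TAB>1500
    ...

one ``>`` header per clone followed by ``N_BANDS`` two-column rows of
mobility (decimal bp) and peak height.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

MOBILITY_MAX = 65535

#: window limits in 0.1-bp units, inclusive at both ends
DEFAULT_WINDOW = (100.0, 650.0)


class BandsParseError(ValueError):
    """Raised on malformed bands files; message names the offending line."""


@dataclass
class BandFingerprint:
    """A clone's fingerprint: sorted integer band mobilities.

    ``raw_bands`` optionally keeps the unclipped band list after windowing so
    that markers outside the alignment window can still be looked up.
    """

    clone_id: str
    bands: list[int]
    heights: list[int] | None = None
    source_library: str = ""
    flags: set[str] = field(default_factory=set)
    raw_bands: list[int] | None = None

    def __post_init__(self) -> None:
        self.bands = sorted(int(b) for b in self.bands)
        for b in self.bands:
            if not (0 < b <= MOBILITY_MAX):
                raise ValueError(
                    f"{self.clone_id}: mobility {b} outside (0, {MOBILITY_MAX}]"
                )
        if self.heights is not None and len(self.heights) != len(self.bands):
            raise ValueError(f"{self.clone_id}: heights length mismatch")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def all_bands(self) -> list[int]:
        """Band list including any clipped-out bands (for marker lookup)."""
        return self.raw_bands if self.raw_bands is not None else self.bands


@dataclass
class QCParams:
    window_bp: tuple[float, float] = DEFAULT_WINDOW
    min_bands: int = 10
    max_bands: int = 100
    profile_match_threshold: float = 0.8
    neighbour_shared_fraction: float = 0.8
    profile_tolerance: int = 5

    def __post_init__(self) -> None:
        if self.min_bands >= self.max_bands:
            raise ValueError("min_bands must be < max_bands")
        if self.window_bp[0] >= self.window_bp[1]:
            raise ValueError("window min must be < window max")
        for t in (self.profile_match_threshold, self.neighbour_shared_fraction):
            if not (0 < t <= 1):
                raise ValueError("thresholds must be in (0, 1]")


def read_bands_file(path) -> list[BandFingerprint]:
    """Parse an extended bands file; decimal bp are scaled x10 to integers."""
    fps: list[BandFingerprint] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.startswith(">"):
            raise BandsParseError(f"line {i}: expected clone header, got {line!r}")
        parts = line[1:].split()
        if len(parts) != 2:
            raise BandsParseError(f"line {i}: malformed header {line!r}")
        clone_id, n_str = parts
        if clone_id in seen:
            raise BandsParseError(f"line {i}: duplicate clone id {clone_id!r}")
        seen.add(clone_id)
        try:
            n = int(n_str)
        except ValueError as exc:
            raise BandsParseError(f"line {i}: bad band count {n_str!r}") from exc
        bands: list[int] = []
        heights: list[int] = []
        for _ in range(n):
            if i >= len(lines):
                raise BandsParseError(f"line {i}: truncated record for {clone_id}")
            row = lines[i].split()
            i += 1
            if len(row) != 2:
                raise BandsParseError(f"line {i}: malformed band row {lines[i - 1]!r}")
            try:
                mob = round(float(row[0]) * 10)
                height = int(row[1])
            except ValueError as exc:
                raise BandsParseError(
                    f"line {i}: non-numeric band row {lines[i - 1]!r}"
                ) from exc
            bands.append(mob)
            heights.append(height)
        order = sorted(range(len(bands)), key=bands.__getitem__)
        fps.append(
            BandFingerprint(
                clone_id,
                [bands[j] for j in order],
                heights=[heights[j] for j in order],
            )
        )
    return fps


def write_bands_file(fps: Iterable[BandFingerprint], path) -> None:
    with open(path, "w") as fh:
        for fp in fps:
            fh.write(f">{fp.clone_id}\t{fp.n_bands}\n")
            heights = fp.heights or [0] * fp.n_bands
            for mob, h in zip(fp.bands, heights):
                fh.write(f"{mob / 10:.1f}\t{h}\n")


def preprocess(
    fps: Sequence[BandFingerprint], params: QCParams | None = None
) -> tuple[list[BandFingerprint], dict[str, int]]:
    """Clip bands to the size window and drop band-count outliers.

    Returns the kept fingerprints (with ``raw_bands`` preserved) and an
    exclusion report whose counts sum to ``len(fps) - len(kept)``.
    """
    params = params or QCParams()
    lo = round(params.window_bp[0] * 10)
    hi = round(params.window_bp[1] * 10)
    kept: list[BandFingerprint] = []
    report = {"too_few_bands": 0, "too_many_bands": 0}
    for fp in fps:
        raw = fp.all_bands()
        idx = [j for j, b in enumerate(fp.bands) if lo <= b <= hi]
        clipped = [fp.bands[j] for j in idx]
        heights = [fp.heights[j] for j in idx] if fp.heights else None
        if len(clipped) < params.min_bands:
            report["too_few_bands"] += 1
            fp.flags.add("excluded")
            continue
        if len(clipped) > params.max_bands:
            report["too_many_bands"] += 1
            fp.flags.add("excluded")
            continue
        kept.append(
            replace(fp, bands=clipped, heights=heights, raw_bands=list(raw))
        )
    return kept, report


def exclusion_details(
    fps: Sequence[BandFingerprint], params: QCParams | None = None
) -> list[tuple[str, str]]:
    """Per-clone exclusion reasons, consistent with :func:`preprocess`."""
    params = params or QCParams()
    lo = round(params.window_bp[0] * 10)
    hi = round(params.window_bp[1] * 10)
    out = []
    for fp in fps:
        n = sum(1 for b in fp.bands if lo <= b <= hi)
        if n < params.min_bands:
            out.append((fp.clone_id, "too_few_bands"))
        elif n > params.max_bands:
            out.append((fp.clone_id, "too_many_bands"))
    return out


def _well_coords(well: str) -> tuple[int, int]:
    row = ord(well[0].upper()) - ord("A")
    col = int(well[1:]) - 1
    return row, col


def _shared_count(b1: Sequence[int], b2: Sequence[int], tol: int) -> int:
    """Greedy one-to-one count of bands matching within +-tol."""
    from .assembly import match_bands

    return len(match_bands(list(b1), list(b2), tol))


def detect_contaminations(
    fps: Sequence[BandFingerprint],
    layout: Mapping[str, tuple[int, str]],
    reference_profiles: Mapping[str, Sequence[int]] | None = None,
    params: QCParams | None = None,
) -> dict[str, set[str]]:
    """Flag chloroplast/artefact profile matches and neighbour-well mixing.

    ``layout`` maps clone_id to (plate, well).  A fingerprint is flagged with
    a profile's name when >= ``profile_match_threshold`` of the profile bands
    are present within ``profile_tolerance`` units.  Two wells on the same
    plate at Chebyshev distance 1 sharing >= ``neighbour_shared_fraction`` of
    the smaller fingerprint's bands are both flagged ``contaminated``.
    """
    params = params or QCParams()
    reference_profiles = reference_profiles or {}
    flags: dict[str, set[str]] = {}

    for fp in fps:
        if fp.clone_id not in layout:
            raise KeyError(f"no plate layout entry for clone {fp.clone_id}")
        for name, profile in reference_profiles.items():
            if not profile:
                continue
            hit = _shared_count(fp.bands, sorted(profile), params.profile_tolerance)
            if hit / len(profile) >= params.profile_match_threshold:
                flags.setdefault(fp.clone_id, set()).add(name)

    by_pos: dict[tuple[int, int, int], BandFingerprint] = {}
    for fp in fps:
        plate, well = layout[fp.clone_id]
        row, col = _well_coords(well)
        by_pos[(plate, row, col)] = fp
    for (plate, row, col), fp in by_pos.items():
        if not fp.bands:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                other = by_pos.get((plate, row + dr, col + dc))
                if other is None or other.clone_id <= fp.clone_id:
                    continue
                if not other.bands:
                    continue
                n_small = min(fp.n_bands, other.n_bands)
                shared = _shared_count(fp.bands, other.bands, params.profile_tolerance)
                if shared / n_small >= params.neighbour_shared_fraction:
                    flags.setdefault(fp.clone_id, set()).add("contaminated")
                    flags.setdefault(other.clone_id, set()).add("contaminated")
    return flags


def apply_linear_recalibration(
    fp: BandFingerprint, slope: float = 1.0, intercept: float = 0.0
) -> BandFingerprint:
    """Optional per-file systematic sizing-error correction hook."""
    new = [max(1, min(MOBILITY_MAX, round(slope * b + intercept))) for b in fp.bands]
    return replace(fp, bands=new)
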