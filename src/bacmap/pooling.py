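"""Random k-sets superpool design, deconvolution and performance simulation.

Each quarter-plate pool (QPP) is pipetted into a unique set of k superpools;
a marker's positive superpools are deconvoluted back into candidate QPPs
(those whose k-set is contained in the positives) and resolved QPPs (those
candidates that own a positive superpool no other candidate covers and are
therefore necessary to explain the scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_V = 90
DEFAULT_K = 4
DEFAULT_N_QPP = 764

WELL_ROWS = 16  # 384-well plate: rows A..P, columns 1..24
WELL_COLS = 24
QUARTER_SIZE = 96


@dataclass
class PoolingDesign:
    v: int
    k: int
    qpp_ids: list[str]
    assignment: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        seen = set()
        for q in self.qpp_ids:
            ks = self.assignment[q]
            if len(ks) != self.k:
                raise ValueError(f"{q}: k-set size {len(ks)} != k={self.k}")
            if not all(1 <= s <= self.v for s in ks):
                raise ValueError(f"{q}: superpool index out of range")
            if ks in seen:
                raise ValueError(f"duplicate k-set {sorted(ks)}")
            seen.add(ks)

    @property
    def n_qpp(self) -> int:
        return len(self.qpp_ids)

    def loads(self) -> dict[int, int]:
        out = {s: 0 for s in range(1, self.v + 1)}
        for ks in self.assignment.values():
            for s in ks:
                out[s] += 1
        return out

    def matrix(self) -> np.ndarray:
        """Boolean n_qpp x v membership matrix (row order = qpp_ids)."""
        m = np.zeros((self.n_qpp, self.v), dtype=bool)
        for i, q in enumerate(self.qpp_ids):
            for s in self.assignment[q]:
                m[i, s - 1] = True
        return m

    def apply_corrections(self, corrections: Mapping[str, Iterable[int]]) -> "PoolingDesign":
        """Pipetting-error bookkeeping: override recorded k-sets per QPP."""
        assignment = dict(self.assignment)
        for q, ks in corrections.items():
            if q not in assignment:
                raise KeyError(f"unknown qpp id {q}")
            assignment[q] = frozenset(int(s) for s in ks)
        return PoolingDesign(self.v, self.k, list(self.qpp_ids), assignment)


def generate_design(
    n_qpp: int = DEFAULT_N_QPP,
    v: int = DEFAULT_V,
    k: int = DEFAULT_K,
    seed: int = 0,
    balanced: bool = True,
    qpp_ids: Sequence[str] | None = None,
) -> PoolingDesign:
    """Draw ``n_qpp`` distinct random k-sets of ``v`` superpools.

    With ``balanced`` the per-superpool loads are kept within 1 of each other
    by always drawing from the least-loaded superpools.
    """
    from math import comb

    if comb(v, k) < n_qpp:
        raise ValueError(f"infeasible: C({v},{k}) < {n_qpp}")
    rng = np.random.default_rng(seed)
    if qpp_ids is None:
        qpp_ids = [f"{(i // 4) + 1:03d}Q{(i % 4) + 1}" for i in range(n_qpp)]
    elif len(qpp_ids) != n_qpp:
        raise ValueError("qpp_ids length must equal n_qpp")
    assignment: dict[str, frozenset[int]] = {}
    seen: set[frozenset[int]] = set()
    loads = np.zeros(v, dtype=int)
    for q in qpp_ids:
        for attempt in range(1000):
            if balanced and attempt < 50:
                jitter = rng.random(v)
                order = np.lexsort((jitter, loads))
                ks = frozenset(int(s) + 1 for s in order[:k])
            else:
                # strictly-balanced choices exhausted (tiny designs): any
                # unused random k-set keeps loads within a small drift
                ks = frozenset(int(s) + 1 for s in rng.choice(v, size=k, replace=False))
            if ks not in seen:
                break
        else:
            raise RuntimeError("could not find an unused k-set")
        seen.add(ks)
        assignment[q] = ks
        for s in ks:
            loads[s - 1] += 1
    return PoolingDesign(v, k, list(qpp_ids), assignment)


def write_design(design: PoolingDesign, path) -> None:
    with open(path, "w") as fh:
        for q in design.qpp_ids:
            ks = "\t".join(str(s) for s in sorted(design.assignment[q]))
            fh.write(f"{q}\t{ks}\n")


def read_design(path, v: int = DEFAULT_V) -> PoolingDesign:
    qpp_ids, assignment = [], {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            qpp_ids.append(parts[0])
            assignment[parts[0]] = frozenset(int(s) for s in parts[1:])
    k = len(next(iter(assignment.values())))
    return PoolingDesign(v, k, qpp_ids, assignment)


def quarter_of_well(well: str) -> int:
    """Quarter index 1..4 from the 96-pin replicator interleave.

    The quarter is set by the row/column parity of the well so that e.g.
    well F12 falls in quarter 4.
    """
    row = ord(well[0].upper()) - ord("A")
    col = int(well[1:]) - 1
    if not (0 <= row < WELL_ROWS and 0 <= col < WELL_COLS):
        raise ValueError(f"well {well!r} outside 384-well plate")
    return 1 + 2 * (row % 2) + (col % 2)


def clone_to_qpp(plate: int, well: str) -> str:
    """Quarter-plate pool id, formatted like ``042Q4``."""
    if plate < 1:
        raise ValueError("plate numbers start at 1")
    return f"{plate:03d}Q{quarter_of_well(well)}"


@dataclass
class DeconvolutionResult:
    positive_superpools: frozenset[int]
    candidates: set[str]
    resolved: set[str]
    uncovered_superpools: set[int] = field(default_factory=set)

    @property
    def unresolved(self) -> set[str]:
        return self.candidates - self.resolved


def deconvolute(
    positive_superpools: Iterable[int], design: PoolingDesign
) -> DeconvolutionResult:
    """Candidates are QPPs whose k-set is contained in the positives;
    resolved candidates own at least one positive superpool covered by no
    other candidate."""
    positives = frozenset(int(s) for s in positive_superpools)
    if not positives <= set(range(1, design.v + 1)):
        raise ValueError("positive superpool index out of range")
    candidates = {
        q for q in design.qpp_ids if design.assignment[q] <= positives
    }
    cover: dict[int, int] = {s: 0 for s in positives}
    for q in candidates:
        for s in design.assignment[q]:
            cover[s] += 1
    resolved = {
        q
        for q in candidates
        if any(cover[s] == 1 for s in design.assignment[q])
    }
    uncovered = {s for s, c in cover.items() if c == 0}
    return DeconvolutionResult(positives, candidates, resolved, uncovered)


def simulate_performance(
    design: PoolingDesign,
    n_positive_range: Sequence[int] = range(2, 14),
    reps: int = 1000,
    seed: int = 0,
):
    """Monte-Carlo collapse curve of the design.

    For each n, draw n truly positive QPPs, pool them, deconvolute, and
    classify the candidate list against the truth.  Returns a DataFrame with
    mean resolved, unresolved-true and false-positive counts per n.
    """
    import pandas as pd

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    m = design.matrix()  # n_qpp x v
    rows = []
    for n in n_positive_range:
        res_sum = unres_sum = fp_sum = 0
        for _ in range(reps):
            truth = rng.choice(design.n_qpp, size=n, replace=False)
            pos = m[truth].any(axis=0)  # positive superpools
            cand = ~(m & ~pos).any(axis=1)  # k-set subset of positives
            cover = m[cand].sum(axis=0)
            owns_private = (m[cand] & (cover == 1)).any(axis=1)
            cand_idx = np.flatnonzero(cand)
            resolved = set(cand_idx[owns_private])
            truth_set = set(int(t) for t in truth)
            res_sum += len(resolved)
            unres_sum += len((set(cand_idx) - resolved) & truth_set)
            fp_sum += len(set(cand_idx) - truth_set)
        rows.append(
            {
                "n_positive": n,
                "mean_resolved": res_sum / reps,
                "mean_unresolved_true": unres_sum / reps,
                "mean_false_positive": fp_sum / reps,
            }
        )
    return pd.DataFrame(rows)
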