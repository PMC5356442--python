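"""Collapse sequencing-error barcodes into parent clones.

Point mutations introduced during PCR and sequencing scatter reads into a
cloud of near-neighbour sequences around each true barcode.  Because true
barcodes are far apart in Hamming space (random 14-mers average 10.5
mismatches) while error sequences sit within a few mismatches of their
parent, reads can be re-assigned by an iterative, abundance-ranked merge:
barcodes seen fewer than ``min_count`` times are dropped, then, for
increasing radii d = 1..4, the surviving barcodes are traversed in
descending abundance and any less-abundant barcode within Hamming distance
d of the current one is absorbed into it (reads summed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "hamming_distance",
    "mean_pairwise_hamming",
    "collapse_barcodes",
    "filter_persistent",
    "CollapseReport",
]

_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(
            f"hamming_distance requires equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def _encode(barcodes: Sequence[str]) -> np.ndarray:
    """Encode equal-length DNA strings as a (n, L) uint8 matrix."""
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ValueError(f"barcodes have unequal lengths: {sorted(lengths)}")
    n = len(barcodes)
    length = lengths.pop() if lengths else 0
    out = np.empty((n, length), dtype=np.uint8)
    for i, bc in enumerate(barcodes):
        out[i] = [_BASE_CODE.get(c, 4) for c in bc]
    return out


def mean_pairwise_hamming(barcodes: Sequence[str]) -> float:
    """Mean Hamming distance over all unordered pairs of barcodes.

    For n uniform-random sequences of length L the expectation is 3L/4
    (10.5 for 14-mers), which is the separation that makes error-collapse
    well posed.
    """
    n = len(barcodes)
    if n < 2:
        raise ValueError("mean_pairwise_hamming requires at least 2 barcodes")
    enc = _encode(barcodes)
    # Sum of pairwise distances per position: for each position, pairs that
    # differ = (n choose 2) - sum_b (count_b choose 2).
    total_pairs = n * (n - 1) // 2
    total = 0.0
    for j in range(enc.shape[1]):
        counts = np.bincount(enc[:, j], minlength=5)
        same = (counts * (counts - 1) // 2).sum()
        total += total_pairs - same
    return total / total_pairs


@dataclass
class CollapseReport:
    """Bookkeeping from one collapse run.

    ``parents`` maps each surviving barcode to the list of (child, distance,
    reads) it absorbed; ``merges_per_round`` counts merges at each radius;
    ``discarded_low_count`` tallies barcodes dropped by ``min_count``.
    """

    parents: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    merges_per_round: dict[int, int] = field(default_factory=dict)
    discarded_low_count: int = 0
    discarded_reads: int = 0

    def assignment(self) -> dict[str, str]:
        """Map every input barcode (surviving min_count) to its final parent."""
        out = {}
        for parent, children in self.parents.items():
            out[parent] = parent
            for child, _, _ in children:
                out[child] = parent
        return out


def collapse_barcodes(
    counts: Mapping[str, int],
    max_distance: int = 4,
    min_count: int = 2,
) -> tuple[dict[str, int], CollapseReport]:
    """Merge likely-error barcodes into their parent barcode.

    Barcodes seen fewer than ``min_count`` times are discarded first.  Then
    for each radius d = 1..max_distance in order, barcodes are traversed in
    descending abundance (ties broken lexicographically) and any
    less-abundant, not-yet-merged barcode within Hamming distance d of the
    current barcode is merged into it, summing reads.  A barcode merged in a
    round is removed before the next round; within a round a merged barcode
    cannot absorb others.  Total reads of the surviving input are conserved.
    """
    if not counts:
        raise ValueError("collapse_barcodes requires a non-empty count table")
    report = CollapseReport()
    kept = {bc: c for bc, c in counts.items() if c >= min_count}
    report.discarded_low_count = len(counts) - len(kept)
    report.discarded_reads = sum(counts.values()) - sum(kept.values())
    if not kept:
        return {}, report

    barcodes = list(kept)
    enc = _encode(barcodes)
    reads = np.array([kept[b] for b in barcodes], dtype=np.int64)
    alive = np.ones(len(barcodes), dtype=bool)
    children: dict[int, list[tuple[int, int]]] = {}

    for d in range(1, max_distance + 1):
        idx_alive = np.flatnonzero(alive)
        # order by descending abundance at the start of the round, then
        # lexicographically for reproducible tie-breaks
        order = sorted(idx_alive, key=lambda i: (-reads[i], barcodes[i]))
        rank = {i: r for r, i in enumerate(order)}
        merged_this_round = np.zeros(len(barcodes), dtype=bool)
        n_merges = 0
        for i in order:
            if not alive[i] or merged_this_round[i]:
                continue
            dist = (enc != enc[i]).sum(axis=1)
            cand = np.flatnonzero((dist <= d) & alive & ~merged_this_round)
            for j in cand:
                if j == i or rank[j] <= rank[i]:
                    continue
                reads[i] += reads[j]
                alive[j] = False
                merged_this_round[j] = True
                children.setdefault(i, []).append((j, int(dist[j])))
                n_merges += 1
        report.merges_per_round[d] = n_merges

    collapsed = {barcodes[i]: int(reads[i]) for i in np.flatnonzero(alive)}
    for i in np.flatnonzero(alive):
        kids = [
            (barcodes[j], dist, kept[barcodes[j]]) for j, dist in children.get(i, [])
        ]
        # absorbed barcodes may themselves have absorbed others in an
        # earlier round; flatten so every merged barcode maps to its final
        # parent
        stack = [j for j, _ in children.get(i, [])]
        seen = {j for j, _ in children.get(i, [])}
        while stack:
            k = stack.pop()
            for j, dist in children.get(k, []):
                if j not in seen:
                    seen.add(j)
                    kids.append((barcodes[j], dist, kept[barcodes[j]]))
                    stack.append(j)
        report.parents[barcodes[i]] = kids
    return dict(sorted(collapsed.items())), report


def filter_persistent(
    tables_per_timepoint: Sequence[Iterable[Mapping[str, int]]],
) -> set[str]:
    """Barcodes detected at every time point (in >=1 library of each).

    ``tables_per_timepoint`` is a sequence over time points; each element is
    the collection of count tables (libraries) for that time point.  A
    barcode is retained iff, for every time point, it appears in at least
    one of that time point's libraries.
    """
    if not tables_per_timepoint:
        raise ValueError("filter_persistent requires at least one time point")
    per_t: list[set[str]] = []
    for tables in tables_per_timepoint:
        detected: set[str] = set()
        for table in tables:
            detected.update(table.keys())
        per_t.append(detected)
    return set.intersection(*per_t)
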