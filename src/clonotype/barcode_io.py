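"""Parse, quality-filter, demultiplex and tabulate barcode amplicon reads.

Reads are single-end amplicons with a fixed layout declared in a
:class:`ReadLayout`: a library index, a constant 5' flank, the clonal
barcode, and a constant 3' flank.  Two named quality policies ship with the
module: ``PLASMID_POOL`` (permissive; used when sequencing the barcode
plasmid pool directly) and ``SORTED_CELLS`` (stringent; used for libraries
amplified from sorted cells, which see more PCR cycles and a lower-complexity
template).
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from clonotype.barcode_grouping import hamming_distance

__all__ = [
    "ReadRecord",
    "ReadLayout",
    "LibrarySpec",
    "QualityPolicy",
    "PLASMID_POOL",
    "SORTED_CELLS",
    "BarcodeCountTable",
    "RejectionTally",
    "read_fastq",
    "filter_reads",
    "demultiplex_and_extract",
    "count_barcodes",
    "write_count_table",
    "read_count_table",
]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class ReadLayout:
    """Fixed positional layout of the amplicon read.

    index (index_len bases) | flank_5 | barcode (barcode_len) | flank_3,
    all offsets measured from the start of the read.
    """

    index_len: int
    flank_5: str
    barcode_len: int
    flank_3: str

    @property
    def barcode_start(self) -> int:
        return self.index_len + len(self.flank_5)

    @property
    def min_read_len(self) -> int:
        return self.barcode_start + self.barcode_len + len(self.flank_3)


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    index_sequence: str
    timepoint: int
    """Day index of the sort (0, 7, 14)."""
    state: str
    """Sorted cell state, 'E' (keratin 8/18 high) or 'M' (low)."""
    replicate: int


@dataclass(frozen=True)
class QualityPolicy:
    """Read-acceptance rule on per-base Phred scores.

    A read passes iff (number of bases with Q < low_q_threshold) is
    strictly less than ``max_low_q_bases`` and no base has
    Q < ``min_base_q``.  If ``require_flank_q`` is set, every base of the
    index and both flanks must additionally have Q > that value (checked at
    demultiplexing, where positions are known).
    """

    max_low_q_bases: int
    low_q_threshold: int
    min_base_q: int
    require_flank_q: int | None = None

    def __post_init__(self):
        if self.min_base_q > self.low_q_threshold:
            raise ValueError("min_base_q must be <= low_q_threshold")

    def accepts(self, qualities: Sequence[int]) -> bool:
        n_low = sum(1 for q in qualities if q < self.low_q_threshold)
        if n_low >= self.max_low_q_bases:
            return False
        return min(qualities) >= self.min_base_q


#: Policy for the plasmid-pool run: < 14 bases below Q25, no base below Q10,
#: index/flank bases above Q25.
PLASMID_POOL = QualityPolicy(
    max_low_q_bases=14, low_q_threshold=25, min_base_q=10, require_flank_q=25
)

#: Policy for sorted-cell libraries: < 6 bases below Q25, no base below Q15.
SORTED_CELLS = QualityPolicy(max_low_q_bases=6, low_q_threshold=25, min_base_q=15)


@dataclass
class RejectionTally:
    total: int = 0
    accepted: int = 0
    reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.total += 1
        self.reasons[reason] += 1

    def accept(self) -> None:
        self.total += 1
        self.accepted += 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "accepted": self.accepted,
                "rejected": self.total - self.accepted,
                "reasons": dict(self.reasons),
            },
            indent=2,
        )


class BarcodeCountTable(dict):
    """library_id -> {barcode -> read count}."""

    def write_tsv(self, path: str | Path) -> None:
        write_count_table(self, path)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (possibly gzipped) FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield ReadRecord(
                    read_id=title.split()[0],
                    sequence=seq.upper(),
                    qualities=tuple(ord(c) - 33 for c in qual),
                )
        except ValueError as exc:  # malformed record
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def filter_reads(
    reads: Iterable[ReadRecord],
    policy: QualityPolicy,
    tally: RejectionTally | None = None,
) -> Iterator[ReadRecord]:
    """Yield reads passing the base-quality policy; rejections are tallied.

    Filtering is idempotent: a stream that passed once passes unchanged.
    """
    if tally is None:
        tally = RejectionTally()
    for read in reads:
        n_low = sum(1 for q in read.qualities if q < policy.low_q_threshold)
        if n_low >= policy.max_low_q_bases:
            tally.reject("too_many_low_q")
            continue
        if min(read.qualities) < policy.min_base_q:
            tally.reject("base_below_min_q")
            continue
        tally.accept()
        yield read


def _validate_specs(specs: Sequence[LibrarySpec]) -> None:
    seen: dict[str, str] = {}
    for spec in specs:
        if spec.index_sequence in seen:
            raise ValueError(
                f"libraries {seen[spec.index_sequence]} and {spec.library_id} "
                f"share index {spec.index_sequence}"
            )
        seen[spec.index_sequence] = spec.library_id
    indexes = list(seen)
    for i in range(len(indexes)):
        for j in range(i + 1, len(indexes)):
            if hamming_distance(indexes[i], indexes[j]) < 2:
                raise ValueError(
                    f"index sequences {indexes[i]} and {indexes[j]} differ by "
                    "fewer than 2 bases"
                )


def demultiplex_and_extract(
    reads: Iterable[ReadRecord],
    specs: Sequence[LibrarySpec],
    layout: ReadLayout,
    policy: QualityPolicy | None = None,
    tally: RejectionTally | None = None,
) -> dict[str, list[str]]:
    """Assign reads to libraries by exact index match and excise barcodes.

    Index matching is exact: indexes are designed >= 2 mismatches apart and
    no 1-mismatch rescue is attempted.  Both flanks must match exactly.
    When ``policy.require_flank_q`` is set, every index/flank base must have
    quality above it.  Returns library_id -> list of barcode strings;
    unassigned reads are tallied.
    """
    _validate_specs(specs)
    if tally is None:
        tally = RejectionTally()
    by_index = {spec.index_sequence: spec for spec in specs}
    index_len = layout.index_len
    for spec in specs:
        if len(spec.index_sequence) != index_len:
            raise ValueError(
                f"library {spec.library_id}: index length != layout.index_len"
            )
    out: dict[str, list[str]] = {spec.library_id: [] for spec in specs}
    bc_start = layout.barcode_start
    bc_end = bc_start + layout.barcode_len
    f3_end = bc_end + len(layout.flank_3)
    for read in reads:
        if len(read.sequence) < layout.min_read_len:
            tally.reject("too_short")
            continue
        spec = by_index.get(read.sequence[:index_len])
        if spec is None:
            tally.reject("no_index_match")
            continue
        if (
            read.sequence[index_len:bc_start] != layout.flank_5
            or read.sequence[bc_end:f3_end] != layout.flank_3
        ):
            tally.reject("flank_mismatch")
            continue
        if policy is not None and policy.require_flank_q is not None:
            fixed_q = (
                read.qualities[:bc_start] + read.qualities[bc_end:f3_end]
            )
            if min(fixed_q) <= policy.require_flank_q:
                tally.reject("flank_low_q")
                continue
        tally.accept()
        out[spec.library_id].append(read.sequence[bc_start:bc_end])
    return out


def count_barcodes(barcodes_by_library: Mapping[str, Iterable[str]]) -> BarcodeCountTable:
    """Exact multiset counting per library, barcodes in lexicographic order."""
    table = BarcodeCountTable()
    for library_id, barcodes in barcodes_by_library.items():
        counts = Counter(barcodes)
        table[library_id] = dict(sorted(counts.items()))
    return table


def write_count_table(table: Mapping[str, Mapping[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\tbarcode\tcount\n")
        for library_id in sorted(table):
            for barcode, count in sorted(table[library_id].items()):
                fh.write(f"{library_id}\t{barcode}\t{count}\n")


def read_count_table(path: str | Path) -> BarcodeCountTable:
    table = BarcodeCountTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["library_id", "barcode", "count"]:
            raise ValueError(f"unexpected count-table header in {path}: {header}")
        for line in fh:
            library_id, barcode, count = line.rstrip("\n").split("\t")
            table.setdefault(library_id, {})[barcode] = int(count)
    return table
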