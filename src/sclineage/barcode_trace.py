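"""Lineage-barcode retrieval from paired scRNA-seq reads.

The expressed cassette is a 48-nt ``bc14 + TGGT + bc30`` string embedded in the
3'UTR of a reporter transcript.  Read 1 carries the droplet cell barcode
(16 nt) and UMI (12 nt); read 2 carries cDNA containing the cassette.  Per
read 2 the TGGT anchor is located (one mismatch allowed), the flanking 14-nt
and 30-nt putative barcodes are extracted and validated against the vendor
whitelists with unique-Hamming-1 correction, and each cell is finally assigned
the most abundant surviving ``bc14:bc30`` pair.
"""

from __future__ import annotations

import gzip
import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

ANCHOR = "TGGT"
BC14_LEN = 14
BC30_LEN = 30
CASSETTE_LEN = BC14_LEN + len(ANCHOR) + BC30_LEN  # 48
CELL_BC_LEN = 16
UMI_LEN = 12

_ALPHABET = "ACGT"


class ShortReadError(ValueError):
    """Read 1 too short to contain a cell barcode and UMI."""


@dataclass(frozen=True)
class Whitelist:
    """Legal bc14 / bc30 vocabularies plus the constant anchor.

    ``bc14`` and ``bc30`` keep the vendor file order (useful for composing
    cassettes); membership tests go through the frozen sets.
    """

    bc14: tuple[str, ...]
    bc30: tuple[str, ...]
    anchor: str = ANCHOR

    def __post_init__(self) -> None:
        for seqs, length, name in ((self.bc14, BC14_LEN, "bc14"), (self.bc30, BC30_LEN, "bc30")):
            if not seqs:
                raise ValueError(f"empty {name} vocabulary")
            if len(set(seqs)) != len(seqs):
                raise ValueError(f"duplicate entries in {name} vocabulary")
            for s in seqs:
                if len(s) != length or any(c not in _ALPHABET for c in s):
                    raise ValueError(f"invalid {name} entry {s!r}")
        object.__setattr__(self, "_bc14_set", frozenset(self.bc14))
        object.__setattr__(self, "_bc30_set", frozenset(self.bc30))

    @property
    def bc14_set(self) -> frozenset:
        return self._bc14_set

    @property
    def bc30_set(self) -> frozenset:
        return self._bc30_set

    def cassette(self, i14: int, i30: int) -> str:
        """Compose the 48-nt cassette for whitelist entries ``i14``, ``i30``."""
        return self.bc14[i14] + self.anchor + self.bc30[i30]

    def lineage_id(self, i14: int, i30: int) -> str:
        return f"{self.bc14[i14]}:{self.bc30[i30]}"

    # -- IO ---------------------------------------------------------------
    def write(self, bc14_path: str | Path, bc30_path: str | Path) -> None:
        Path(bc14_path).write_text("\n".join(self.bc14) + "\n")
        Path(bc30_path).write_text("\n".join(self.bc30) + "\n")

    @classmethod
    def read(cls, bc14_path: str | Path, bc30_path: str | Path) -> "Whitelist":
        bc14 = tuple(Path(bc14_path).read_text().split())
        bc30 = tuple(Path(bc30_path).read_text().split())
        return cls(bc14, bc30)


@dataclass(frozen=True)
class CassetteHit:
    """A validated cassette extracted from one read 2."""

    bc14: str
    bc30: str
    anchor_mismatches: int
    bc14_corrected: bool
    bc30_corrected: bool

    @property
    def lineage_id(self) -> str:
        return f"{self.bc14}:{self.bc30}"


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def find_anchor(seq: str, anchor: str = ANCHOR,
                min_left: int = BC14_LEN, min_right: int = BC30_LEN) -> Optional[int]:
    """Locate the anchor in a read-2 sequence.

    Only positions leaving at least ``min_left`` nt upstream and ``min_right``
    nt downstream are valid (otherwise no barcode pair can be extracted).
    Exact occurrences win over single-mismatch ones; ties go to the leftmost
    valid position.  Returns the 0-based start or ``None``.
    """
    k = len(anchor)
    lo, hi = min_left, len(seq) - k - min_right  # inclusive bounds
    if hi < lo:
        return None
    # exact pass via str.find
    p = seq.find(anchor, lo)
    while p != -1:
        if p <= hi:
            return p
        p = seq.find(anchor, p + 1)
    # one-mismatch pass
    for p in range(lo, hi + 1):
        window = seq[p:p + k]
        if sum(a != b for a, b in zip(window, anchor)) <= 1:
            return p
    return None


def correct_barcode(putative: str, vocabulary) -> Optional[str]:
    """Whitelist-validate a putative barcode with unique-Hamming-1 correction.

    Returns ``putative`` itself when already in the vocabulary, the unique
    vocabulary member at Hamming distance 1 otherwise, and ``None`` when zero
    or two-or-more members lie at distance 1 (ambiguous corrections are
    rejected rather than guessed).
    """
    vocabulary = vocabulary if isinstance(vocabulary, (set, frozenset)) else set(vocabulary)
    some = next(iter(vocabulary))
    if len(putative) != len(some):
        raise ValueError(f"barcode length {len(putative)} does not match vocabulary length {len(some)}")
    if putative in vocabulary:
        return putative
    hit: Optional[str] = None
    for i, orig in enumerate(putative):
        for base in _ALPHABET:
            if base == orig:
                continue
            neighbor = putative[:i] + base + putative[i + 1:]
            if neighbor in vocabulary:
                if hit is not None:
                    return None  # second distance-1 member: ambiguous
                hit = neighbor
    return hit


def parse_read(read2: str, wl: Whitelist) -> Optional[CassetteHit]:
    """Extract and validate the cassette from one read-2 sequence.

    Acceptance follows the sequential rule: whitelisted pairs pass as-is; if
    exactly one half is absent it alone is corrected; if both are absent the
    bc14 is corrected first and the bc30 is attempted only when that succeeds.
    Reads whose halves cannot be uniquely corrected yield ``None``.
    """
    p = find_anchor(read2, wl.anchor)
    if p is None:
        return None
    put14 = read2[p - BC14_LEN:p]
    put30 = read2[p + len(wl.anchor):p + len(wl.anchor) + BC30_LEN]
    mism = sum(a != b for a, b in zip(read2[p:p + len(wl.anchor)], wl.anchor))

    in14 = put14 in wl.bc14_set
    in30 = put30 in wl.bc30_set
    if in14 and in30:
        return CassetteHit(put14, put30, mism, False, False)
    if in14 != in30:  # exactly one absent
        if in14:
            fixed30 = correct_barcode(put30, wl.bc30_set)
            if fixed30 is None:
                return None
            return CassetteHit(put14, fixed30, mism, False, True)
        fixed14 = correct_barcode(put14, wl.bc14_set)
        if fixed14 is None:
            return None
        return CassetteHit(fixed14, put30, mism, True, False)
    # both absent: bc14 first, bc30 only on success
    fixed14 = correct_barcode(put14, wl.bc14_set)
    if fixed14 is None:
        return None
    fixed30 = correct_barcode(put30, wl.bc30_set)
    if fixed30 is None:
        return None
    return CassetteHit(fixed14, fixed30, mism, True, True)


def extract_cell_umi(read1: str) -> tuple[str, str]:
    """Split read 1 into (16-nt cell barcode, 12-nt UMI); trailing bases ignored."""
    if len(read1) < CELL_BC_LEN + UMI_LEN:
        raise ShortReadError(f"read 1 of length {len(read1)} < {CELL_BC_LEN + UMI_LEN}")
    return read1[:CELL_BC_LEN], read1[CELL_BC_LEN:CELL_BC_LEN + UMI_LEN]


def assign_lineages(records: Iterable[tuple[str, str, str]]) -> pd.DataFrame:
    """Assign each cell the most abundant lineage barcode.

    ``records`` is a stream of ``(cell, umi, lineage_id)`` triples.  Abundance
    is the number of distinct UMIs supporting a lineage within a cell (PCR
    deduplication); ties break by read count, then by lexicographically
    smallest lineage id with the ``ambiguous`` flag set.  The result is
    independent of record order.
    """
    umis: dict[tuple[str, str], set] = defaultdict(set)
    reads: dict[tuple[str, str], int] = defaultdict(int)
    for cell, umi, lineage in records:
        umis[(cell, lineage)].add(umi)
        reads[(cell, lineage)] += 1

    per_cell: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for (cell, lineage), s in umis.items():
        per_cell[cell].append((lineage, len(s), reads[(cell, lineage)]))

    rows = []
    for cell in sorted(per_cell):
        cand = sorted(per_cell[cell], key=lambda t: (-t[1], -t[2], t[0]))
        lineage, u, r = cand[0]
        runner_up = cand[1][1] if len(cand) > 1 else 0
        ambiguous = len(cand) > 1 and cand[1][1] == u and cand[1][2] == r
        rows.append((cell, lineage, u, r, runner_up, ambiguous))
    return pd.DataFrame(
        rows,
        columns=["cell", "lineage", "umi_support", "read_support", "runner_up_support", "ambiguous"],
    ).set_index("cell")


# ---------------------------------------------------------------------------
# End-to-end FASTQ tracing
# ---------------------------------------------------------------------------

def _fastq_records(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (title, sequence) from a FASTQ(.gz) file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            title = fh.readline()
            if not title:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # +
            fh.readline()  # qualities
            yield title.rstrip("\n"), seq


def trace_fastq(r1_path: str | Path, r2_path: str | Path,
                wl: Whitelist) -> tuple[pd.DataFrame, dict]:
    """Run the full retrieval on paired FASTQ files.

    Returns the cell->lineage assignment table and a statistics dict
    (reads seen, anchors found, corrected halves, rejected reads, short
    read-1 records skipped).
    """
    stats = {
        "reads": 0,
        "short_read1": 0,
        "anchor_found": 0,
        "bc14_corrected": 0,
        "bc30_corrected": 0,
        "rejected": 0,
        "accepted": 0,
    }

    def records() -> Iterator[tuple[str, str, str]]:
        for (_, r1), (_, r2) in zip(_fastq_records(r1_path), _fastq_records(r2_path)):
            stats["reads"] += 1
            try:
                cell, umi = extract_cell_umi(r1)
            except ShortReadError:
                stats["short_read1"] += 1
                continue
            hit = parse_read(r2, wl)
            if find_anchor(r2, wl.anchor) is not None:
                stats["anchor_found"] += 1
            if hit is None:
                stats["rejected"] += 1
                continue
            stats["accepted"] += 1
            stats["bc14_corrected"] += int(hit.bc14_corrected)
            stats["bc30_corrected"] += int(hit.bc30_corrected)
            yield cell, umi, hit.lineage_id

    table = assign_lineages(records())
    return table, stats


def write_trace_outputs(table: pd.DataFrame, stats: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "cell_lineage.tsv", sep="\t")
    (outdir / "trace_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
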