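"""Overlap-based merging of read pairs and post-merge length filtering.

The merger is FLASH-style: mate 2 is reverse-complemented, every candidate
overlap of at least ``min_overlap`` bases is scored by mismatch density, and
the best (lowest density, ties broken toward the longer overlap) wins if its
density does not exceed ``max_mismatch_density``.  Within the overlap the
consensus base is the one with the higher quality score, ties going to mate 1.
Merged reads shorter than 300 b are then excluded, as are pairs with no
acceptable overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .simulate import revcomp

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_DENSITY = 0.25
DEFAULT_MIN_LENGTH = 300


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_len: int
    mismatch_count: int


@dataclass
class QCReport:
    n_input: int = 0
    n_merged: int = 0
    n_kept: int = 0

    @property
    def n_merge_rejected(self) -> int:
        return self.n_input - self.n_merged

    @property
    def n_length_filtered(self) -> int:
        return self.n_merged - self.n_kept

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            fh.write(f"input_pairs\t{self.n_input}\n")
            fh.write(f"merged\t{self.n_merged}\n")
            fh.write(f"merge_rejected\t{self.n_merge_rejected}\n")
            fh.write(f"kept\t{self.n_kept}\n")
            fh.write(f"length_filtered\t{self.n_length_filtered}\n")


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_density: float = DEFAULT_MAX_MISMATCH_DENSITY,
) -> MergedRead | None:
    """Merge one pair by best overlap; ``None`` means rejection.

    Candidate overlaps place the reverse-complemented mate 2 so that its
    prefix overlaps the suffix of mate 1 (the amplicon is assumed no shorter
    than either read).  The overlap minimizing mismatch density wins, with
    ties resolved toward the longer overlap.
    """
    if not pair.seq1 or not pair.seq2:
        raise ValueError(f"read {pair.id}: empty mate sequence")
    s1 = pair.seq1.upper()
    s2 = revcomp(pair.seq2.upper())
    q2 = pair.qual2[::-1]

    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)

    best: tuple[float, int, int] | None = None  # (density, overlap, mismatches)
    max_o = min(len(s1), len(s2))
    for o in range(min_overlap, max_o + 1):
        mism = int((a1[len(s1) - o :] != a2[:o]).sum())
        density = mism / o
        if density > max_mismatch_density:
            continue
        if best is None or density < best[0] or (density == best[0] and o > best[1]):
            best = (density, o, mism)
    if best is None:
        return None

    _, o, mism = best
    head = s1[: len(s1) - o]
    tail = s2[o:]
    consensus = []
    cons_qual = []
    for k in range(o):
        i1 = len(s1) - o + k
        b1, b2 = s1[i1], s2[k]
        c1, c2 = pair.qual1[i1], q2[k]
        if b1 == b2:
            consensus.append(b1)
            cons_qual.append(max(c1, c2))
        elif c2 > c1:  # strictly higher quality on mate 2; ties -> mate 1
            consensus.append(b2)
            cons_qual.append(c2)
        else:
            consensus.append(b1)
            cons_qual.append(c1)
    merged_seq = head + "".join(consensus) + tail
    merged_qual = pair.qual1[: len(s1) - o] + "".join(cons_qual) + q2[o:]
    return MergedRead(
        id=pair.id,
        seq=merged_seq,
        qual=merged_qual,
        overlap_len=o,
        mismatch_count=mism,
    )


def filter_reads(
    reads: Iterable[MergedRead],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mean_quality: float | None = None,
) -> tuple[list[MergedRead], QCReport]:
    """Keep merged reads of length >= min_length (300 b default).

    ``min_mean_quality`` (Phred) is an optional extra filter, off by default.
    The report only tracks counts of the reads passed in (n_input is set by
    the caller when it also saw unmerged pairs).
    """
    kept = []
    report = QCReport()
    for read in reads:
        report.n_input += 1
        report.n_merged += 1
        if len(read.seq) < min_length:
            continue
        if min_mean_quality is not None:
            mean_q = np.mean([ord(c) - 33 for c in read.qual])
            if mean_q < min_mean_quality:
                continue
        kept.append(read)
        report.n_kept += 1
    return kept, report


def parse_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files (plain text, same order)."""
    with open(r1_path) as f1, open(r2_path) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline()
            q1 = f1.readline().strip()
            h2 = f2.readline()
            if not h2:
                raise ValueError("R2 file truncated relative to R1")
            s2 = f2.readline().strip()
            f2.readline()
            q2 = f2.readline().strip()
            rid = h1.strip()[1:].split()[0]
            if rid.endswith("/1"):
                rid = rid[:-2]
            yield ReadPair(id=rid, seq1=s1, qual1=q1, seq2=s2, qual2=q2)


def merge_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_density: float = DEFAULT_MAX_MISMATCH_DENSITY,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[MergedRead], QCReport]:
    """Merge + length-filter a FASTQ pair; report counts every pair seen."""
    report = QCReport()
    kept: list[MergedRead] = []
    for pair in parse_fastq_pairs(r1_path, r2_path):
        report.n_input += 1
        merged = merge_pair(pair, min_overlap, max_mismatch_density)
        if merged is None:
            continue
        report.n_merged += 1
        if len(merged.seq) >= min_length:
            kept.append(merged)
            report.n_kept += 1
    return kept, report


def write_merged_fastq(reads: Iterable[MergedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")
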