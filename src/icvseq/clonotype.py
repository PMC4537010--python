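"""Clonotyping by exact CDR3 identity, replicate concordance filtering,
dominant-clone calling and intra-clonotype variant enumeration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotate import AnnotatedRead
from ._util import round_half_up

DEFAULT_MIN_FREQ_EACH_REPLICATE = 0.01  # percent
DEFAULT_MIN_COUNT_EACH_REPLICATE = 2
DEFAULT_DOMINANT_THRESHOLD = 5.0  # percent; 7.8 recommended for MM calling
MM_RECOMMENDED_THRESHOLD = 7.8


@dataclass
class Clonotype:
    """Reads sharing one exact CDR3 nucleotide sequence."""

    cdr3_nt: str
    count_repA: int
    count_repB: int
    freq_pct: float  # of all CDR3-bearing assigned reads (both replicates)
    v_call: str  # plurality germline allele call
    members: list[AnnotatedRead] = field(default_factory=list, repr=False)

    @property
    def count_total(self) -> int:
        return self.count_repA + self.count_repB


@dataclass
class Variant:
    """One unique V-region sequence within a clonotype."""

    variant_seq: str
    count_repA: int
    count_repB: int
    rank: int

    @property
    def count_total(self) -> int:
        return self.count_repA + self.count_repB


@dataclass
class VariantTable:
    cdr3_nt: str
    variants: list[Variant]
    start: int = 0  # germline coordinate of variant_seq column 0
    v_call: str = ""

    @property
    def total_count(self) -> int:
        return sum(v.count_total for v in self.variants)

    def top_n(self, n: int = 10) -> "VariantTable":
        return VariantTable(
            cdr3_nt=self.cdr3_nt,
            variants=self.variants[:n],
            start=self.start,
            v_call=self.v_call,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [v.rank for v in self.variants],
                "count_total": [v.count_total for v in self.variants],
                "count_repA": [v.count_repA for v in self.variants],
                "count_repB": [v.count_repB for v in self.variants],
                "start": [self.start for _ in self.variants],
                "v_call": [self.v_call for _ in self.variants],
                "variant_seq": [v.variant_seq for v in self.variants],
            }
        )

    @classmethod
    def from_tsv(cls, path: str | Path, cdr3_nt: str = "") -> "VariantTable":
        df = pd.read_csv(path, sep="\t")
        variants = [
            Variant(
                variant_seq=row.variant_seq,
                count_repA=int(row.count_repA),
                count_repB=int(row.count_repB),
                rank=int(row.rank),
            )
            for row in df.itertuples()
        ]
        start = int(df["start"].iloc[0]) if len(df) else 0
        v_call = str(df["v_call"].iloc[0]) if len(df) else ""
        return cls(cdr3_nt=cdr3_nt, variants=variants, start=start, v_call=v_call)


def group_by_cdr3(reads: Iterable[AnnotatedRead]) -> tuple[list[Clonotype], int]:
    """Group assigned, CDR3-bearing reads into clonotypes by exact CDR3 match.

    Returns the clonotype table (sorted by total count descending, ties by
    CDR3 string) and the number of reads excluded for lacking an assignment
    or a CDR3.  Frequencies are percentages of all included reads.
    """
    groups: dict[str, list[AnnotatedRead]] = {}
    n_excluded = 0
    for read in reads:
        if not read.assigned or read.cdr3_nt is None:
            n_excluded += 1
            continue
        groups.setdefault(read.cdr3_nt, []).append(read)
    total = sum(len(members) for members in groups.values())
    clonotypes = []
    for cdr3, members in groups.items():
        count_a = sum(1 for m in members if m.replicate == "A")
        count_b = len(members) - count_a
        v_counts: dict[str, int] = {}
        for m in members:
            v_counts[m.allele] = v_counts.get(m.allele, 0) + 1
        v_call = max(sorted(v_counts), key=lambda k: v_counts[k])
        clonotypes.append(
            Clonotype(
                cdr3_nt=cdr3,
                count_repA=count_a,
                count_repB=count_b,
                freq_pct=100.0 * len(members) / total if total else 0.0,
                v_call=v_call,
                members=members,
            )
        )
    clonotypes.sort(key=lambda c: (-c.count_total, c.cdr3_nt))
    return clonotypes, n_excluded


def concordance_filter(
    clonotypes: Sequence[Clonotype],
    min_freq_each_replicate: float = DEFAULT_MIN_FREQ_EACH_REPLICATE,
    min_count_each_replicate: int = DEFAULT_MIN_COUNT_EACH_REPLICATE,
) -> list[Clonotype]:
    """Retain clonotypes present at sufficient frequency in BOTH replicates.

    A clonotype passes when, in each replicate separately, its frequency
    (percent of that replicate's reads over all clonotypes) is >= the
    threshold and its count is >= min_count_each_replicate.  Frequencies of
    the survivors are recomputed over the retained reads.
    """
    total_a = sum(c.count_repA for c in clonotypes)
    total_b = sum(c.count_repB for c in clonotypes)
    if clonotypes and (total_a == 0 or total_b == 0):
        raise ValueError("one replicate is empty: two technical replicates required")
    kept = []
    for c in clonotypes:
        freq_a = 100.0 * c.count_repA / total_a
        freq_b = 100.0 * c.count_repB / total_b
        if (
            freq_a >= min_freq_each_replicate
            and freq_b >= min_freq_each_replicate
            and c.count_repA >= min_count_each_replicate
            and c.count_repB >= min_count_each_replicate
        ):
            kept.append(c)
    new_total = sum(c.count_total for c in kept)
    for c in kept:
        c.freq_pct = 100.0 * c.count_total / new_total if new_total else 0.0
    return kept


def detect_dominant(
    clonotypes: Sequence[Clonotype],
    threshold_pct: float = DEFAULT_DOMINANT_THRESHOLD,
) -> Clonotype | None:
    """Top clonotype iff its frequency strictly exceeds the threshold.

    Default 5%; 7.8% is the stricter cut-off recommended for calling a tumor
    clone in IgG deep sequencing.  Returns None for diverse (control/normal)
    repertoires.
    """
    if not clonotypes:
        return None
    top = max(clonotypes, key=lambda c: c.freq_pct)
    return top if top.freq_pct > threshold_pct else None


def _variant_key(read: AnnotatedRead, start: int, end: int) -> str:
    """Projection truncated to the clonotype's shared covered interval."""
    return read.v_projection[start - read.aln_start_germ : end - read.aln_start_germ]


def enumerate_variants(clonotype: Clonotype) -> VariantTable:
    """Unique V-region sequences within one clonotype, ranked by read count.

    Variant identity is the germline-coordinate V projection truncated to the
    interval covered by every member, so differing read extents do not split
    variants.  Ties in count are broken by lexicographic sequence.
    """
    members = clonotype.members
    if not members:
        return VariantTable(cdr3_nt=clonotype.cdr3_nt, variants=[])
    start = max(m.aln_start_germ for m in members)
    end = min(m.aln_end_germ for m in members)
    if end < start:
        end = start
    counts: dict[str, list[int]] = {}
    for m in members:
        key = _variant_key(m, start, end)
        pair = counts.setdefault(key, [0, 0])
        pair[0 if m.replicate == "A" else 1] += 1
    ordered = sorted(counts.items(), key=lambda kv: (-(kv[1][0] + kv[1][1]), kv[0]))
    variants = [
        Variant(variant_seq=seq, count_repA=ab[0], count_repB=ab[1], rank=i + 1)
        for i, (seq, ab) in enumerate(ordered)
    ]
    return VariantTable(
        cdr3_nt=clonotype.cdr3_nt,
        variants=variants,
        start=start,
        v_call=clonotype.v_call,
    )


def concordance_filter_variants(
    table: VariantTable,
    total_repA: int,
    total_repB: int,
    min_freq_each_replicate: float = DEFAULT_MIN_FREQ_EACH_REPLICATE,
    min_count_each_replicate: int = DEFAULT_MIN_COUNT_EACH_REPLICATE,
) -> VariantTable:
    """The replicate-concordance rule applied at the variant level.

    ``total_repA/B`` are the per-replicate denominators (all clonotyped reads
    in that replicate).  Survivors are re-ranked.
    """
    if total_repA == 0 or total_repB == 0:
        raise ValueError("one replicate is empty: two technical replicates required")
    kept = [
        v
        for v in table.variants
        if 100.0 * v.count_repA / total_repA >= min_freq_each_replicate
        and 100.0 * v.count_repB / total_repB >= min_freq_each_replicate
        and v.count_repA >= min_count_each_replicate
        and v.count_repB >= min_count_each_replicate
    ]
    kept.sort(key=lambda v: (-v.count_total, v.variant_seq))
    return VariantTable(
        cdr3_nt=table.cdr3_nt,
        variants=[
            Variant(v.variant_seq, v.count_repA, v.count_repB, rank=i + 1)
            for i, v in enumerate(kept)
        ],
        start=table.start,
        v_call=table.v_call,
    )


def germline_usage_summary(clonotypes: Sequence[Clonotype]) -> pd.DataFrame:
    """% of reads per germline gene (alleles collapsed to gene level).

    Suitable for a linear-scale expression bar chart; empty input gives an
    empty table.
    """
    counts: dict[str, int] = {}
    for c in clonotypes:
        gene = c.v_call.split("*", 1)[0]
        counts[gene] = counts.get(gene, 0) + c.count_total
    total = sum(counts.values())
    rows = [
        {"gene": gene, "reads": n, "freq_pct": round_half_up(100.0 * n / total, 1)}
        for gene, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["gene", "reads", "freq_pct"])


def write_clonotype_tsv(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cdr3": [c.cdr3_nt for c in clonotypes],
            "v_call": [c.v_call for c in clonotypes],
            "count_total": [c.count_total for c in clonotypes],
            "count_repA": [c.count_repA for c in clonotypes],
            "count_repB": [c.count_repB for c in clonotypes],
            "freq_pct": [c.freq_pct for c in clonotypes],
        }
    )
    df.to_csv(path, sep="\t", index=False)
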