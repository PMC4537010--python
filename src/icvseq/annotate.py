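"""Germline V-allele assignment, mutation calling, % homology and CDR3 extraction.

Each merged read is aligned semi-globally (free end gaps, so the read's
junction/constant tail and any missing 5' bases are unpenalized) against every
candidate allele; the best-scoring allele wins, ties broken by lexicographic
allele name.  Mutations, % homology over the aligned V span, and the CDR3 —
anchored at the allele's conserved Cys codon and closed by the first in-frame
TGG-GGx J tryptophan — are derived from that alignment.

The alignment is also projected onto germline coordinates (one character per
germline position, deletions as ``-``, insertions dropped), which downstream
modules use for variant identity and gap-free multiple alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import Align

from .germline import GermlineAllele
from .merge import MergedRead
from ._util import round_half_up

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -1
DEFAULT_GAP_OPEN = -6
DEFAULT_GAP_EXTEND = -1
MIN_ALIGNED_BASES = 100
MIN_IDENTITY = 0.5
MAX_GAP_COLUMNS = 3
CDR3_SEARCH_WINDOW = 120

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_region(nt: str) -> str:
    """Translate an in-frame nucleotide string; ambiguity codons become X."""
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not a multiple of 3")
    return "".join(
        CODON_TABLE.get(nt[i : i + 3].upper(), "X") for i in range(0, len(nt), 3)
    )


def classify_mutation(
    germ_codon: str, obs_codon: str
) -> Literal["silent", "replacement", "unknown"]:
    """Silent iff both codons translate to the same amino acid."""
    g = CODON_TABLE.get(germ_codon.upper())
    o = CODON_TABLE.get(obs_codon.upper())
    if g is None or o is None:
        return "unknown"
    return "silent" if g == o else "replacement"


@dataclass
class Mutation:
    pos: int  # 0-based germline coordinate
    germ_base: str
    read_base: str
    codon_index: int
    aa_effect: str

    def __post_init__(self) -> None:
        if self.germ_base == self.read_base:
            raise ValueError("not a substitution: bases equal")


@dataclass
class GermAlignment:
    """Read-vs-allele alignment summary in germline coordinates."""

    allele: str
    score: float
    aln_start_germ: int  # inclusive
    aln_end_germ: int  # exclusive
    matches: int
    projection: str  # one char per germline position in [start, end); '-' = deletion
    n_gap_columns: int
    blocks: tuple[tuple[int, int, int], ...]  # (germ_start, germ_end, read_start)
    n_insertions: int = 0  # read bases inserted between aligned blocks

    @property
    def aligned_span(self) -> int:
        return self.aln_end_germ - self.aln_start_germ

    @property
    def identity(self) -> float:
        """Matches over all alignment columns (span + inserted read bases)."""
        columns = self.aligned_span + self.n_insertions
        return self.matches / columns if columns else 0.0

    def read_pos(self, germ_pos: int) -> int | None:
        """Read coordinate aligned to germ_pos, None if in a deletion."""
        for ts, te, qs in self.blocks:
            if ts <= germ_pos < te:
                return qs + (germ_pos - ts)
        return None


@dataclass
class AnnotatedRead:
    read_id: str
    replicate: str
    allele: str | None
    aln_start_germ: int
    aln_end_germ: int
    mutations: list[Mutation]
    homology_pct: float
    cdr3_nt: str | None
    cdr3_aa: str | None
    v_projection: str
    flags: list[str] = field(default_factory=list)

    @property
    def assigned(self) -> bool:
        return self.allele is not None and "unassignable" not in self.flags


def make_aligner(
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on both sequences (overlap alignment)
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def _summarize_alignment(
    allele: GermlineAllele, read_seq: str, alignment: Align.Alignment
) -> GermAlignment:
    blocks = alignment.aligned  # ((tstart,tend),...), ((qstart,qend),...)
    tblocks, qblocks = blocks[0], blocks[1]
    if len(tblocks) == 0:
        return GermAlignment(allele.name, alignment.score, 0, 0, 0, "", 0, ())
    start = int(tblocks[0][0])
    end = int(tblocks[-1][1])
    proj = ["-"] * (end - start)
    matches = 0
    inserted = 0
    prev_qend: int | None = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_qend is not None:
            inserted += int(qs) - prev_qend
        prev_qend = int(qe)
        for k in range(int(te) - int(ts)):
            base = read_seq[int(qs) + k]
            proj[int(ts) + k - start] = base
            if base == allele.seq[int(ts) + k]:
                matches += 1
    deleted = (end - start) - sum(int(te) - int(ts) for ts, te in tblocks)
    return GermAlignment(
        allele=allele.name,
        score=float(alignment.score),
        aln_start_germ=start,
        aln_end_germ=end,
        matches=matches,
        projection="".join(proj),
        n_gap_columns=deleted + inserted,
        blocks=tuple(
            (int(ts), int(te), int(qs))
            for (ts, te), (qs, _qe) in zip(tblocks, qblocks)
        ),
        n_insertions=inserted,
    )


def assign_germline(
    read: MergedRead,
    alleles: Sequence[GermlineAllele],
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[GermlineAllele, GermAlignment] | None:
    """Best allele by overlap-alignment score; None when below the floor.

    Ties on score are broken by lexicographic allele name.  A best hit with
    <100 aligned germline bases or <50% identity is unassignable.
    """
    if not alleles:
        raise ValueError("at least one germline allele required")
    if aligner is None:
        aligner = make_aligner()
    best: tuple[GermlineAllele, GermAlignment] | None = None
    for allele in sorted(alleles, key=lambda a: a.name):
        alignment = aligner.align(allele.seq, read.seq)[0]
        summary = _summarize_alignment(allele, read.seq, alignment)
        if best is None or summary.score > best[1].score:
            best = (allele, summary)
    assert best is not None
    if best[1].aligned_span < MIN_ALIGNED_BASES or best[1].identity < MIN_IDENTITY:
        return None
    return best


def percent_homology(alignment: GermAlignment) -> float:
    """100 x identical positions / aligned germline span, 1 decimal (half-up).

    Indel columns (deleted germline positions) fall inside the span and count
    as non-identity.
    """
    if alignment.aligned_span == 0:
        raise ValueError("zero aligned length: % homology undefined")
    return round_half_up(100.0 * alignment.matches / alignment.aligned_span, 1)


def call_mutations(allele: GermlineAllele, alignment: GermAlignment) -> list[Mutation]:
    """Substitutions in germline coordinates, with silent/replacement calls.

    The amino-acid effect compares the germline codon with the observed codon
    read off the germline-coordinate projection; codons not fully covered by
    the alignment are classified unknown.
    """
    muts = []
    start = alignment.aln_start_germ
    proj = alignment.projection
    for offset, base in enumerate(proj):
        pos = start + offset
        germ_base = allele.seq[pos]
        if base == "-" or base == germ_base:
            continue
        codon_index = pos // 3
        cstart = codon_index * 3
        effect = "unknown"
        if alignment.aln_start_germ <= cstart and cstart + 3 <= alignment.aln_end_germ:
            obs_codon = proj[cstart - start : cstart + 3 - start]
            if "-" not in obs_codon:
                effect = classify_mutation(allele.seq[cstart : cstart + 3], obs_codon)
        muts.append(
            Mutation(
                pos=pos,
                germ_base=germ_base,
                read_base=base,
                codon_index=codon_index,
                aa_effect=effect,
            )
        )
    return muts


def extract_cdr3(
    read: MergedRead, alignment: GermAlignment, allele: GermlineAllele
) -> str | None:
    """CDR3 from the conserved-Cys codon through the first in-frame TGG-GGx
    tryptophan codon (W inclusive); None when the anchor is missing.

    The J anchor must start within 120 b downstream of the Cys codon.
    """
    cys_read = alignment.read_pos(allele.cys104_pos)
    if cys_read is None:
        return None
    seq = read.seq
    j = cys_read + 3
    while j + 5 <= len(seq) and j - cys_read - 3 <= CDR3_SEARCH_WINDOW:
        if seq[j : j + 3] == "TGG" and seq[j + 3 : j + 5] == "GG":
            return seq[cys_read : j + 3]
        j += 3
    return None


def annotate_read(
    read: MergedRead,
    alleles: Sequence[GermlineAllele],
    replicate: str = "A",
    aligner: Align.PairwiseAligner | None = None,
) -> AnnotatedRead:
    result = assign_germline(read, alleles, aligner)
    if result is None:
        return AnnotatedRead(
            read_id=read.id,
            replicate=replicate,
            allele=None,
            aln_start_germ=0,
            aln_end_germ=0,
            mutations=[],
            homology_pct=0.0,
            cdr3_nt=None,
            cdr3_aa=None,
            v_projection="",
            flags=["unassignable"],
        )
    allele, alignment = result
    flags = []
    if alignment.n_gap_columns > MAX_GAP_COLUMNS:
        flags.append("excess_gaps")
    cdr3 = extract_cdr3(read, alignment, allele)
    cdr3_aa = None
    if cdr3 is not None and len(cdr3) % 3 == 0:
        cdr3_aa = translate_region(cdr3)
    elif cdr3 is None:
        flags.append("cdr3_absent")
    return AnnotatedRead(
        read_id=read.id,
        replicate=replicate,
        allele=allele.name,
        aln_start_germ=alignment.aln_start_germ,
        aln_end_germ=alignment.aln_end_germ,
        mutations=call_mutations(allele, alignment),
        homology_pct=percent_homology(alignment),
        cdr3_nt=cdr3,
        cdr3_aa=cdr3_aa,
        v_projection=alignment.projection,
        flags=flags,
    )


def annotate_reads(
    reads: Iterable[MergedRead],
    alleles: Sequence[GermlineAllele],
    replicate: str = "A",
    aligner: Align.PairwiseAligner | None = None,
) -> list[AnnotatedRead]:
    """Annotate many reads, caching by sequence (deep repertoires are highly
    redundant, so identical reads are aligned once)."""
    if aligner is None:
        aligner = make_aligner()
    cache: dict[str, AnnotatedRead] = {}
    out = []
    for read in reads:
        hit = cache.get(read.seq)
        if hit is None:
            hit = annotate_read(read, alleles, replicate, aligner)
            cache[read.seq] = hit
        out.append(
            AnnotatedRead(
                read_id=read.id,
                replicate=replicate,
                allele=hit.allele,
                aln_start_germ=hit.aln_start_germ,
                aln_end_germ=hit.aln_end_germ,
                mutations=hit.mutations,
                homology_pct=hit.homology_pct,
                cdr3_nt=hit.cdr3_nt,
                cdr3_aa=hit.cdr3_aa,
                v_projection=hit.v_projection,
                flags=list(hit.flags),
            )
        )
    return out


AIRR_COLUMNS = [
    "sequence_id",
    "replicate",
    "v_call",
    "v_identity_pct",
    "v_alignment_start",
    "v_alignment_end",
    "cdr3",
    "cdr3_aa",
    "v_projection",
    "mutations",
    "flags",
]


def write_airr_tsv(reads: Iterable[AnnotatedRead], path: str | Path) -> None:
    """AIRR-C style rearrangement TSV (mutations as a JSON column)."""
    with open(path, "w") as fh:
        fh.write("\t".join(AIRR_COLUMNS) + "\n")
        for r in reads:
            muts = json.dumps(
                [
                    [m.pos, m.germ_base, m.read_base, m.codon_index, m.aa_effect]
                    for m in r.mutations
                ]
            )
            row = [
                r.read_id,
                r.replicate,
                r.allele or "",
                f"{r.homology_pct:.1f}",
                str(r.aln_start_germ),
                str(r.aln_end_germ),
                r.cdr3_nt or "",
                r.cdr3_aa or "",
                r.v_projection,
                muts,
                ",".join(r.flags),
            ]
            fh.write("\t".join(row) + "\n")


def read_airr_tsv(path: str | Path) -> list[AnnotatedRead]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            muts = [
                Mutation(pos=p, germ_base=g, read_base=b, codon_index=c, aa_effect=e)
                for p, g, b, c, e in json.loads(cells[idx["mutations"]])
            ]
            out.append(
                AnnotatedRead(
                    read_id=cells[idx["sequence_id"]],
                    replicate=cells[idx["replicate"]],
                    allele=cells[idx["v_call"]] or None,
                    aln_start_germ=int(cells[idx["v_alignment_start"]]),
                    aln_end_germ=int(cells[idx["v_alignment_end"]]),
                    mutations=muts,
                    homology_pct=float(cells[idx["v_identity_pct"]]),
                    cdr3_nt=cells[idx["cdr3"]] or None,
                    cdr3_aa=cells[idx["cdr3_aa"]] or None,
                    v_projection=cells[idx["v_projection"]],
                    flags=[f for f in cells[idx["flags"]].split(",") if f],
                )
            )
    return out
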