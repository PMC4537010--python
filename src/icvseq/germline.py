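"""Germline IGHV allele references.

An allele is a nucleotide sequence annotated with the 0-based offset of the
conserved CDR3-anchoring cysteine codon (``cys104_pos``).  Alleles are read
from / written to FASTA with a ``;cys104=<int>`` tag appended to the header,
e.g. ``>IGHVS1-1*01;cys104=294``.

A set of four synthetic-but-realistic default alleles (~300 nt, in frame,
conserved TGT at ``cys104_pos``, pairwise >=10 substitutions apart) is built
deterministically at import time so the toolkit runs with no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GermlineAllele:
    """Reference IGHV allele with its conserved-Cys annotation."""

    name: str
    seq: str
    cys104_pos: int

    def __post_init__(self) -> None:
        codon = self.seq[self.cys104_pos : self.cys104_pos + 3]
        if codon not in ("TGT", "TGC"):
            raise ValueError(
                f"allele {self.name}: codon at cys104_pos={self.cys104_pos} "
                f"is {codon!r}, expected TGT/TGC"
            )

    @property
    def gene(self) -> str:
        """Gene name with the allele suffix stripped (IGHV4-39*01 -> IGHV4-39)."""
        return self.name.split("*", 1)[0]

    @property
    def cys_end(self) -> int:
        return self.cys104_pos + 3


def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """In-frame sequence with no stop codons and no TGT/TGC codons."""
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon in _STOPS or codon in ("TGT", "TGC"):
            continue
        codons.append(codon)
    return "".join(codons)


def _mutate_outside_cys(
    rng: np.random.Generator, seq: str, cys_pos: int, n_sub: int
) -> str:
    """Apply n_sub substitutions at distinct positions, sparing the Cys codon."""
    eligible = [i for i in range(len(seq)) if not cys_pos <= i < cys_pos + 3]
    sites = rng.choice(eligible, size=n_sub, replace=False)
    out = list(seq)
    for i in sites:
        out[i] = rng.choice([b for b in _BASES if b != out[i]])
    return "".join(out)


def default_alleles() -> list[GermlineAllele]:
    """Four deterministic IGHV-like alleles, 300 nt, Cys codon at 294."""
    rng = np.random.default_rng(20260905)
    cys_pos = 294
    base = _random_coding_sequence(rng, 98) + "TGT" + _random_coding_sequence(rng, 1)
    assert len(base) == 300 and base[cys_pos : cys_pos + 3] == "TGT"
    names = ["IGHVS1-1*01", "IGHVS2-7*02", "IGHVS3-30*18", "IGHVS4-59*01"]
    alleles = []
    for name in names:
        seq = _mutate_outside_cys(rng, base, cys_pos, 18)
        alleles.append(GermlineAllele(name=name, seq=seq, cys104_pos=cys_pos))
    return alleles


def write_fasta(alleles: list[GermlineAllele], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.seq), id=f"{a.name};cys104={a.cys104_pos}", description="")
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[GermlineAllele]:
    """Parse a germline FASTA whose headers carry the ``;cys104=<int>`` tag."""
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if ";cys104=" not in header:
            raise ValueError(f"germline header {header!r} lacks ';cys104=' tag")
        name, tag = header.split(";cys104=", 1)
        alleles.append(
            GermlineAllele(name=name, seq=str(rec.seq).upper(), cys104_pos=int(tag))
        )
    if not alleles:
        raise ValueError(f"no germline alleles found in {path}")
    return alleles
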