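"""Intraclonal variation (ICV) statistics for the dominant clonotype.

The ICV fraction is the proportion of clonal reads carrying any sequence over
and above the single dominant (rank-1) variant:
100 x (1 - dominant count / total clonal count), reported half-up to one
decimal.  ``variant_burden`` extrapolates that fraction onto an absolute
tumor-cell count.  ``mutation_partition`` splits the mutations observed in
the top variants into the shared trunk set and the variant (ICV) set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .clonotype import VariantTable
from .germline import GermlineAllele
from ._util import round_half_up


def icv_fraction(variant_table: VariantTable) -> float:
    """% of clonal reads not matching the rank-1 variant, 1 decimal half-up."""
    if not variant_table.variants:
        raise ValueError("empty variant table")
    total = variant_table.total_count
    if total == 0:
        raise ValueError("variant table has zero total reads")
    dominant = variant_table.variants[0].count_total
    return icv_fraction_from_counts(dominant, total)


def icv_fraction_from_counts(dominant_count: int, total_count: int) -> float:
    """Same statistic from bare counts (worked-example entry point)."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if dominant_count < 0 or dominant_count > total_count:
        raise ValueError("dominant_count outside [0, total_count]")
    return round_half_up(100.0 * (1.0 - dominant_count / total_count), 1)


def variant_burden(icv_fraction_pct: float, total_tumor_cells: float) -> float:
    """Absolute cell count carried by variant subclones: pct/100 x tumor mass."""
    if icv_fraction_pct < 0 or total_tumor_cells < 0:
        raise ValueError("inputs must be non-negative")
    return icv_fraction_pct / 100.0 * total_tumor_cells


def format_burden(cells: float) -> str:
    return f"{cells:.2e}"


def _mutated_positions(variant_seq: str, germline_seq: str, start: int) -> dict[int, str]:
    """Substituted germline positions -> observed base for one variant row."""
    out = {}
    for offset, base in enumerate(variant_seq):
        pos = start + offset
        germ = germline_seq[pos]
        if base != "-" and base != germ:
            out[pos] = base
    return out


@dataclass
class MutationPartition:
    trunk: dict[int, str]  # germline pos -> base shared by every top variant
    icv: set[int]  # positions mutated in some but not all variants

    def is_disjoint_exhaustive(self, observed: set[int]) -> bool:
        trunk_pos = set(self.trunk)
        return trunk_pos.isdisjoint(self.icv) and trunk_pos | self.icv == observed


def mutation_partition(
    variant_seqs: Sequence[str], germline: GermlineAllele, start: int
) -> MutationPartition:
    """Split observed substitutions into trunk (in all variants, same base)
    and ICV (everything else, including reversions of a trunk position).

    ``variant_seqs`` are equal-length germline-coordinate projections starting
    at germline position ``start``.
    """
    if not variant_seqs:
        raise ValueError("no variants")
    if len({len(s) for s in variant_seqs}) != 1:
        raise ValueError("variant rows must be equal length")
    per_variant = [_mutated_positions(s, germline.seq, start) for s in variant_seqs]
    all_pos: set[int] = set()
    for muts in per_variant:
        all_pos.update(muts)
    trunk: dict[int, str] = {}
    icv: set[int] = set()
    for pos in all_pos:
        bases = {muts.get(pos) for muts in per_variant}
        if None not in bases and len(bases) == 1:
            trunk[pos] = bases.pop()
        else:
            icv.add(pos)
    return MutationPartition(trunk=trunk, icv=icv)


@dataclass
class ICVReport:
    cdr3_nt: str
    dominant_variant_count: int
    clonotype_total: int
    icv_fraction_pct: float
    n_variants: int
    trunk_positions: dict[int, str] = field(default_factory=dict)
    icv_positions: list[int] = field(default_factory=list)
    burden_cells: float | None = None

    def to_json(self, path: str | Path) -> None:
        raw = {
            "cdr3_nt": self.cdr3_nt,
            "dominant_variant_count": self.dominant_variant_count,
            "clonotype_total": self.clonotype_total,
            "icv_fraction_pct": self.icv_fraction_pct,
            "n_variants": self.n_variants,
            "trunk_positions": {str(k): v for k, v in self.trunk_positions.items()},
            "icv_positions": sorted(self.icv_positions),
        }
        if self.burden_cells is not None:
            raw["burden_cells"] = format_burden(self.burden_cells)
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=1, sort_keys=True)


def build_icv_report(
    table: VariantTable,
    germline: GermlineAllele,
    start: int,
    top_n: int = 10,
    total_tumor_cells: float | None = None,
) -> ICVReport:
    frac = icv_fraction(table)
    top = table.top_n(top_n)
    partition = mutation_partition(
        [v.variant_seq for v in top.variants], germline, start
    )
    return ICVReport(
        cdr3_nt=table.cdr3_nt,
        dominant_variant_count=table.variants[0].count_total,
        clonotype_total=table.total_count,
        icv_fraction_pct=frac,
        n_variants=len(table.variants),
        trunk_positions=partition.trunk,
        icv_positions=sorted(partition.icv),
        burden_cells=(
            variant_burden(frac, total_tumor_cells)
            if total_tumor_cells is not None
            else None
        ),
    )


def render_variant_alignment(
    table: VariantTable,
    germline: GermlineAllele,
    start: int,
    top_n: int = 10,
    informative_only: bool = True,
) -> str:
    """Text alignment: dominant variant vs germline, others vs dominant.

    Identity to the reference row is drawn as ``.``; by default only columns
    where some variant differs from the dominant, or the dominant differs
    from germline, are shown.
    """
    top = table.top_n(top_n).variants
    if not top:
        return "(no variants)"
    dom = top[0].variant_seq
    n = len(dom)
    germ = germline.seq[start : start + n]
    if informative_only:
        cols = [
            j
            for j in range(n)
            if germ[j] != dom[j] or any(v.variant_seq[j] != dom[j] for v in top[1:])
        ]
    else:
        cols = list(range(n))
    lines = []
    width = max(len(f"v{v.rank}_{v.count_total}") for v in top)
    width = max(width, len("germline"))
    header = " ".join(f"{start + j:>4d}" for j in cols)
    lines.append(f"{'pos':<{width}} {header}")
    lines.append(
        f"{'germline':<{width}} " + " ".join(f"{germ[j]:>4}" for j in cols)
    )
    dom_row = " ".join(f"{'.' if dom[j] == germ[j] else dom[j]:>4}" for j in cols)
    lines.append(f"{f'v1_{top[0].count_total}':<{width}} {dom_row}")
    for v in top[1:]:
        row = " ".join(
            f"{'.' if v.variant_seq[j] == dom[j] else v.variant_seq[j]:>4}"
            for j in cols
        )
        lines.append(f"{f'v{v.rank}_{v.count_total}':<{width}} {row}")
    return "\n".join(lines)
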