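"""Synthetic paired-end IGHV amplicon repertoires with known clonal architecture.

Generates two technical replicates of 250 b paired-end FASTQ reads drawn from
a dominant clonal lineage (trunk mutations + ongoing-hypermutation subclone
variants, all sharing one CDR3) on top of a polyclonal IgG background with
power-law clone sizes, then layers PCR and sequencing substitution errors.
Ground truth (lineage, expected and realized per-replicate counts) is emitted
alongside the reads.

The mutation model is substitution-only.  Trunk and ongoing mutations target
germline V positions upstream of the conserved Cys codon, weighted at AID
hotspot motifs (WRCY/RGYW), so every lineage member keeps an identical CDR3
by construction; sequencing/PCR errors still hit the whole read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .germline import GermlineAllele, default_alleles, read_fasta

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

# J segment downstream of the anchoring Trp, then an IgG CH1-like stub so the
# reverse read originates outside the V region, as in the FR1->IgG amplicon.
J_REMAINDER = "GGCCAAGGGACCACGGTCACCGTCTCCTCA"
CONSTANT_STUB = "GCCTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCACCCTCCTCCAAGAGCACCTCTGGG"


@dataclass
class SimConfig:
    """Parameters of one simulated two-replicate sequencing run."""

    seed: int = 0
    germline_ref: str | None = None  # path to allele FASTA; None -> built-ins
    n_background_clones: int = 50
    background_abundance_shape: float = 1.5
    dominant_clone_fraction: float = 0.8
    trunk_mutations: int = 15
    n_subclone_generations: int = 3
    per_generation_mutation_rate: float = 2.0
    hotspot_weight: float = 5.0
    seq_error_rate: float = 3e-4
    pcr_error_rate: float = 4.4e-7
    pcr_cycles: int = 30
    read_length: int = 250
    amplicon_length_range: tuple[int, int] = (400, 450)
    total_read_pairs: int = 10_000
    replicate_split: float = 0.5

    def validate(self) -> None:
        rates = {
            "dominant_clone_fraction": self.dominant_clone_fraction,
            "per-base seq_error_rate": self.seq_error_rate,
            "pcr_error_rate": self.pcr_error_rate,
            "replicate_split": self.replicate_split,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        lo, hi = self.amplicon_length_range
        if lo > hi:
            raise ValueError("amplicon_length_range min > max")
        min_overlap = 10
        if 2 * self.read_length < lo + min_overlap:
            raise ValueError(
                "read_length*2 must cover amplicon min length plus overlap"
            )
        for name in (
            "n_background_clones",
            "trunk_mutations",
            "n_subclone_generations",
            "pcr_cycles",
            "total_read_pairs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hotspot_weight < 1.0:
            raise ValueError("hotspot_weight must be >= 1")
        if self.background_abundance_shape <= 0:
            raise ValueError("background_abundance_shape must be positive")

    def load_alleles(self) -> list[GermlineAllele]:
        if self.germline_ref is None:
            return default_alleles()
        return read_fasta(self.germline_ref)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "amplicon_length_range" in raw:
            raw["amplicon_length_range"] = tuple(raw["amplicon_length_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["amplicon_length_range"] = list(self.amplicon_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class VariantNode:
    """One member of the clonal lineage (full V sequence, edge substitutions)."""

    id: int
    parent: int | None
    v_seq: str
    amplicon: str
    edge_mutations: dict[int, str] = field(default_factory=dict)


@dataclass
class BackgroundClone:
    id: int
    allele: str
    cdr3: str
    amplicon: str
    weight: float


@dataclass
class GroundTruth:
    """Planted architecture plus realized per-replicate read counts."""

    allele: str
    clone_cdr3: str
    dominant_clone_fraction: float
    lineage: list[VariantNode]
    variant_weights: dict[int, float]  # within-clone expected fraction
    background_clonotypes: list[BackgroundClone]
    realized_counts: dict[str, list[int]] = field(default_factory=dict)

    def planted_icv_fraction_pct(self) -> float:
        """Expected % of clone reads not carrying the top variant sequence."""
        counts = self.variant_sequence_weights()
        return 100.0 * (1.0 - max(counts.values()) / sum(counts.values()))

    def variant_sequence_weights(self) -> dict[str, float]:
        """Within-clone weights aggregated by amplicon sequence (children that
        drew zero mutations are indistinguishable from their parent)."""
        agg: dict[str, float] = {}
        for node in self.lineage:
            agg[node.amplicon] = agg.get(node.amplicon, 0.0) + self.variant_weights[
                node.id
            ]
        return agg

    def variant_sequence_counts(self) -> dict[str, tuple[int, int]]:
        """Realized (repA, repB) lineage read counts keyed by amplicon sequence."""
        agg: dict[str, list[int]] = {}
        for node in self.lineage:
            a, b = self.realized_counts.get(f"L{node.id}", (0, 0))
            cur = agg.setdefault(node.amplicon, [0, 0])
            cur[0] += a
            cur[1] += b
        return {seq: (ab[0], ab[1]) for seq, ab in agg.items()}

    def all_amplicons(self) -> set[str]:
        seqs = {n.amplicon for n in self.lineage}
        seqs.update(c.amplicon for c in self.background_clonotypes)
        return seqs

    def to_json(self, path: str | Path) -> None:
        raw = {
            "allele": self.allele,
            "clone_cdr3": self.clone_cdr3,
            "dominant_clone_fraction": self.dominant_clone_fraction,
            "lineage": [
                {
                    "id": n.id,
                    "parent": n.parent,
                    "v_seq": n.v_seq,
                    "amplicon": n.amplicon,
                    "edge_mutations": {str(k): v for k, v in n.edge_mutations.items()},
                }
                for n in self.lineage
            ],
            "variant_weights": {str(k): v for k, v in self.variant_weights.items()},
            "background_clonotypes": [asdict(c) for c in self.background_clonotypes],
            "realized_counts": self.realized_counts,
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            allele=raw["allele"],
            clone_cdr3=raw["clone_cdr3"],
            dominant_clone_fraction=raw["dominant_clone_fraction"],
            lineage=[
                VariantNode(
                    id=n["id"],
                    parent=n["parent"],
                    v_seq=n["v_seq"],
                    amplicon=n["amplicon"],
                    edge_mutations={int(k): v for k, v in n["edge_mutations"].items()},
                )
                for n in raw["lineage"]
            ],
            variant_weights={int(k): v for k, v in raw["variant_weights"].items()},
            background_clonotypes=[
                BackgroundClone(**c) for c in raw["background_clonotypes"]
            ],
            realized_counts={k: list(v) for k, v in raw["realized_counts"].items()},
        )


def hotspot_site_weights(v_seq: str, n_sites: int, hotspot_weight: float) -> np.ndarray:
    """Per-position mutation weights over the first n_sites of v_seq;
    positions inside any WRCY or RGYW 4-mer get hotspot_weight, others 1."""
    is_hot = np.zeros(n_sites, dtype=bool)
    W, R, Y = set("AT"), set("AG"), set("CT")
    for i in range(len(v_seq) - 3):
        a, b, c, d = v_seq[i : i + 4]
        wrcy = a in W and b in R and c == "C" and d in Y
        rgyw = a in R and b == "G" and c in Y and d in W
        if wrcy or rgyw:
            is_hot[i : min(i + 4, n_sites)] = True
    weights = np.where(is_hot, hotspot_weight, 1.0)
    return weights / weights.sum()


def _random_junction(rng: np.random.Generator, n_codons: int) -> str:
    """In-frame junction codons: no stops, no Trp (keeps the J anchor first)."""
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon in _STOPS or codon == "TGG":
            continue
        codons.append(codon)
    return "".join(codons)


def _mutate(
    rng: np.random.Generator,
    seq: list[str],
    weights: np.ndarray,
    k: int,
    distinct: bool = False,
) -> dict[int, str]:
    """Apply k weighted substitutions in place; returns net {pos: new_base}.

    With ``distinct``, positions are drawn without replacement so exactly k
    sites end up substituted.  Otherwise repeat draws can restore a site to
    its starting base; such no-ops are excluded from the returned diff.
    """
    before = list(seq)
    for pos in rng.choice(len(weights), size=k, p=weights, replace=not distinct):
        pos = int(pos)
        seq[pos] = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
    return {i: seq[i] for i in range(len(weights)) if seq[i] != before[i]}


def _fit_length(amplicon: str, lo: int, hi: int) -> str:
    """Pad (cycling the constant stub) or trim the tail into [lo, hi]."""
    while len(amplicon) < lo:
        amplicon += CONSTANT_STUB[: lo - len(amplicon)]
    if len(amplicon) > hi:
        amplicon = amplicon[:hi]
    return amplicon


def _assemble_amplicon(
    v_seq: str, cys_end: int, junction: str, lo: int, hi: int
) -> str:
    amp = v_seq[:cys_end] + junction + "TGG" + J_REMAINDER + CONSTANT_STUB
    return _fit_length(amp, lo, hi)


def simulate_lineage(
    config: SimConfig, rng: np.random.Generator
) -> tuple[GroundTruth, GermlineAllele]:
    """Build the dominant clonal lineage and the background clonotypes.

    The founder is the chosen germline allele with ``trunk_mutations``
    hotspot-weighted substitutions and a random in-frame V(D)J junction fixing
    the clone CDR3.  Each of ``n_subclone_generations`` rounds lets every
    existing variant spawn one child carrying Poisson(rate) further weighted
    substitutions, so a lineage of 2^g variants results.  Within-clone
    abundance weights are Dirichlet(1), sorted so the founder dominates.
    """
    config.validate()
    alleles = config.load_alleles()
    if not alleles:
        raise ValueError("empty germline allele set")
    lo, hi = config.amplicon_length_range

    allele = alleles[int(rng.integers(len(alleles)))]
    n_v_sites = allele.cys104_pos  # mutable V positions: upstream of the Cys codon
    weights = hotspot_site_weights(allele.seq, n_v_sites, config.hotspot_weight)

    junction = _random_junction(rng, int(rng.integers(5, 11)))
    clone_cdr3 = allele.seq[allele.cys104_pos : allele.cys_end] + junction + "TGG"

    founder = list(allele.seq)
    trunk = _mutate(rng, founder, weights, config.trunk_mutations, distinct=True)
    nodes = [
        VariantNode(
            id=0,
            parent=None,
            v_seq="".join(founder),
            amplicon=_assemble_amplicon("".join(founder), allele.cys_end, junction, lo, hi),
            edge_mutations=trunk,
        )
    ]
    for _ in range(config.n_subclone_generations):
        for parent in list(nodes):
            child_seq = list(parent.v_seq)
            k = int(rng.poisson(config.per_generation_mutation_rate))
            edge = _mutate(rng, child_seq, weights, k)
            nodes.append(
                VariantNode(
                    id=len(nodes),
                    parent=parent.id,
                    v_seq="".join(child_seq),
                    amplicon=_assemble_amplicon(
                        "".join(child_seq), allele.cys_end, junction, lo, hi
                    ),
                    edge_mutations=edge,
                )
            )

    w = np.sort(rng.dirichlet(np.ones(len(nodes))))[::-1]
    variant_weights = {node.id: float(w[i]) for i, node in enumerate(nodes)}

    background: list[BackgroundClone] = []
    if config.n_background_clones > 0:
        ranks = np.arange(1, config.n_background_clones + 1, dtype=float)
        bg_w = ranks ** (-config.background_abundance_shape)
        bg_w /= bg_w.sum()
        seen_cdr3 = {clone_cdr3}
        for i in range(config.n_background_clones):
            bg_allele = alleles[int(rng.integers(len(alleles)))]
            while True:
                bg_junction = _random_junction(rng, int(rng.integers(5, 11)))
                cdr3 = (
                    bg_allele.seq[bg_allele.cys104_pos : bg_allele.cys_end]
                    + bg_junction
                    + "TGG"
                )
                if cdr3 not in seen_cdr3:
                    seen_cdr3.add(cdr3)
                    break
            bg_weights = hotspot_site_weights(
                bg_allele.seq, bg_allele.cys104_pos, config.hotspot_weight
            )
            bg_seq = list(bg_allele.seq)
            _mutate(rng, bg_seq, bg_weights, int(rng.poisson(6.0)))
            background.append(
                BackgroundClone(
                    id=i,
                    allele=bg_allele.name,
                    cdr3=cdr3,
                    amplicon=_assemble_amplicon(
                        "".join(bg_seq), bg_allele.cys_end, bg_junction, lo, hi
                    ),
                    weight=float(bg_w[i]),
                )
            )

    truth = GroundTruth(
        allele=allele.name,
        clone_cdr3=clone_cdr3,
        dominant_clone_fraction=config.dominant_clone_fraction,
        lineage=nodes,
        variant_weights=variant_weights,
        background_clonotypes=background,
    )
    return truth, allele


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _apply_substitution_errors(
    rng: np.random.Generator, seq: str, p: float
) -> str:
    if p <= 0.0:
        return seq
    k = rng.binomial(len(seq), p)
    if k == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        out[pos] = str(rng.choice([b for b in "ACGT" if b != out[pos]]))
    return "".join(out)


def simulate_repertoire(
    config: SimConfig, outdir: str | Path
) -> tuple[Path, Path, Path, Path, GroundTruth]:
    """Emit the four FASTQ files (repA/repB x R1/R2) plus ground truth.

    Read pairs are multinomially sampled over lineage variants and background
    clones, assigned to replicate A with probability ``replicate_split``, and
    subjected first to PCR errors (per-base 1-(1-rate)^cycles) on the amplicon
    then to per-base sequencing errors on each mate.  Deterministic for a
    given config: identical seed => byte-identical FASTQ.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth, _allele = simulate_lineage(config, rng)

    sources: list[tuple[str, str]] = [
        (f"L{n.id}", n.amplicon) for n in truth.lineage
    ]
    probs = [
        config.dominant_clone_fraction * truth.variant_weights[n.id]
        for n in truth.lineage
    ]
    bg_total = 1.0 - config.dominant_clone_fraction
    for clone in truth.background_clonotypes:
        sources.append((f"B{clone.id}", clone.amplicon))
        probs.append(bg_total * clone.weight)
    probs = np.asarray(probs)
    if probs.sum() == 0:
        probs = np.ones(len(probs)) / len(probs)
    probs = probs / probs.sum()

    if config.total_read_pairs == 0:
        logger.warning("total_read_pairs=0: emitting empty FASTQ outputs")
        counts = np.zeros(len(sources), dtype=int)
    else:
        counts = rng.multinomial(config.total_read_pairs, probs)

    p_pcr = 1.0 - (1.0 - config.pcr_error_rate) ** config.pcr_cycles
    L = config.read_length
    qual = "F" * L  # constant Q37

    paths = {
        ("A", 1): outdir / "repA_R1.fastq",
        ("A", 2): outdir / "repA_R2.fastq",
        ("B", 1): outdir / "repB_R1.fastq",
        ("B", 2): outdir / "repB_R2.fastq",
    }
    handles = {k: open(p, "w") for k, p in paths.items()}
    try:
        read_no = 0
        for (source_id, amplicon), n_reads in zip(sources, counts):
            n_a = int(rng.binomial(n_reads, config.replicate_split))
            truth.realized_counts[source_id] = [n_a, int(n_reads) - n_a]
            for j in range(int(n_reads)):
                rep = "A" if j < n_a else "B"
                template = _apply_substitution_errors(rng, amplicon, p_pcr)
                r1 = _apply_substitution_errors(
                    rng, template[:L], config.seq_error_rate
                )
                r2 = _apply_substitution_errors(
                    rng, revcomp(template[-L:]), config.seq_error_rate
                )
                read_no += 1
                name = f"SIM{config.seed}:{read_no:07d}"
                handles[(rep, 1)].write(f"@{name}/1\n{r1}\n+\n{qual}\n")
                handles[(rep, 2)].write(f"@{name}/2\n{r2}\n+\n{qual}\n")
    finally:
        for fh in handles.values():
            fh.close()

    truth.to_json(outdir / "ground_truth.json")
    config.to_yaml(outdir / "sim_config.yaml")
    return (
        paths[("A", 1)],
        paths[("A", 2)],
        paths[("B", 1)],
        paths[("B", 2)],
        truth,
    )
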