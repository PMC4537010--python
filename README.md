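# icvseq

Analysis toolkit for deep-sequenced IGHV (immunoglobulin heavy-chain
variable) IgG amplicon libraries prepared as two technical replicates:
it merges paired-end reads, assigns germline V alleles, groups reads into
clonotypes by exact CDR3 nucleotide identity, filters out artifacts that are
not concordant between the replicates, calls a dominant (tumor-like) clone,
quantifies intraclonal variation (ICV) among its subclonal sequence variants,
and builds neighbor-joining lineage trees over the top variants with
read-count leaf labels.

A synthetic-data module generates paired-end FASTQ replicates with a known
clonal architecture (trunk-mutated founder, ongoing-hypermutation subclones
sharing one CDR3, a power-law polyclonal background, PCR and sequencing
errors) plus a ground-truth JSON, so the whole pipeline is testable offline.

## CLI

```bash
icvseq simulate --outdir sim/ --seed 7            # synthetic two-replicate data
icvseq merge --r1 sim/repA_R1.fastq --r2 sim/repA_R2.fastq \
             --out merged.fastq --qc qc.tsv       # FLASH-style merge + >=300 b filter
icvseq annotate --fastq merged.fastq --out rearr.tsv --replicate A
icvseq clonotype --airr rearr.tsv --dominant-threshold 5.0 --out-prefix out
icvseq icv --variants out.variants.tsv --tumor-cells 5e11 --out icv.json
icvseq tree --variants out.variants.tsv --out tree.nwk
icvseq run --config pipeline.yaml --outdir run/   # everything end to end
```

`icvseq run` expects a YAML config naming the four replicate FASTQ files
(repA/repB x R1/R2) and optional thresholds; every stage writes its artifact
(merged FASTQ, AIRR-style rearrangement TSV, clonotype/variant tables, ICV
report JSON, Newick tree) into the run directory along with a `summary.json`
recording read counts through each stage.

The dominant-clone cut-off defaults to a strict 5% of clonotyped reads; pass
`--dominant-threshold 7.8` for the stricter cut-off recommended when calling
a myeloma tumor clone in IgG libraries.

Germline references are FASTA files whose headers carry a
`;cys104=<offset>` tag marking the conserved CDR3-anchoring cysteine codon;
`icvseq write-germline --out germline.fasta` exports the four bundled
synthetic alleles used by default.

## Key conventions

- Coordinates are 0-based half-open, in germline space.
- A clonotype is the set of reads with a byte-identical CDR3 nucleotide
  sequence (conserved Cys codon through the first in-frame TGG-GGx J-anchor
  tryptophan, inclusive).
- % homology = identical aligned positions / aligned germline span, to one
  decimal (half-up), computed over the sequenced V portion only.
- ICV fraction = 100 x (1 - dominant-variant reads / total clonal reads),
  referenced to the single most abundant full-length variant.
- Replicate concordance: a clonotype (or variant) is kept only if it reaches
  the frequency and count floors in *both* technical replicates.
- NJ trees use Saitou-Nei neighbor joining on Hamming distances between
  germline-projected variants, with deterministic tie-breaking; negative
  branch lengths are clamped to zero with the remainder moved to the sibling
  edge.
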