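# dualguide

Genome-scale guide-RNA library design for **dual-mode bacterial CRISPR
activation and interference** (CRISPRa/i) with a PAM-flexible, nuclease-dead
Cas9 (dxCas9-type, recognising NG, GAA and GAT in addition to canonical NGG)
fused to a transcriptional effector.

It is written for synthetic biologists and genome engineers who need a
pooled, cloning-ready sgRNA library for a bacterial genome: activation
guides placed in a fixed window upstream of every gene, repression guides
against promoter-proximal/early-CDS sites, seed-based off-target screening,
non-targeting controls, and a pooled manifest with Golden Gate oligos.

## The method

For each annotated gene, the designer scans the region **190–250 bp upstream
of the start codon (ATG)**, on both strands, for protospacers anchored at a
PAM from the repertoire {NGG, NG, GAA, GAT}. A candidate site is the 20-nt
sequence immediately 5′ of the PAM on the PAM-bearing strand; a site belongs
to the window iff its PAM-proximal base lies at offset −250…−190 from the
ATG. One guide per gene is then selected by three rules:

1. **PAM-class preference** — NGG over NG over GAA/GAT (binding efficiency);
2. **operon redundancy elimination** — guides are kept only for the
   transcriptional leader of each operon (an upstream activator acts on the
   whole transcription unit); an `all-genes` mode disables this;
3. **one optimal guide per gene** — within a class, the candidate closest to
   the −190 window edge wins, ties broken by lexicographically smallest
   spacer, making the selection deterministic and auditable.

Repression guides are designed on the **non-template strand** in a window
from 20 bp upstream of the ATG to 100 bp into the CDS, ranked by proximity
to the start codon — early-CDS roadblocks repress most strongly, with
efficacy falling off downstream. External genome-wide repression libraries
(EcoWG1-style TSVs) can be imported instead and pooled as-is.

Off-target screening uses the **seed criterion**: a guide hits a locus iff
its 12 PAM-proximal bases sit identically next to an NGG anywhere in the
genome (both strands). Non-targeting controls are rejection-sampled random
20-mers with zero such hits. Everything is reproducible from explicit seeds.

Coordinates are 0-based half-open internally; FASTA/GenBank/GFF3/BED keep
their native conventions at the file boundary. A TSS-relative offset utility
(negative = upstream) supports reporter-style constructs where the TSS is
taken as the first base of the ribosome-binding site.

## Worked example

```bash
python examples/01_activation_design.py
```

```text
genome: 8574 bp, 12 genes, 3 multi-gene operons
7 activation guides (one per operon leader / singleton)
5 genes covered indirectly through their operon leader
not designable: none
  g0001_a1: AATTATTTAATATAAATTTT NGG at -206
  g0005_a1: TTATTAATTTTTTTAAAAAT NGG at -206
  g0006_a1: AATAATTAAAATATATTAAA NGG at -210
```

Twelve genes collapse to seven transcription units, each receiving exactly
one guide; `at -206` means the guide's PAM-proximal base sits 206 bp
upstream of the start codon, inside the activation window. The other
examples show off-target screening/controls (`02`) and pooled-library
assembly with oligos and QC (`03`).

The same pipeline is available as a CLI for file-based workflows:

```bash
dualguide fixtures --n-genes 8 --seed 5 --out fx
dualguide design-activation --genome fx/genome.fasta --annotation fx/genes.gff3 \
    --operons fx/operons.tsv --out act --seed 1
dualguide design-repression --genome fx/genome.fasta --annotation fx/genes.gff3 \
    --out rep --seed 1
dualguide controls --genome fx/genome.fasta --n 5 --seed 2 --out ctl
dualguide merge --activation act/library.tsv --repression rep/library.tsv \
    --controls ctl/library.tsv --out pooled
```

Each output directory holds `library.tsv` (re-readable manifest),
`spacers.fasta`, `protospacers.bed`, `oligos.tsv` and a `provenance.json`
recording config, genome and seed.

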