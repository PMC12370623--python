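"""Deterministic synthetic genomes with planted, machine-checkable ground truth.

The generator emulates the structure the genome-wide scan assumes: protein
coding genes on both strands with a defined start codon anchor, operons of
adjacent same-strand genes, an activation window 190-250 bp upstream of each
start codon, and (optionally) a planted candidate site in every window.

To make planted-truth recovery exact, each gene's window neighbourhood is
re-sampled from A/T-only background before the site is planted. An A/T
region can anchor no PAM of any class on either strand (every pattern in the
repertoire needs a G, or a C on the opposite strand), so the planted NGG is
the unique top-class candidate in its window and must win the documented
ranking. Spacers are A/T 20-mers with a TGG PAM for the same reason. This is
a deliberate idealisation: real windows hold several competing candidates,
which the ranking handles but the planted truth does not exercise.

Layout spacing keeps windows, planted writes and inter-gene gaps disjoint;
everything is drawn from one seeded generator, so identical parameters give
byte-identical FASTA/GFF3/TSV/JSON output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._seq import revcomp
from .exceptions import LayoutError, ValidationError
from .genome_io import (
    GeneAnnotation,
    GenomeRecord,
    OperonMap,
    write_annotation,
    write_genome,
)

_AT = np.frombuffer(b"AT", dtype=np.uint8)
_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSite:
    """One planted candidate: where it is and what the scan must recover."""

    gene_id: str
    pam_strand: str
    anchor_pos: int  # genomic position of the PAM-proximal protospacer base
    offset: int  # anchor offset from the start codon (negative = upstream)
    spacer: str
    pam: str = "TGG"
    pam_class: str = "NGG"


@dataclass(frozen=True)
class PlantedOffTarget:
    spacer: str
    #: (contig_id, pam_position, strand) of every planted copy
    occurrences: tuple[tuple[str, int, str], ...]


@dataclass
class FixtureTruth:
    """A synthetic genome plus every planted fact a test may assert against."""

    genome: GenomeRecord
    genes: list[GeneAnnotation]
    operon_map: OperonMap
    planted_sites: dict[str, Optional[PlantedSite]]
    planted_offtargets: list[PlantedOffTarget] = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)
    occupied: list[tuple[int, int]] = field(default_factory=list)

    @property
    def records(self) -> list[GenomeRecord]:
        return [self.genome]

    def write(self, out_dir) -> dict[str, Path]:
        """Emit FASTA + GFF3 + operon TSV + truth JSON; byte-stable per seed."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "genome.fasta",
            "gff3": out_dir / "genes.gff3",
            "operons": out_dir / "operons.tsv",
            "truth": out_dir / "truth.json",
        }
        write_genome(self.records, paths["fasta"])
        write_annotation(
            self.genes, paths["gff3"],
            contig_lengths={self.genome.contig_id: self.genome.length},
        )
        with open(paths["operons"], "w") as fh:
            fh.write("gene_id\toperon_id\n")
            for gid in sorted(self.operon_map.mapping):
                fh.write(f"{gid}\t{self.operon_map.mapping[gid]}\n")
        truth = {
            "seed": self.seed,
            "params": self.params,
            "genes": [
                {"gene_id": g.gene_id, "start": g.start, "end": g.end,
                 "strand": g.strand} for g in self.genes
            ],
            "operons": {g: o for g, o in sorted(self.operon_map.mapping.items())},
            "leaders": sorted(self.operon_map.leaders),
            "planted_sites": {
                gid: (None if s is None else {
                    "pam_strand": s.pam_strand, "anchor_pos": s.anchor_pos,
                    "offset": s.offset, "spacer": s.spacer, "pam": s.pam,
                    "pam_class": s.pam_class,
                }) for gid, s in sorted(self.planted_sites.items())
            },
            "planted_offtargets": [
                {"spacer": p.spacer, "occurrences": [list(o) for o in p.occurrences]}
                for p in self.planted_offtargets
            ],
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _write(arr: np.ndarray, start: int, s: str) -> None:
    arr[start : start + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)


def synth_genome(
    n_genes: int,
    contig_len: Optional[int] = None,
    operon_fraction: float = 0.3,
    seed: int = 0,
    *,
    gene_len: int = 300,
    plant_prob: float = 1.0,
    gc: float = 0.5,
    upstream_near: int = 190,
    upstream_far: int = 250,
    contig_id: str = "synth1",
    tail: int = 800,
) -> FixtureTruth:
    """Generate a synthetic genome with one planted activation site per gene.

    ``operon_fraction`` is the per-gene probability of extending the current
    operon (same strand, gap 15-45 bp; operons capped at 4 genes); other
    neighbours are separated by 560-640 bp so that windows and planted writes
    never collide. ``plant_prob`` < 1 leaves some windows PAM-free, giving
    known not-designable genes. ``gc`` shapes only the background (E. coli is
    ~0.508); window neighbourhoods are A/T by construction (see module docs).
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if not (0 <= operon_fraction <= 1):
        raise ValidationError("operon_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    # --- layout ---------------------------------------------------------
    layout: list[tuple[int, int, str]] = []  # start, end, strand
    groups: list[list[int]] = []
    pos = 400
    for i in range(n_genes):
        extend = (
            bool(groups)
            and len(groups[-1]) < 4
            and rng.random() < operon_fraction
        )
        if i == 0:
            gap = 0
            strand = "+-"[rng.integers(0, 2)]
            groups.append([i])
        elif extend:
            gap = int(rng.integers(15, 46))
            strand = layout[-1][2]
            groups[-1].append(i)
        else:
            gap = int(rng.integers(560, 641))
            strand = "+-"[rng.integers(0, 2)]
            groups.append([i])
        start = (layout[-1][1] if layout else pos) + gap
        layout.append((start, start + gene_len, strand))
    needed = layout[-1][1] + tail
    if contig_len is None:
        contig_len = needed
    elif contig_len < needed:
        raise LayoutError(
            f"layout infeasible: {n_genes} genes need {needed} bp, "
            f"contig_len={contig_len}"
        )

    # --- background -----------------------------------------------------
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_ACGT, size=contig_len, p=p)

    # --- genes, window neutralisation, planting -------------------------
    genes: list[GeneAnnotation] = []
    planted: dict[str, Optional[PlantedSite]] = {}
    occupied: list[tuple[int, int]] = []
    for i, (start, end, strand) in enumerate(layout):
        gid = f"g{i + 1:04d}"
        gene = GeneAnnotation(gid, contig_id, start, end, strand)
        genes.append(gene)
        occupied.append((start, end))
        anchor = gene.start_codon_pos
        if strand == "+":
            w0, w1 = anchor - upstream_far, anchor - upstream_near + 1
        else:
            w0, w1 = anchor + upstream_near, anchor + upstream_far + 1
        z0, z1 = w0 - 3, w1 + 3  # cover PAM footprints anchored at window edges
        arr[z0:z1] = rng.choice(_AT, size=z1 - z0)
        occupied.append((z0, z1))
        if rng.random() < plant_prob:
            offset = int(rng.integers(-upstream_far, -upstream_near + 1))
            pam_strand = "+-"[rng.integers(0, 2)]
            a = anchor + offset if strand == "+" else anchor - offset
            spacer = "".join("AT"[b] for b in rng.integers(0, 2, 20))
            if pam_strand == "+":
                _write(arr, a - 19, spacer + "TGG")
                occupied.append((a - 19, a + 4))
            else:
                _write(arr, a - 3, "CCA" + revcomp(spacer))
                occupied.append((a - 3, a + 20))
            planted[gid] = PlantedSite(gid, pam_strand, a, offset, spacer)
        else:
            planted[gid] = None

    mapping: dict[str, str] = {}
    leaders: set[str] = set()
    op_idx = 0
    for members in groups:
        if len(members) < 2:
            continue
        op_idx += 1
        oid = f"op{op_idx:03d}"
        for m in members:
            mapping[genes[m].gene_id] = oid
        strand = layout[members[0]][2]
        leader = members[0] if strand == "+" else members[-1]
        leaders.add(genes[leader].gene_id)

    return FixtureTruth(
        genome=GenomeRecord(contig_id, arr.tobytes().decode("ascii")),
        genes=genes,
        operon_map=OperonMap(mapping=mapping, leaders=frozenset(leaders)),
        planted_sites=planted,
        seed=seed,
        params={
            "n_genes": n_genes, "contig_len": contig_len,
            "operon_fraction": operon_fraction, "gene_len": gene_len,
            "plant_prob": plant_prob, "gc": gc,
            "upstream_near": upstream_near, "upstream_far": upstream_far,
        },
        occupied=occupied,
    )


def _bruteforce_seed_hits(seq: str, spacer: str, seed_len: int = 12) -> int:
    """Count of (seed + NGG) occurrences on both strands, by string scanning."""
    seed = spacer[-seed_len:]
    count = 0
    p = seq.find(seed)
    while p >= 0:
        q = p + seed_len
        if q + 3 <= len(seq) and seq[q + 1 : q + 3] == "GG":
            count += 1
        p = seq.find(seed, p + 1)
    rcseed = revcomp(seed)
    p = seq.find(rcseed)
    while p >= 0:
        if p >= 3 and seq[p - 3 : p - 1] == "CC":
            count += 1
        p = seq.find(rcseed, p + 1)
    return count


def plant_offtarget(
    truth: FixtureTruth,
    spacer: str,
    copies: int,
    seed: Optional[int] = None,
    margin: int = 20,
) -> FixtureTruth:
    """Write ``copies`` of spacer+CGG into intergenic background, recording them.

    Placement replaces background bases (insertion would shift every
    downstream coordinate). After writing, a brute-force scan must find
    exactly ``copies`` seed+NGG occurrences of the spacer; a background
    collision raises rather than silently corrupting the truth.
    """
    if copies < 1:
        raise ValidationError("copies must be >= 1")
    spacer = spacer.upper()
    if len(spacer) != 20 or set(spacer) - set("ACGT"):
        raise ValidationError("spacer must be a 20-nt ACGT string")
    if seed is None:
        seed = (truth.seed + 101 * (len(truth.planted_offtargets) + 1)) % (2**31)
    rng = np.random.default_rng(seed)
    insert = spacer + "CGG"
    length = len(insert)

    merged: list[tuple[int, int]] = []
    for s, e in sorted(truth.occupied):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    free: list[tuple[int, int]] = []
    prev = 50
    for s, e in merged:
        if s - prev >= length + 2 * margin:
            free.append((prev, s))
        prev = max(prev, e)
    if truth.genome.length - 50 - prev >= length + 2 * margin:
        free.append((prev, truth.genome.length - 50))

    starts: list[int] = []
    for s, e in free:
        starts.extend(range(s + margin, e - margin - length + 1, length + margin))
    rng.shuffle(starts)
    chosen: list[int] = []
    for cand in starts:
        if all(abs(cand - c) >= length + margin for c in chosen):
            chosen.append(cand)
        if len(chosen) == copies:
            break
    if len(chosen) < copies:
        raise LayoutError(
            f"no room for {copies} off-target copies (found {len(chosen)} slots)"
        )
    chosen.sort()

    seq = bytearray(truth.genome.sequence, "ascii")
    for c in chosen:
        seq[c : c + length] = insert.encode()
        truth.occupied.append((c, c + length))
    new_seq = seq.decode("ascii")
    found = _bruteforce_seed_hits(new_seq, spacer)
    if found != copies:
        raise LayoutError(
            f"planted {copies} copies but brute force finds {found}; background "
            "collision - use a different spacer or fixture seed"
        )
    truth.genome = GenomeRecord(truth.genome.contig_id, new_seq)
    truth.planted_offtargets.append(
        PlantedOffTarget(
            spacer=spacer,
            occurrences=tuple(
                (truth.genome.contig_id, c + 20, "+") for c in chosen
            ),
        )
    )
    return truth
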