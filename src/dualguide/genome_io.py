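"""Genome and annotation I/O, plus operon resolution.

Coordinate contract
-------------------
Internally everything is 0-based, half-open ``[start, end)`` on the forward
axis of each contig. All file formats (FASTA/GenBank/GFF3) keep their native
conventions; the conversion happens exactly once, at read/write time.

The start codon anchor of a gene is the genomic position of the first base of
its start codon: ``start`` for a ``+`` strand gene, ``end - 1`` for a ``-``
strand gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import NoSequencesError, ParseError, ValidationError

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: an identifier and an upper-case DNA sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"contig {self.contig_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene on a contig, 0-based half-open, with its transcription strand."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def start_codon_pos(self) -> int:
        """Genomic position of the first base of the start codon (A of ATG)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class OperonMap:
    """Gene -> operon membership with one transcriptional leader per operon.

    Genes absent from the mapping are implicit singleton operons (their own
    leaders). Equality compares the *partition* into multi-gene operons and
    the leader set, not the operon id strings, so maps from different sources
    (truth tables vs. adjacency inference) compare meaningfully.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)
    leaders: frozenset = frozenset()

    def operon_of(self, gene_id: str) -> str:
        return self.mapping.get(gene_id, gene_id)

    def is_leader(self, gene_id: str) -> bool:
        return gene_id not in self.mapping or gene_id in self.leaders

    def members(self, operon_id: str) -> list[str]:
        return sorted(g for g, o in self.mapping.items() if o == operon_id)

    def _partition(self):
        by_operon: dict[str, set] = {}
        for g, o in self.mapping.items():
            by_operon.setdefault(o, set()).add(g)
        multi = frozenset(frozenset(m) for m in by_operon.values() if len(m) >= 2)
        covered = set().union(*multi) if multi else set()
        return multi, frozenset(self.leaders & covered)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OperonMap):
            return NotImplemented
        return self._partition() == other._partition()

    def __hash__(self) -> int:
        return hash(self._partition())


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    return "fasta"


def read_genome(
    path, format: Optional[str] = None, ambiguous: str = "map-to-n"
) -> list[GenomeRecord]:
    """Read a FASTA or GenBank genome into a list of :class:`GenomeRecord`.

    Sequences are upper-cased. IUPAC ambiguity codes other than N are either
    mapped to N (``ambiguous="map-to-n"``, default) or rejected
    (``ambiguous="reject"``).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in ("fasta", "genbank"):
        raise ValidationError(f"unsupported genome format {fmt!r}")
    with open(path) as handle:
        seqrecords = list(SeqIO.parse(handle, fmt))
    if not seqrecords:
        raise NoSequencesError(f"no sequences in {path}")
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in seqrecords:
        if rec.id in seen:
            raise ValidationError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        extra = set(seq) - _VALID_BASES
        if extra:
            if ambiguous == "reject":
                raise ValidationError(
                    f"contig {rec.id!r}: ambiguous bases {sorted(extra)} present"
                )
            seq = re.sub("[^ACGTN]", "N", seq)
        records.append(GenomeRecord(rec.id, seq))
    return records


def write_genome(records: Sequence[GenomeRecord], path, format: str = "fasta") -> Path:
    """Write contigs as FASTA or GenBank. Deterministic byte-for-byte output."""
    path = Path(path)
    seqrecords = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.contig_id, description="")
        if format == "genbank":
            sr.annotations["molecule_type"] = "DNA"
            sr.annotations["date"] = "01-JAN-1980"  # pinned: reproducible output
        seqrecords.append(sr)
    with open(path, "w") as handle:
        SeqIO.write(seqrecords, handle, format)
    return path


def _gene_id_from_attributes(attrs, fallback: Optional[str]) -> Optional[str]:
    for key in ("locus_tag", "ID", "Name", "gene"):
        if key in attrs and attrs[key]:
            val = attrs[key]
            return val[0] if isinstance(val, (list, tuple)) else val
    return fallback


def read_annotation(
    path,
    format: Optional[str] = None,
    genome: Optional[Sequence[GenomeRecord]] = None,
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or GenBank into 0-based half-open records.

    GFF3/GenBank coordinates are 1-based inclusive on disk; the conversion to
    the internal convention happens here. Features whose type is not in
    ``feature_types`` are ignored. If ``genome`` is given (or the GFF3 carries
    ``##sequence-region`` directives), coordinates are validated against
    contig lengths.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    contig_lengths: dict[str, int] = {}
    if genome is not None:
        contig_lengths = {r.contig_id: r.length for r in genome}

    genes: list[GeneAnnotation] = []
    if fmt == "gff3":
        try:
            db = gffutils.create_db(
                str(path), ":memory:", force=True, keep_order=True,
                merge_strategy="create_unique",
            )
        except Exception as exc:  # gffutils raises bare ValueError on bad lines
            raise ParseError(f"could not parse GFF3 {path}: {exc}") from exc
        if not contig_lengths:
            for directive in db.directives:
                m = re.match(r"sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", directive)
                if m:
                    contig_lengths[m.group(1)] = int(m.group(3))
        for ftype in feature_types:
            for feat in db.features_of_type(ftype):
                if feat.strand not in ("+", "-"):
                    raise ValidationError(
                        f"feature at {feat.seqid}:{feat.start}-{feat.end}: "
                        "strand field missing"
                    )
                gid = _gene_id_from_attributes(dict(feat.attributes), feat.id)
                if gid is None:
                    raise ValidationError(
                        f"feature at {feat.seqid}:{feat.start}-{feat.end}: no "
                        "ID or locus_tag attribute"
                    )
                attr_name = dict(feat.attributes).get("Name")
                name = attr_name[0] if attr_name else None
                genes.append(
                    GeneAnnotation(
                        gene_id=gid,
                        contig_id=feat.seqid,
                        start=feat.start - 1,
                        end=feat.end,
                        strand=feat.strand,
                        name=None if name == gid else name,
                    )
                )
    elif fmt == "genbank":
        with open(path) as handle:
            for rec in SeqIO.parse(handle, "genbank"):
                contig_lengths.setdefault(rec.id, len(rec.seq))
                for feat in rec.features:
                    if feat.type not in feature_types:
                        continue
                    if feat.location is None or feat.location.strand not in (1, -1):
                        raise ValidationError(
                            f"feature in {rec.id}: strand field missing"
                        )
                    gid = _gene_id_from_attributes(feat.qualifiers, None)
                    if gid is None:
                        raise ValidationError(f"feature in {rec.id}: no locus_tag")
                    genes.append(
                        GeneAnnotation(
                            gene_id=gid,
                            contig_id=rec.id,
                            start=int(feat.location.start),
                            end=int(feat.location.end),
                            strand="+" if feat.location.strand == 1 else "-",
                        )
                    )
    else:
        raise ValidationError(f"unsupported annotation format {fmt!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
        if g.contig_id in contig_lengths and g.end > contig_lengths[g.contig_id]:
            raise ValidationError(
                f"gene {g.gene_id!r}: end {g.end} exceeds contig "
                f"{g.contig_id!r} length {contig_lengths[g.contig_id]}"
            )
    genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))
    return genes


def write_annotation(
    genes: Sequence[GeneAnnotation],
    path,
    contig_lengths: Optional[Mapping[str, int]] = None,
    feature_type: str = "gene",
    source: str = "dualguide",
) -> Path:
    """Write annotations as GFF3 (1-based inclusive on disk)."""
    path = Path(path)
    genes = sorted(genes, key=lambda g: (g.contig_id, g.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for cid in sorted(contig_lengths):
                fh.write(f"##sequence-region {cid} 1 {contig_lengths[cid]}\n")
        for g in genes:
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
            if g.name and g.name != g.gene_id:
                attrs += f";Name={g.name}"
            fh.write(
                f"{g.contig_id}\t{source}\t{feature_type}\t{g.start + 1}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )
    return path


def resolve_operons(
    genes: Sequence[GeneAnnotation],
    table=None,
    max_gap: int = 50,
) -> OperonMap:
    """Resolve operon membership from a TSV table or by adjacency inference.

    With ``table`` (TSV with columns ``gene_id``, ``operon_id``) the table is
    used verbatim. Otherwise consecutive same-strand genes on a contig whose
    intergenic gap is at most ``max_gap`` bp share an operon. The leader is
    the 5'-most gene in transcription direction. Output is independent of the
    input gene order.
    """
    ordered = sorted(genes, key=lambda g: (g.contig_id, g.start, g.gene_id))
    by_id = {g.gene_id: g for g in ordered}

    groups: list[tuple[str, list[GeneAnnotation]]] = []
    if table is not None:
        df = pd.read_csv(table, sep="\t", dtype=str)
        missing = {"gene_id", "operon_id"} - set(df.columns)
        if missing:
            raise ValidationError(f"operon table missing columns {sorted(missing)}")
        unknown = set(df["gene_id"]) - set(by_id)
        if unknown:
            raise ValidationError(
                f"operon table references unknown genes {sorted(unknown)[:5]}"
            )
        for oid, sub in df.groupby("operon_id", sort=True):
            groups.append((str(oid), [by_id[g] for g in sub["gene_id"]]))
    else:
        run: list[GeneAnnotation] = []
        runs: list[list[GeneAnnotation]] = []
        prev: Optional[GeneAnnotation] = None
        for g in ordered:
            contiguous = (
                prev is not None
                and g.contig_id == prev.contig_id
                and g.strand == prev.strand
                and g.start - prev.end <= max_gap
            )
            if contiguous:
                run.append(g)
            else:
                if len(run) >= 2:
                    runs.append(run)
                run = [g]
            prev = g
        if len(run) >= 2:
            runs.append(run)
        groups = [(f"operon{i + 1:04d}", members) for i, members in enumerate(runs)]

    mapping: dict[str, str] = {}
    leaders: set[str] = set()
    for oid, members in groups:
        for g in members:
            mapping[g.gene_id] = oid
        head = min(members, key=lambda g: g.start)  # 5'-most member sets direction
        if head.strand == "+":
            leader = head
        else:
            leader = max(members, key=lambda g: g.end)
        leaders.add(leader.gene_id)
    return OperonMap(mapping=mapping, leaders=frozenset(leaders))
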