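"""Selection rules producing the activation and repression guide sets.

Activation: for every gene, all PAM-anchored candidates in the -250..-190
window upstream of the start codon are ranked by (1) PAM class (NGG before
NG before GAA/GAT), (2) anchor proximity to the -190 window edge, (3)
lexicographically smallest spacer, and the top candidate is kept - one guide
per gene. In ``operon_mode="dedup"`` only the transcriptional leader of each
operon retains a guide (an upstream activator acts on the whole transcription
unit); ``"all-genes"`` designs for every gene regardless.

Repression: candidates on the non-template strand in a window spanning the
promoter-proximal region and early coding sequence (default 20 bp upstream of
the start codon through +100 bp into the CDS), ranked by proximity to the
start codon - early-CDS sites block RNA polymerase most effectively, and
efficacy falls off further downstream.

External repression libraries (EcoWG1-style TSVs) are ingested as-is, with
optional re-mapping of each spacer onto the genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from ._seq import revcomp
from .exceptions import ParseError, ValidationError
from .genome_io import GeneAnnotation, GenomeRecord, OperonMap
from .offtarget import SeedIndex, query_offtargets
from .site_scan import (
    DEFAULT_PAM_SET,
    CandidateSite,
    PamSpec,
    TargetWindow,
    activation_window,
    find_pam_sites,
)


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the design; defaults reproduce the library recipe.

    ``upstream_near``/``upstream_far`` bound the activation window (bp
    upstream of the start codon, both inclusive); ``repression_upstream``/
    ``repression_cds`` bound the repression window around the start codon.
    """

    pam_set: tuple[PamSpec, ...] = DEFAULT_PAM_SET
    upstream_near: int = 190
    upstream_far: int = 250
    strands: tuple[str, ...] = ("+", "-")
    operon_mode: str = "dedup"  # or "all-genes"
    repression_upstream: int = 20
    repression_cds: int = 100
    repression_guides_per_gene: int = 1
    seed_len: int = 12
    offtarget_pam: str = "NGG"
    circular: bool = False

    def __post_init__(self) -> None:
        if self.operon_mode not in ("dedup", "all-genes"):
            raise ValidationError(f"unknown operon_mode {self.operon_mode!r}")
        if not (0 < self.upstream_near < self.upstream_far):
            raise ValidationError("need upstream_far > upstream_near > 0")

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pam_set" in raw:
            raw["pam_set"] = tuple(
                PamSpec(d["pattern"], int(d["class_rank"])) for d in raw["pam_set"]
            )
        for key in ("strands",):
            if key in raw:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pam_set"] = [
            {"pattern": p.pattern, "class_rank": p.class_rank} for p in self.pam_set
        ]
        d["strands"] = list(self.strands)
        return d


@dataclass
class GuideRecord:
    """One selected guide with its role, provenance and off-target count."""

    guide_id: str
    gene_id: str
    role: str  # activation | repression | control
    spacer: str
    pam: Optional[str] = None
    pam_class: Optional[str] = None
    contig_id: Optional[str] = None
    start: Optional[int] = None  # protospacer interval, 0-based half-open
    end: Optional[int] = None
    strand: Optional[str] = None
    offset_anchor: Optional[int] = None
    offtarget_hits: Optional[int] = None
    selection_rank_trace: str = ""
    meta: dict = field(default_factory=dict)


def _genome_by_contig(
    genome: Union[GenomeRecord, Iterable[GenomeRecord]]
) -> dict[str, GenomeRecord]:
    records = [genome] if isinstance(genome, GenomeRecord) else list(genome)
    return {r.contig_id: r for r in records}


def enumerate_activation_candidates(
    genome: Union[GenomeRecord, Iterable[GenomeRecord]],
    genes: Sequence[GeneAnnotation],
    config: DesignConfig = DesignConfig(),
) -> dict[str, list[CandidateSite]]:
    """Per gene, every candidate site in its activation window (may be empty).

    Genes with an empty list are "not designable" - that is data, not an
    error; see :func:`not_designable`.
    """
    contigs = _genome_by_contig(genome)
    out: dict[str, list[CandidateSite]] = {}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        if gene.contig_id not in contigs:
            raise ValidationError(
                f"gene {gene.gene_id!r} on unknown contig {gene.contig_id!r}"
            )
        rec = contigs[gene.contig_id]
        window = activation_window(
            gene, config.upstream_near, config.upstream_far, contig_length=rec.length
        )
        out[gene.gene_id] = find_pam_sites(
            rec, window, pams=config.pam_set, strands=config.strands
        )
    return out


def not_designable(candidates: Mapping[str, list[CandidateSite]]) -> list[str]:
    """Gene ids with zero candidate sites, sorted."""
    return sorted(g for g, sites in candidates.items() if not sites)


def _activation_rank_key(config: DesignConfig):
    near = config.upstream_near

    def key(site: CandidateSite):
        return (
            site.pam_class.class_rank,
            abs(site.offset_anchor + near),  # distance from the -near edge
            site.spacer,
        )

    return key


def select_guides(
    candidates: Mapping[str, list[CandidateSite]],
    operon_map: OperonMap = OperonMap(),
    config: DesignConfig = DesignConfig(),
) -> list[GuideRecord]:
    """One activation guide per (designable) gene, by the documented ranking.

    Ranking: PAM class rank, then anchor distance from the -``upstream_near``
    edge, then lexicographically smallest spacer. In ``dedup`` mode only
    operon leaders retain guides; see :func:`covered_via_operon` for the
    genes covered indirectly. Output is deterministic and independent of the
    input ordering.
    """
    key = _activation_rank_key(config)
    guides: list[GuideRecord] = []
    for gene_id in sorted(candidates):
        sites = candidates[gene_id]
        if not sites:
            continue
        if config.operon_mode == "dedup" and not operon_map.is_leader(gene_id):
            continue
        ranked = sorted(sites, key=key)
        best = ranked[0]
        trace = (
            f"{best.pam_class.pattern}(rank {best.pam_class.class_rank}) at "
            f"{best.offset_anchor:+d} from ATG, {abs(best.offset_anchor + config.upstream_near)} bp "
            f"from -{config.upstream_near} edge; chosen from {len(ranked)} candidates"
        )
        guides.append(
            GuideRecord(
                guide_id=f"{gene_id}_a1",
                gene_id=gene_id,
                role="activation",
                spacer=best.spacer,
                pam=best.pam,
                pam_class=best.pam_class.pattern,
                contig_id=best.contig_id or None,
                start=best.protospacer_start,
                end=best.protospacer_end,
                strand=best.pam_strand,
                offset_anchor=best.offset_anchor,
                selection_rank_trace=trace,
            )
        )
    return guides


def covered_via_operon(
    genes: Sequence[GeneAnnotation],
    operon_map: OperonMap,
    guides: Sequence[GuideRecord],
) -> dict[str, str]:
    """Non-leader genes whose operon leader carries a guide: gene -> leader."""
    leader_of: dict[str, str] = {}
    guided = {g.gene_id for g in guides}
    by_operon: dict[str, list[str]] = {}
    for gene in genes:
        oid = operon_map.operon_of(gene.gene_id)
        by_operon.setdefault(oid, []).append(gene.gene_id)
    for oid, members in by_operon.items():
        leaders = [m for m in members if operon_map.is_leader(m) and m in guided]
        if not leaders:
            continue
        for m in members:
            if m not in guided:
                leader_of[m] = leaders[0]
    return leader_of


def repression_window(
    gene: GeneAnnotation,
    upstream: int = 20,
    downstream: int = 100,
    contig_length: Optional[int] = None,
) -> TargetWindow:
    """Window spanning -upstream..+downstream around the start codon."""
    p = gene.start_codon_pos
    if gene.strand == "+":
        start, end = p - upstream, p + downstream + 1
    else:
        start, end = p - downstream, p + upstream + 1
    start = max(0, start)
    if contig_length is not None:
        end = min(end, contig_length)
    if end < start:
        end = start
    return TargetWindow(
        contig_id=gene.contig_id, start=start, end=end, gene_id=gene.gene_id,
        anchor="ATG", offset_bounds=(-upstream, downstream),
        direction=gene.strand, anchor_pos=p,
    )


def design_repression(
    genome: Union[GenomeRecord, Iterable[GenomeRecord]],
    genes: Sequence[GeneAnnotation],
    config: DesignConfig = DesignConfig(),
) -> list[GuideRecord]:
    """Up to k repression guides per gene on the non-template strand.

    The non-template (sense) strand of a gene is the strand carrying the
    gene's own orientation, so only ``gene.strand`` is scanned. Candidates
    are ranked by |offset from the start codon| (closest first), then PAM
    class, then spacer.
    """
    contigs = _genome_by_contig(genome)
    k = config.repression_guides_per_gene
    guides: list[GuideRecord] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        if gene.contig_id not in contigs:
            raise ValidationError(
                f"gene {gene.gene_id!r} on unknown contig {gene.contig_id!r}"
            )
        rec = contigs[gene.contig_id]
        window = repression_window(
            gene, config.repression_upstream, config.repression_cds,
            contig_length=rec.length,
        )
        sites = find_pam_sites(
            rec, window, pams=config.pam_set, strands=(gene.strand,)
        )
        ranked = sorted(
            sites,
            key=lambda s: (abs(s.offset_anchor), s.pam_class.class_rank, s.spacer),
        )
        for i, site in enumerate(ranked[:k]):
            guides.append(
                GuideRecord(
                    guide_id=f"{gene.gene_id}_r{i + 1}",
                    gene_id=gene.gene_id,
                    role="repression",
                    spacer=site.spacer,
                    pam=site.pam,
                    pam_class=site.pam_class.pattern,
                    contig_id=site.contig_id or None,
                    start=site.protospacer_start,
                    end=site.protospacer_end,
                    strand=site.pam_strand,
                    offset_anchor=site.offset_anchor,
                    selection_rank_trace=(
                        f"non-template {site.pam_class.pattern} at "
                        f"{site.offset_anchor:+d} from ATG; rank {i + 1}/{len(ranked)}"
                    ),
                )
            )
    return guides


_REQUIRED_LIBRARY_COLUMNS = ("guide_id", "gene_id", "spacer")


def import_external_library(
    path,
    genome: Union[GenomeRecord, Iterable[GenomeRecord], None] = None,
    index: Optional[SeedIndex] = None,
) -> list[GuideRecord]:
    """Ingest an external repression library TSV (guide_id, gene_id, spacer).

    Extra columns are preserved in ``meta``. With ``genome``, each spacer is
    located on either strand (leftmost occurrence wins) and its coordinates
    and adjacent PAM are filled in; unmappable spacers are flagged in
    ``meta["unmappable"]``, never dropped. With ``index``, off-target counts
    are filled (excluding the mapped locus).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed TSV {path}: {exc}") from exc
    missing = set(_REQUIRED_LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {sorted(missing)} (header, line 1)"
        )
    extra_cols = [c for c in df.columns if c not in _REQUIRED_LIBRARY_COLUMNS]
    contigs = _genome_by_contig(genome) if genome is not None else {}

    records: list[GuideRecord] = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header
        spacer = str(row["spacer"]).strip().upper()
        if not spacer or set(spacer) - set("ACGT"):
            raise ParseError(f"{path}: line {line}: invalid spacer {row['spacer']!r}")
        rec = GuideRecord(
            guide_id=str(row["guide_id"]),
            gene_id=str(row["gene_id"]),
            role="repression",
            spacer=spacer,
            meta={c: str(row[c]) for c in extra_cols},
        )
        if contigs:
            _locate_spacer(rec, contigs)
            if index is not None and rec.contig_id is not None:
                rec.offtarget_hits = len(
                    query_offtargets(
                        spacer, index, exclude=(rec.contig_id, rec.start, rec.end)
                    )
                )
        records.append(rec)
    return records


def _locate_spacer(rec: GuideRecord, contigs: Mapping[str, GenomeRecord]) -> None:
    best: Optional[tuple[str, int, str]] = None
    for cid in sorted(contigs):
        seq = contigs[cid].sequence
        p_fwd = seq.find(rec.spacer)
        p_rev = seq.find(revcomp(rec.spacer))
        for pos, strand in ((p_fwd, "+"), (p_rev, "-")):
            if pos >= 0 and (best is None or pos < best[1]):
                best = (cid, pos, strand)
        if best is not None:
            break  # contigs scanned in sorted order; leftmost on first hit contig
    if best is None:
        rec.meta["unmappable"] = "yes"
        rec.selection_rank_trace = "spacer not found in genome"
        return
    cid, pos, strand = best
    seq = contigs[cid].sequence
    rec.contig_id = cid
    rec.start = pos
    rec.end = pos + len(rec.spacer)
    rec.strand = strand
    if strand == "+":
        rec.pam = seq[rec.end : rec.end + 3]
    else:
        rec.pam = revcomp(seq[max(0, rec.start - 3) : rec.start])


def annotate_offtargets(
    guides: Sequence[GuideRecord], index: SeedIndex
) -> list[GuideRecord]:
    """Fill ``offtarget_hits`` in place (own locus excluded where mapped)."""
    for g in guides:
        if len(g.spacer) < index.seed_len:
            continue
        exclude = None
        if g.contig_id is not None and g.start is not None and g.end is not None:
            exclude = (g.contig_id, g.start, g.end)
        g.offtarget_hits = len(query_offtargets(g.spacer, index, exclude=exclude))
    return list(guides)
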