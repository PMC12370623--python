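"""PAM-anchored protospacer discovery and the two coordinate systems.

A candidate site is anchored at the genomic position of its PAM-proximal
protospacer base (the base immediately 5' of the PAM on the PAM-bearing
strand). Window membership is decided by that anchor: a site belongs to a
window iff its anchor lies inside the window interval, so the PAM itself, and
the 5' end of the spacer, may extend past the window edge. The anchored
element is the dCas9 footprint, which is what the activation geometry cares
about.

Two offset conventions are exposed:

* ATG-relative (library design): the activation scan covers offsets
  -250..-190 bp from the first base of the start codon, in transcription
  direction, negative = upstream.
* TSS-relative (reporter-style constructs): the user supplies the TSS
  position (here, the first base of the ribosome-binding site) and
  :func:`tss_offset` returns the signed distance in transcription direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from ._seq import IUPAC, pam_anchor_positions, revcomp, seq_to_array
from .exceptions import (
    AmbiguousBaseError,
    InsufficientFlankError,
    ValidationError,
    WindowClippedWarning,
)
from .genome_io import GeneAnnotation, GenomeRecord

SPACER_LEN = 20


@dataclass(frozen=True)
class PamSpec:
    """One PAM pattern (IUPAC, 5'->3') with its preference rank (lower = better)."""

    pattern: str
    class_rank: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if not (2 <= len(self.pattern) <= 3):
            raise ValidationError(f"PAM pattern {self.pattern!r}: length must be 2 or 3")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValidationError(
                f"PAM pattern {self.pattern!r}: non-IUPAC characters {sorted(bad)}"
            )


#: The PAM repertoire of the PAM-flexible dCas9 used for activation design:
#: canonical NGG preferred, then NG, then GAA/GAT (one shared rank).
DEFAULT_PAM_SET: tuple[PamSpec, ...] = (
    PamSpec("NGG", 0),
    PamSpec("NG", 1),
    PamSpec("GAA", 2),
    PamSpec("GAT", 2),
)


@dataclass(frozen=True)
class TargetWindow:
    """A genomic interval to scan, tied to a gene anchor and offset bounds.

    ``direction`` is the transcription direction used for offset arithmetic;
    ``anchor_pos`` is the genomic position of the anchor (offset 0).
    """

    contig_id: str
    start: int
    end: int
    gene_id: str
    anchor: str  # "ATG", "TSS" or "REGION"
    offset_bounds: tuple[int, int]
    direction: str = "+"
    anchor_pos: int = 0

    @property
    def length(self) -> int:
        return max(0, self.end - self.start)


def region_window(contig_id: str, start: int, end: int, gene_id: str = "region") -> TargetWindow:
    """A plain interval window (anchor at its left edge, forward direction)."""
    return TargetWindow(
        contig_id=contig_id, start=start, end=end, gene_id=gene_id,
        anchor="REGION", offset_bounds=(0, max(0, end - start - 1)),
        direction="+", anchor_pos=start,
    )


@dataclass(frozen=True)
class CandidateSite:
    """A 20-nt protospacer anchored at a PAM, with genomic coordinates.

    ``spacer`` is written 5'->3' as it would be synthesized; ``pam_strand`` is
    the strand whose sequence literally contains spacer+PAM; ``offset_anchor``
    is the signed offset of the PAM-proximal protospacer base from the window
    anchor (negative = upstream in transcription direction).
    """

    gene_id: str
    spacer: str
    pam: str
    pam_class: PamSpec
    pam_strand: str
    protospacer_start: int
    protospacer_end: int
    offset_anchor: int
    contig_id: str = ""

    @property
    def pam_proximal_pos(self) -> int:
        """Genomic position of the PAM-proximal protospacer base (the anchor)."""
        return self.protospacer_end - 1 if self.pam_strand == "+" else self.protospacer_start

    @property
    def pam_start(self) -> int:
        """Genomic start (forward axis) of the PAM."""
        if self.pam_strand == "+":
            return self.protospacer_end
        return self.protospacer_start - len(self.pam)


def find_pam_sites(
    genome: GenomeRecord,
    region: TargetWindow,
    pams: Sequence[PamSpec] = DEFAULT_PAM_SET,
    strands: Sequence[str] = ("+", "-"),
    require_spacer: bool = True,
) -> list[CandidateSite]:
    """All PAM-anchored candidate sites whose anchor lies inside ``region``.

    One site is emitted per (strand, anchor) position; where several PAM
    patterns match the same anchor (NG is a superset of NGG) the best-ranked
    class wins. Sites whose spacer or PAM would contain an N are dropped.
    With ``require_spacer=False`` (testing aid) sites lacking a full 20-nt
    5' flank are still reported, with a clipped spacer.
    """
    if not pams:
        raise ValidationError("PAM set must be non-empty")
    for s in strands:
        if s not in ("+", "-"):
            raise ValidationError(f"invalid strand {s!r}")
    if region.length <= 0:
        return []
    arr = seq_to_array(genome.sequence)
    seq = genome.sequence
    n = genome.length
    chosen: dict[tuple[str, int], CandidateSite] = {}
    for pam in sorted(pams, key=lambda p: (p.class_rank, p.pattern)):
        plen = len(pam.pattern)
        for strand in strands:
            anchors = pam_anchor_positions(arr, pam.pattern, strand)
            lo, hi = region.start, region.end
            anchors = anchors[(anchors >= lo) & (anchors < hi)]
            for a in anchors:
                a = int(a)
                key = (strand, a)
                if key in chosen:
                    continue
                if strand == "+":
                    ps_start, ps_end = a + 1 - SPACER_LEN, a + 1
                    pam_seq = seq[a + 1 : a + 1 + plen]
                    if ps_start < 0:
                        if require_spacer:
                            continue
                        ps_start = 0
                    spacer = seq[ps_start:ps_end]
                else:
                    ps_start, ps_end = a, a + SPACER_LEN
                    pam_seq = revcomp(seq[a - plen : a])
                    if ps_end > n:
                        if require_spacer:
                            continue
                        ps_end = n
                    spacer = revcomp(seq[ps_start:ps_end])
                if "N" in spacer or "N" in pam_seq:
                    continue
                if region.direction == "+":
                    offset = a - region.anchor_pos
                else:
                    offset = region.anchor_pos - a
                chosen[key] = CandidateSite(
                    gene_id=region.gene_id,
                    spacer=spacer,
                    pam=pam_seq,
                    pam_class=pam,
                    pam_strand=strand,
                    protospacer_start=ps_start,
                    protospacer_end=ps_end,
                    offset_anchor=offset,
                    contig_id=region.contig_id,
                )
    return sorted(
        chosen.values(),
        key=lambda s: (s.protospacer_start, s.pam_strand, s.protospacer_end),
    )


def extract_spacer(
    genome: GenomeRecord,
    pam_position: int,
    strand: str,
    pam_len: int = 3,
    spacer_len: int = SPACER_LEN,
) -> str:
    """The ``spacer_len`` bases immediately 5' of a PAM on the PAM-bearing strand.

    ``pam_position`` is the 0-based genomic start (forward axis) of the PAM.
    For a minus-strand PAM the flank lies at higher forward coordinates and
    the returned spacer is the reverse complement of that slice.
    """
    if strand not in ("+", "-"):
        raise ValidationError(f"invalid strand {strand!r}")
    seq = genome.sequence
    if strand == "+":
        lo, hi = pam_position - spacer_len, pam_position
        if lo < 0:
            raise InsufficientFlankError(
                f"only {pam_position} bases 5' of PAM at {pam_position} on '+'"
            )
        spacer = seq[lo:hi]
    else:
        lo, hi = pam_position + pam_len, pam_position + pam_len + spacer_len
        if hi > genome.length:
            raise InsufficientFlankError(
                f"only {genome.length - lo} bases 5' of PAM at {pam_position} on '-'"
            )
        spacer = revcomp(seq[lo:hi])
    if "N" in spacer:
        raise AmbiguousBaseError("spacer contains ambiguous base N")
    return spacer


def activation_window(
    gene: GeneAnnotation,
    upstream_near: int = 190,
    upstream_far: int = 250,
    contig_length: int | None = None,
) -> TargetWindow:
    """The activation scan window: offsets -far..-near from the start codon.

    Both endpoints inclusive, in the gene's transcription direction (for a
    minus-strand gene the window lies at larger genomic coordinates). With
    defaults (190/250) an unclipped window spans 61 anchor positions. Windows
    running past a contig end are clipped with a :class:`WindowClippedWarning`.
    """
    if not (0 < upstream_near < upstream_far):
        raise ValidationError(
            f"need upstream_far > upstream_near > 0, got {upstream_near}/{upstream_far}"
        )
    p = gene.start_codon_pos
    if gene.strand == "+":
        start, end = p - upstream_far, p - upstream_near + 1
    else:
        start, end = p + upstream_near, p + upstream_far + 1
    raw = (start, end)
    start = max(0, start)
    if contig_length is not None:
        end = min(end, contig_length)
    if end < start:
        end = start
    if (start, end) != raw:
        warnings.warn(
            f"activation window for gene {gene.gene_id!r} clipped to "
            f"[{start}, {end}) at contig end",
            WindowClippedWarning,
            stacklevel=2,
        )
    return TargetWindow(
        contig_id=gene.contig_id, start=start, end=end, gene_id=gene.gene_id,
        anchor="ATG", offset_bounds=(-upstream_far, -upstream_near),
        direction=gene.strand, anchor_pos=p,
    )


def tss_offset(site: CandidateSite, tss_pos: int, strand: str = "+") -> int:
    """Signed distance, in transcription direction, from the TSS to the site anchor.

    Negative = upstream of the TSS; 0 = the anchor sits exactly on the TSS.
    ``strand`` is the transcription unit's strand (not the PAM strand).
    """
    if strand not in ("+", "-"):
        raise ValidationError(f"invalid strand {strand!r}")
    a = site.pam_proximal_pos
    return a - tss_pos if strand == "+" else tss_pos - a
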