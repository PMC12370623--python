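"""Pooled dual-library assembly: oligos, merging, QC statistics, file output.

Guides are ordered as annealed oligo pairs for Golden Gate cloning: each
oligo is the spacer (or its reverse complement) prefixed with a 4-nt
single-stranded overhang matching the digested expression vector. The
default overhang scheme (ACCG / AAAC, BsaI) is this package's own documented
convention for a standard sgRNA acceptor vector and is fully configurable.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp
from .design import GuideRecord
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverhangScheme:
    """Golden Gate overhangs and the Type IIS recognition site to warn about."""

    name: str = "bsaI-sgrna"
    fwd_overhang: str = "ACCG"
    rev_overhang: str = "AAAC"
    recognition_site: str = "GGTCTC"  # BsaI


DEFAULT_SCHEME = OverhangScheme()


@dataclass(frozen=True)
class OligoPair:
    guide_id: str
    forward_oligo: str
    reverse_oligo: str
    overhang_scheme: str
    recognition_site_warning: bool = False


def make_oligos(guide: GuideRecord, scheme: OverhangScheme = DEFAULT_SCHEME) -> OligoPair:
    """Annealed oligo pair for one guide: overhang + spacer / overhang + revcomp.

    A warning flag is set (pair still emitted) if the spacer contains the
    scheme's Type IIS recognition site on either strand, which would be
    re-cut during assembly.
    """
    spacer = guide.spacer
    if not spacer or set(spacer) - set("ACGT"):
        raise ValidationError(
            f"guide {guide.guide_id!r}: spacer must be non-empty ACGT, got {spacer!r}"
        )
    pair = OligoPair(
        guide_id=guide.guide_id,
        forward_oligo=scheme.fwd_overhang + spacer,
        reverse_oligo=scheme.rev_overhang + revcomp(spacer),
        overhang_scheme=scheme.name,
        recognition_site_warning=(
            scheme.recognition_site in spacer
            or revcomp(scheme.recognition_site) in spacer
        ),
    )
    if annealed_insert(pair, scheme) != spacer:  # simulated annealing self-check
        raise ValidationError(f"oligo pair for {guide.guide_id!r} does not anneal")
    return pair


def annealed_insert(pair: OligoPair, scheme: OverhangScheme = DEFAULT_SCHEME) -> str:
    """Reconstruct the double-stranded insert core from an annealed pair."""
    top = pair.forward_oligo[len(scheme.fwd_overhang):]
    bottom = pair.reverse_oligo[len(scheme.rev_overhang):]
    if revcomp(bottom) != top:
        raise ValidationError(
            f"oligo pair {pair.guide_id!r}: strands do not base-pair"
        )
    return top


@dataclass
class LibraryManifest:
    """The pooled library: all guide records plus provenance and QC hooks."""

    guides: list[GuideRecord]
    provenance: dict = field(default_factory=dict)
    collisions: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.guide_id for g in self.guides]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate guide ids {dupes[:5]}")

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(g.role for g in self.guides))

    @property
    def total(self) -> int:
        return len(self.guides)


_ROLE_PREFIX = {"activation": "act", "repression": "rep", "control": "ctl"}


def _as_control_records(controls: Iterable) -> list[GuideRecord]:
    records = []
    for i, c in enumerate(controls):
        if isinstance(c, GuideRecord):
            records.append(c)
        else:  # bare spacer string
            records.append(
                GuideRecord(
                    guide_id=f"nt{i + 1:03d}", gene_id="", role="control", spacer=str(c)
                )
            )
    return records


def merge_libraries(
    activation: Sequence[GuideRecord],
    repression: Sequence[GuideRecord],
    controls: Sequence = (),
    provenance: Optional[dict] = None,
) -> LibraryManifest:
    """Pool the three components, prefixing guide ids by role.

    Spacer sequences shared across roles are logged as collisions but every
    record is kept; duplicate guide ids after prefixing are an error.
    """
    merged: list[GuideRecord] = []
    for group, role in (
        (activation, "activation"),
        (repression, "repression"),
        (_as_control_records(controls), "control"),
    ):
        prefix = _ROLE_PREFIX[role]
        for g in group:
            merged.append(replace(g, guide_id=f"{prefix}_{g.guide_id}", role=role))
    by_spacer: dict[str, set[str]] = {}
    for g in merged:
        by_spacer.setdefault(g.spacer, set()).add(g.role)
    collisions = sorted(
        (sp, tuple(sorted(roles))) for sp, roles in by_spacer.items() if len(roles) > 1
    )
    for sp, roles in collisions:
        logger.warning("spacer %s present in roles %s; all records kept", sp, roles)
    return LibraryManifest(
        guides=merged, provenance=provenance or {}, collisions=collisions
    )


@dataclass
class QCStats:
    genes_covered: dict[str, int]
    mean_guides_per_gene: dict[str, float]
    pam_histogram: dict[str, int]
    gc_summary: dict[str, float]
    offtarget_histogram: dict[str, int]


def _gc_fraction(spacer: str) -> float:
    return (spacer.count("G") + spacer.count("C")) / len(spacer)


def compute_stats(manifest: LibraryManifest) -> QCStats:
    """Coverage, PAM-class and GC summaries over the pooled library.

    Mean guides/gene is computed per role over genes with at least one guide
    (the "average of five gRNAs per gene" convention).
    """
    if not manifest.guides:
        raise ValidationError("cannot compute statistics of an empty manifest")
    genes_covered: dict[str, int] = {}
    mean_gpg: dict[str, float] = {}
    for role in sorted({g.role for g in manifest.guides}):
        per_gene = Counter(
            g.gene_id for g in manifest.guides if g.role == role and g.gene_id
        )
        genes_covered[role] = len(per_gene)
        mean_gpg[role] = (
            sum(per_gene.values()) / len(per_gene) if per_gene else 0.0
        )
    pam_hist = dict(Counter(g.pam_class or "none" for g in manifest.guides))
    gc = np.array([_gc_fraction(g.spacer) for g in manifest.guides])
    gc_summary = {
        "mean": float(gc.mean()),
        "min": float(gc.min()),
        "q25": float(np.quantile(gc, 0.25)),
        "median": float(np.median(gc)),
        "q75": float(np.quantile(gc, 0.75)),
        "max": float(gc.max()),
    }
    ot_hist = dict(
        Counter(
            str(g.offtarget_hits) if g.offtarget_hits is not None else "unknown"
            for g in manifest.guides
        )
    )
    return QCStats(genes_covered, mean_gpg, pam_hist, gc_summary, ot_hist)


_TSV_COLUMNS = [
    "guide_id", "gene_id", "role", "spacer", "pam", "pam_class", "contig_id",
    "start", "end", "strand", "offset_anchor", "offtarget_hits",
    "selection_rank_trace", "meta",
]
_INT_COLUMNS = ("start", "end", "offset_anchor", "offtarget_hits")


def write_library(
    manifest: LibraryManifest,
    out_dir,
    formats: Sequence[str] = ("tsv", "fasta", "bed"),
    scheme: Optional[OverhangScheme] = None,
) -> dict[str, Path]:
    """Write the manifest as TSV (always re-readable), FASTA, BED and sidecars.

    The provenance JSON sidecar is always written. With ``scheme``, a
    cloning-oligo TSV is emitted as well. BED lines cover the protospacer
    intervals of mapped guides (controls have no locus and are skipped there).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if "tsv" in formats:
        rows = []
        for g in manifest.guides:
            row = {c: getattr(g, c) for c in _TSV_COLUMNS if c != "meta"}
            row["meta"] = json.dumps(g.meta, sort_keys=True)
            for c in _TSV_COLUMNS:
                if row[c] is None:
                    row[c] = ""
            rows.append(row)
        df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
        paths["tsv"] = out_dir / "library.tsv"
        df.to_csv(paths["tsv"], sep="\t", index=False)
    if "fasta" in formats:
        paths["fasta"] = out_dir / "spacers.fasta"
        with open(paths["fasta"], "w") as fh:
            SeqIO.write(
                (
                    SeqRecord(Seq(g.spacer), id=g.guide_id, description="")
                    for g in manifest.guides
                ),
                fh,
                "fasta",
            )
    if "bed" in formats:
        paths["bed"] = out_dir / "protospacers.bed"
        with open(paths["bed"], "w") as fh:
            for g in manifest.guides:
                if g.contig_id is None or g.start is None:
                    continue
                fh.write(
                    f"{g.contig_id}\t{g.start}\t{g.end}\t{g.guide_id}\t.\t{g.strand}\n"
                )
    if scheme is not None:
        paths["oligos"] = out_dir / "oligos.tsv"
        with open(paths["oligos"], "w") as fh:
            fh.write("guide_id\tforward_oligo\treverse_oligo\tscheme\twarning\n")
            for g in manifest.guides:
                pair = make_oligos(g, scheme)
                fh.write(
                    f"{pair.guide_id}\t{pair.forward_oligo}\t{pair.reverse_oligo}"
                    f"\t{pair.overhang_scheme}\t{int(pair.recognition_site_warning)}\n"
                )
    paths["provenance"] = out_dir / "provenance.json"
    with open(paths["provenance"], "w") as fh:
        json.dump(
            {"provenance": manifest.provenance, "counts": manifest.counts,
             "total": manifest.total},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    return paths


def read_library(tsv_path, provenance_path=None) -> LibraryManifest:
    """Re-read a library TSV written by :func:`write_library` (round-trip safe)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    guides: list[GuideRecord] = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in _TSV_COLUMNS:
            val = row[c] if c in row else ""
            if c == "meta":
                kwargs[c] = json.loads(val) if val else {}
            elif val == "":
                kwargs[c] = None if c not in ("gene_id", "selection_rank_trace") else ""
            elif c in _INT_COLUMNS:
                kwargs[c] = int(val)
            else:
                kwargs[c] = val
        guides.append(GuideRecord(**kwargs))
    provenance = {}
    if provenance_path is not None:
        with open(provenance_path) as fh:
            provenance = json.load(fh).get("provenance", {})
    return LibraryManifest(guides=guides, provenance=provenance)
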