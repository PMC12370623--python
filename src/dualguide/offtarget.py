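"""Seed-based off-target screening and non-targeting control generation.

The match criterion is identity of the 12 PAM-proximal spacer bases (the
seed) immediately 5' of an NGG PAM occurrence, genome-wide on both strands.
Longer agreement is reported through ``matched_len`` (greedy 5' extension)
but plays no part in the uniqueness decision: the criterion is a threshold,
not a mismatch model.

Non-targeting controls are rejection-sampled random 20-mers with zero seed
hits anywhere in the genome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np

from ._seq import match_positions, revcomp, seq_to_array
from .exceptions import SamplingExhaustedError, ValidationError
from .genome_io import GenomeRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class SeedOccurrence(NamedTuple):
    contig_id: str
    pam_position: int  # 0-based genomic start of the PAM (forward axis)
    strand: str


@dataclass
class OffTargetHit:
    contig_id: str
    pam_position: int
    strand: str
    matched_len: int


@dataclass
class SeedIndex:
    """Genome-wide map: seed (PAM-proximal k-mer) -> PAM occurrences, both strands."""

    seed_len: int
    pam_pattern: str
    occurrences: Mapping[str, list[SeedOccurrence]]
    sequences: Mapping[str, str]

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.occurrences.values())


def build_seed_index(
    genome: Union[GenomeRecord, Iterable[GenomeRecord]],
    seed_len: int = 12,
    pam: str = "NGG",
) -> SeedIndex:
    """Index every PAM occurrence (both strands) with >= ``seed_len`` 5' bases.

    Occurrences whose seed or PAM would contain an N are skipped.
    """
    records = [genome] if isinstance(genome, GenomeRecord) else list(genome)
    if not records:
        raise ValidationError("genome must be non-empty")
    if seed_len < 1:
        raise ValidationError("seed_len must be >= 1")
    pam = pam.upper()
    plen = len(pam)
    occ: dict[str, list[SeedOccurrence]] = defaultdict(list)
    for rec in records:
        arr = seq_to_array(rec.sequence)
        seq = rec.sequence
        for q in match_positions(arr, pam):  # plus strand: seed 5' = lower coords
            q = int(q)
            if q < seed_len:
                continue
            seed = seq[q - seed_len : q]
            if "N" in seed:
                continue
            occ[seed].append(SeedOccurrence(rec.contig_id, q, "+"))
        for q in match_positions(arr, revcomp(pam)):  # minus strand PAM at [q, q+plen)
            q = int(q)
            if q + plen + seed_len > rec.length:
                continue
            seed = revcomp(seq[q + plen : q + plen + seed_len])
            if "N" in seed:
                continue
            occ[seed].append(SeedOccurrence(rec.contig_id, q, "-"))
    for hits in occ.values():
        hits.sort()
    return SeedIndex(
        seed_len=seed_len,
        pam_pattern=pam,
        occurrences=dict(occ),
        sequences={r.contig_id: r.sequence for r in records},
    )


def _protospacer_interval(
    occ: SeedOccurrence, spacer_len: int, pam_len: int
) -> tuple[int, int]:
    if occ.strand == "+":
        return occ.pam_position - spacer_len, occ.pam_position
    return occ.pam_position + pam_len, occ.pam_position + pam_len + spacer_len


def _matched_len(spacer: str, seq: str, occ: SeedOccurrence, seed_len: int, pam_len: int) -> int:
    """Greedy 5' extension of the seed match along the genome."""
    ml = seed_len
    j = len(spacer) - seed_len - 1
    if occ.strand == "+":
        i = occ.pam_position - seed_len - 1
        while j >= 0 and i >= 0 and seq[i] == spacer[j]:
            ml += 1
            i -= 1
            j -= 1
    else:
        i = occ.pam_position + pam_len + seed_len
        n = len(seq)
        while j >= 0 and i < n and _COMP[seq[i]] == spacer[j]:
            ml += 1
            i += 1
            j -= 1
    return ml


def query_offtargets(
    spacer: str,
    index: SeedIndex,
    exclude: Optional[tuple[str, int, int]] = None,
) -> list[OffTargetHit]:
    """All indexed occurrences whose seed equals the spacer's PAM-proximal seed.

    ``exclude`` is a genomic interval ``(contig_id, start, end)``; occurrences
    whose protospacer overlaps it (typically the guide's own locus) are
    dropped. A guide is *unique* iff its only hit is its own locus.
    """
    spacer = spacer.upper()
    k = index.seed_len
    if len(spacer) < k:
        raise ValidationError(
            f"spacer length {len(spacer)} shorter than seed_len {k}"
        )
    seed = spacer[-k:]
    plen = len(index.pam_pattern)
    hits: list[OffTargetHit] = []
    for occ in index.occurrences.get(seed, ()):
        if exclude is not None and occ.contig_id == exclude[0]:
            ps, pe = _protospacer_interval(occ, len(spacer), plen)
            if ps < exclude[2] and exclude[1] < pe:
                continue
        ml = _matched_len(spacer, index.sequences[occ.contig_id], occ, k, plen)
        hits.append(OffTargetHit(occ.contig_id, occ.pam_position, occ.strand, ml))
    return hits


def is_unique(
    spacer: str, index: SeedIndex, own_locus: tuple[str, int, int]
) -> bool:
    """True iff the spacer has no seed hits outside its own locus."""
    return not query_offtargets(spacer, index, exclude=own_locus)


_BASES = "ACGT"


def generate_nontargeting(
    genome: Union[GenomeRecord, Iterable[GenomeRecord], None],
    index: SeedIndex,
    n: int,
    rng_seed: int,
    attempt_cap: int = 100_000,
    spacer_len: int = 20,
) -> list[str]:
    """``n`` distinct random 20-mers with zero seed+PAM hits in the genome.

    Rejection sampling from uniform ACGT; the same ``rng_seed`` reproduces the
    same spacers byte for byte. ``genome`` is accepted for interface symmetry
    (the decision is made entirely against ``index``).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        if attempts >= attempt_cap:
            raise SamplingExhaustedError(
                f"found only {len(out)}/{n} non-targeting spacers in "
                f"{attempt_cap} attempts"
            )
        attempts += 1
        sp = "".join(_BASES[i] for i in rng.integers(0, 4, spacer_len))
        if sp in seen:
            continue
        seen.add(sp)
        if query_offtargets(sp, index):
            continue
        out.append(sp)
    return out
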