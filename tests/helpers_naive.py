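"""Independent oracles used by the tests: deliberately naive re-implementations.

These share no code path with the package: PAM matching is character-by-
character over every position of an explicitly reverse-complemented string,
and off-target search slides the literal seed+PAM string with ``str.find``.
"""

from __future__ import annotations

IUPAC_SETS = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _matches(segment: str, pattern: str) -> bool:
    return len(segment) == len(pattern) and all(
        c in IUPAC_SETS[p] for c, p in zip(segment, pattern)
    )


def naive_pam_sites(seq, pams, strands=("+", "-"), spacer_len=20):
    """Set of (strand, forward-axis anchor, pam pattern, spacer) by full enumeration.

    Scans each requested strand as an explicit oriented string, position by
    position, applying the best-rank-wins rule per (strand, anchor). Sites
    without a full N-free spacer are dropped, mirroring the library contract.
    """
    n = len(seq)
    best: dict[tuple[str, int], tuple[int, str, str]] = {}
    ordered = sorted(pams, key=lambda p: (p.class_rank, p.pattern))
    for strand in strands:
        oriented = seq if strand == "+" else naive_revcomp(seq)
        for pam in ordered:
            plen = len(pam.pattern)
            for q in range(n - plen + 1):
                if not _matches(oriented[q : q + plen], pam.pattern):
                    continue
                if q < spacer_len:
                    continue
                spacer = oriented[q - spacer_len : q]
                if "N" in spacer or "N" in oriented[q : q + plen]:
                    continue
                anchor_fwd = q - 1 if strand == "+" else n - q
                key = (strand, anchor_fwd)
                if key not in best:
                    best[key] = (pam.class_rank, pam.pattern, spacer)
    return {
        (strand, anchor, pattern, spacer)
        for (strand, anchor), (_, pattern, spacer) in best.items()
    }


def bruteforce_seed_hits(seq, spacer, seed_len=12, contig="c"):
    """Set of (contig, pam_position, strand) where seed sits 5' of an NGG."""
    seed = spacer[-seed_len:]
    hits = set()
    p = seq.find(seed)
    while p >= 0:
        q = p + seed_len
        if q + 3 <= len(seq) and seq[q + 1 : q + 3] == "GG":
            hits.add((contig, q, "+"))
        p = seq.find(seed, p + 1)
    rcseed = naive_revcomp(seed)
    p = seq.find(rcseed)
    while p >= 0:
        if p >= 3 and seq[p - 3 : p - 1] == "CC":
            hits.add((contig, p - 3, "-"))
        p = seq.find(rcseed, p + 1)
    return hits


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
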