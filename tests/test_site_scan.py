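"""PAM scanning, spacer extraction and coordinate conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualguide import (
    CandidateSite,
    DEFAULT_PAM_SET,
    GeneAnnotation,
    GenomeRecord,
    InsufficientFlankError,
    PamSpec,
    ValidationError,
    WindowClippedWarning,
    activation_window,
    extract_spacer,
    find_pam_sites,
    region_window,
    revcomp,
    tss_offset,
)
from helpers_naive import naive_pam_sites, random_dna

NGG = PamSpec("NGG", 0)
NG = PamSpec("NG", 1)


def _sites_as_tuples(sites):
    return {
        (s.pam_strand, s.pam_proximal_pos, s.pam_class.pattern, s.spacer)
        for s in sites
    }


class TestFindPamSites:
    def test_single_forward_pam_without_spacer_requirement(self):
        genome = GenomeRecord("c", "ACCTGG")
        sites = find_pam_sites(
            genome, region_window("c", 0, 6), pams=[NGG], strands=("+",),
            require_spacer=False,
        )
        assert len(sites) == 1
        assert sites[0].pam_start == 3
        assert sites[0].pam == "TGG"

    def test_region_shorter_than_pam_is_empty_not_error(self):
        genome = GenomeRecord("c", "AC")
        assert find_pam_sites(genome, region_window("c", 0, 2), pams=[NGG]) == []

    def test_invalid_pam_characters_rejected(self):
        with pytest.raises(ValidationError, match="non-IUPAC"):
            PamSpec("NXG", 0)

    def test_ngg_wins_over_ng_at_the_same_anchor(self):
        """A TGG matches both NGG and NG at one anchor: reported once, as NGG."""
        seq = "A" * 25 + "TGG" + "A" * 20 + "TG" + "A" * 20
        genome = GenomeRecord("c", seq)
        sites = find_pam_sites(
            genome, region_window("c", 0, len(seq)), pams=[NGG, NG], strands=("+",)
        )
        by_anchor = {s.pam_proximal_pos: s for s in sites}
        # the planted TGG (PAM at 25) anchors at 24 and is classed NGG, once
        assert by_anchor[24].pam_class.pattern == "NGG"
        assert sum(1 for s in sites if s.pam_proximal_pos == 24) == 1
        # the planted TG (PAM at 48) is an NG site
        assert by_anchor[47].pam_class.pattern == "NG"
        # no site anywhere is labelled NG where NGG also matches its anchor
        for s in sites:
            if s.pam_class.pattern == "NG":
                assert not seq[s.pam_start : s.pam_start + 3].endswith("GG")

    def test_minus_strand_site_matches_manual_reverse_complement(self):
        # forward CCA + 20 nt: minus strand reads spacer(20) + TGG
        flank = "ATGCATGCATGCATGCATGC"
        seq = "CCA" + revcomp(flank) + "TTTT"
        genome = GenomeRecord("c", seq)
        sites = find_pam_sites(
            genome, region_window("c", 0, len(seq)), pams=[NGG], strands=("-",)
        )
        assert len(sites) == 1
        assert sites[0].spacer == flank
        assert sites[0].pam == "TGG"
        assert sites[0].protospacer_start == 3

    def test_spacer_and_pam_reslice_from_genome(self, small_truth):
        genome = small_truth.genome
        sites = find_pam_sites(genome, region_window(genome.contig_id, 0, 3000))
        assert sites, "scan found nothing in 3 kb"
        for s in sites:
            segment = genome.sequence[s.protospacer_start : s.protospacer_end]
            if s.pam_strand == "+":
                pam = genome.sequence[s.pam_start : s.pam_start + len(s.pam)]
                assert segment == s.spacer and pam == s.pam
            else:
                assert revcomp(segment) == s.spacer
                pam = genome.sequence[s.pam_start : s.pam_start + len(s.pam)]
                assert revcomp(pam) == s.pam

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(60, 400))
    def test_matches_naive_enumeration_on_random_sequences(self, seed, length):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, length)
        genome = GenomeRecord("c", seq)
        sites = find_pam_sites(genome, region_window("c", 0, length))
        assert _sites_as_tuples(sites) == naive_pam_sites(seq, DEFAULT_PAM_SET)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_minus_scan_equals_mirrored_plus_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 300)
        fwd = GenomeRecord("c", seq)
        rev = GenomeRecord("c", revcomp(seq))
        minus = find_pam_sites(fwd, region_window("c", 0, 300), strands=("-",))
        plus_on_rc = find_pam_sites(rev, region_window("c", 0, 300), strands=("+",))
        mirrored = {(300 - 1 - s.pam_proximal_pos, s.pam_class.pattern, s.spacer)
                    for s in plus_on_rc}
        got = {(s.pam_proximal_pos, s.pam_class.pattern, s.spacer) for s in minus}
        assert got == mirrored


class TestExtractSpacer:
    def test_plus_strand_exact_slice(self):
        seq = "ACGTACGTACGTACGTACGT" + "TGG"
        genome = GenomeRecord("c", seq)
        assert extract_spacer(genome, 20, "+") == seq[:20]

    def test_minus_strand_reverse_complement(self):
        core = "ACGTACGTACGTACGTACGT"
        seq = "CCA" + revcomp(core)
        genome = GenomeRecord("c", seq)
        assert extract_spacer(genome, 0, "-") == core

    def test_insufficient_flank_raises(self):
        genome = GenomeRecord("c", "A" * 30)
        with pytest.raises(InsufficientFlankError):
            extract_spacer(genome, 10, "+")


class TestActivationWindow:
    def test_plus_strand_window_covers_750_to_810(self):
        gene = GeneAnnotation("g", "c", 1000, 1900, "+")
        w = activation_window(gene)
        assert (w.start, w.end) == (750, 811)
        assert w.length == 61

    def test_minus_strand_window_covers_2089_to_2149(self):
        gene = GeneAnnotation("g", "c", 1000, 1900, "-")
        w = activation_window(gene)
        assert (w.start, w.end) == (2089, 2150)
        assert w.length == 61

    def test_window_near_contig_start_clipped_with_warning(self):
        gene = GeneAnnotation("g", "c", 100, 400, "+")
        with pytest.warns(WindowClippedWarning):
            w = activation_window(gene)
        assert w.length == 0

    def test_invalid_bounds_rejected(self):
        gene = GeneAnnotation("g", "c", 1000, 1900, "+")
        with pytest.raises(ValidationError):
            activation_window(gene, upstream_near=250, upstream_far=190)


def _site_at(anchor, strand="+"):
    """A minimal candidate whose PAM-proximal base sits at ``anchor``."""
    if strand == "+":
        start, end = anchor - 19, anchor + 1
    else:
        start, end = anchor, anchor + 20
    return CandidateSite(
        gene_id="g", spacer="A" * 20, pam="TGG", pam_class=NGG,
        pam_strand=strand, protospacer_start=start, protospacer_end=end,
        offset_anchor=0, contig_id="c",
    )


class TestTssOffset:
    def test_site_191_bp_upstream_reports_minus_191(self):
        assert tss_offset(_site_at(809), tss_pos=1000, strand="+") == -191

    def test_site_on_tss_reports_zero(self):
        assert tss_offset(_site_at(1000), tss_pos=1000, strand="+") == 0

    def test_minus_strand_upstream_site_is_negative(self):
        # upstream of a minus-strand unit lies at larger genomic coordinates
        assert tss_offset(_site_at(1015, "-"), tss_pos=1000, strand="-") == -15

    @pytest.mark.parametrize("offset", [66, 158, 28])
    def test_downstream_sites_are_positive(self, offset):
        assert tss_offset(_site_at(1000 + offset), tss_pos=1000, strand="+") == offset
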