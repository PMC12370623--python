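# Methods

## Scope and model

`dualguide` implements rule-based guide design for a dual-mode bacterial
CRISPRa/i system built on a PAM-flexible dead Cas9. The model of guide
placement is purely geometric: activation requires the effector to sit in a
narrow window upstream of the promoter region (parameterised as 190–250 bp
upstream of the start codon, the ATG serving as the anchor available for
every annotated gene), while repression requires a roadblock on the
non-template strand near the transcription start or early coding sequence.
No activity model (on-target efficacy score, secondary structure, GC
filter) is applied: candidate ordering is by PAM class and geometry only.

## Coordinate contract

All internal coordinates are 0-based half-open on the forward genome axis;
GFF3/GenBank (1-based inclusive) and BED (0-based half-open) conventions are
converted exactly once at the file boundary. A gene's anchor is the first
base of its start codon: `start` on the plus strand, `end − 1` on the minus
strand. A candidate site is *anchored* at its PAM-proximal protospacer base;
window membership tests that anchor, so a PAM or the spacer 5′ end may
extend past the window edge — the anchored element is the dCas9 footprint,
which is what the activation geometry constrains. The endpoints −250 and
−190 are both inclusive, giving 61 anchor positions per unclipped window;
both values are configurable.

Two offset systems are exposed. Library design is entirely ATG-relative.
TSS-relative offsets (TSS = first base of the ribosome-binding site, in the
reporter convention) are provided as a utility for reporter-style constructs
where the user supplies the TSS position; signs are negative upstream in
transcription direction, so a site 191 bp upstream reports −191 and an
early-CDS site reports a positive offset such as +28.

## PAM scanning

The scanner matches IUPAC patterns with per-letter boolean lookup tables
over the byte array of the sequence (vectorised with numpy), on both strands;
a minus-strand PAM is located by matching the reverse-complemented pattern
on the forward axis. One site is emitted per (strand, anchor): where several
patterns match the same anchor (every NGG is also an NG) the best-ranked
class wins, preventing duplicate guides that differ only in PAM label. The
default repertoire is NGG (rank 0) < NG (1) < GAA = GAT (2); GAA and GAT
share a rank deliberately, since no efficiency ordering between them is
established, and the remaining tie-break keys keep selection deterministic.
Genomic `N` matches no pattern letter, and any site whose spacer or PAM
would contain an `N` is dropped: such guides are ambiguous to synthesize.
Both strands are scanned by default (`strands` restricts this); genomes are
treated as linear, so windows are clipped at contig ends with a warning.

## Selection rules

Per gene, candidates are ranked by (1) PAM class rank, (2) absolute distance
of the anchor from the −190 window edge, (3) lexicographically smallest
spacer; the top candidate is the gene's guide. Rule 2 reflects that the
most effective activation sites cluster at the promoter-proximal end of the
window; rule 3 exists only to make the outcome a pure function of the input,
replacing manual curation with an auditable tie-break. `selection_rank_trace`
records why each winner won.

Operon handling ships in two modes because the underlying operation is
genuinely ambiguous: `dedup` designs only for the transcriptional leader
(5′-most gene) of each operon and reports the other members as covered via
their leader; `all-genes` designs for every gene. Operon membership comes
from an explicit TSV when available, otherwise from adjacency inference
(consecutive same-strand genes with intergenic gap ≤ 50 bp), which is a
deliberately naive stand-in for a curated operon database.

Repression guides use the window −20…+100 around the ATG on the
non-template strand only, ranked by |offset| (closest to the start codon
first, mirroring the observed efficacy ordering of early-CDS over
downstream sites), then PAM class, then spacer; up to k guides per gene
(default 1). External repression libraries are imported with role
`repression`, optionally re-mapped onto the genome (leftmost occurrence on
either strand); unmappable spacers are flagged, never dropped.

## Off-target criterion

A guide hits a locus iff its 12 PAM-proximal bases occur identically,
5′-adjacent to an NGG, anywhere in the genome (both strands). This is a
threshold criterion, not a mismatch model: `matched_len` reports how far
identity extends 5′ of the seed (greedy extension), but plays no part in
the uniqueness decision. Off-target screening of library guides is
report-only (the count is recorded, the guide retained); the hard zero-hit
requirement applies to non-targeting controls, which are rejection-sampled
uniform 20-mers, deterministic per seed, with a configurable attempt cap.
Only NGG is indexed for off-target PAMs by default; the `pam` argument of
the index builder admits a more conservative repertoire.

## Library assembly

Pooling prefixes guide ids by role (`act_`, `rep_`, `ctl_`); spacer
sequences shared across roles are logged as collisions but all records are
kept. Oligo pairs are `fwd_overhang + spacer` and
`rev_overhang + revcomp(spacer)` under a named scheme (default ACCG/AAAC
with BsaI recognition site GGTCTC — a common sgRNA acceptor-vector
convention, chosen here as a documented default and fully configurable);
emission self-checks that the pair anneals back to the spacer, and flags
spacers containing the recognition site. QC statistics cover per-role gene
coverage, mean guides/gene over genes with ≥ 1 guide, PAM-class histogram,
spacer GC distribution and the off-target-hit histogram. A provenance JSON
(config, genome identifier, tool version, seed) accompanies every output
set.

## Synthetic genomes and what they do (not) show

The fixture generator emulates the structural assumptions of the scan:
genes of 300 bp on both strands, operons of up to 4 adjacent same-strand
genes with 15–45 bp internal gaps, 560–640 bp between transcription units
(spacing chosen so windows and planted sequence writes can never collide),
uniform-composition background with configurable GC (E. coli is ~0.508;
tests default to 0.5 so PAM density is controlled). Each gene's window
neighbourhood is re-sampled to A/T-only background before one site
(A/T spacer + TGG PAM, random strand, random in-window offset) is planted:
an A/T region can anchor no PAM of any class on either strand, so the
planted site is provably the unique top-class candidate and the documented
ranking must recover it exactly. Off-target fixtures overwrite intergenic
background with spacer+CGG copies (overwriting, not inserting, so all
coordinates stay valid) and verify the resulting copy count by brute force.

This construction makes planted-truth recovery exact, which is the point —
but it also means passing tests demonstrate correctness of the selection
*rules*, not performance on real promoter sequence, where windows typically
hold many competing candidates of several classes, annotation start codons
may be mis-called, and operon structure is messier than a 50-bp gap rule.
Real-genome runs should therefore use a curated operon table where
available.

## Numerical and procedural choices

* Determinism everywhere: all randomness flows through explicit
  `numpy.random.default_rng` seeds; selection is order-independent
  (inputs are sorted internally); fixture emission is byte-stable per seed.
* Problem sizes in the test and acceptance runs (10-kb scan sequences,
  50-kb off-target genome, 100–120-gene design fixtures, 500 queried
  spacers, 100 controls) were chosen as the smallest sizes at which every
  code path — multi-operon layouts, both strands, planted duplications,
  clipped windows — is exercised with comfortable margins.
* The published pooled-library accounting (3,640 activating + 21,417
  repressing = 25,057 guides) is reproduced through the merge machinery
  with synthetic component records of those sizes; the external repression
  library itself is an imported artifact, not re-derived.
* Degenerate inputs: empty windows return empty candidate lists (data, not
  errors); a region shorter than a PAM yields no sites; empty manifests are
  rejected by the statistics step; exhausted control sampling raises rather
  than returning short.

## Known limitations

No mismatch-tolerant off-target scoring (CFD/MIT-style), no efficacy
prediction, no circular-origin window wrapping (sequences are linear), no
essentiality-aware filtering, and eukaryotic annotation features (introns,
UTRs) are out of scope. The operon-dedup interpretation of redundancy
elimination is one of two defensible readings; both are shipped and neither
is claimed as canonical.
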