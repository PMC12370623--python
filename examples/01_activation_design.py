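"""Design one activation guide per gene on a small synthetic genome.

Builds a 12-gene genome with operons, scans the -250..-190 window upstream of
each start codon for PAM-anchored candidates, and applies the selection rules
(NGG preferred, operon leaders only, one guide per gene).
"""

from dualguide import (
    covered_via_operon,
    enumerate_activation_candidates,
    not_designable,
    select_guides,
    synth_genome,
)

truth = synth_genome(n_genes=12, operon_fraction=0.4, seed=11)
print(f"genome: {truth.genome.length} bp, {len(truth.genes)} genes, "
      f"{len(set(truth.operon_map.mapping.values()))} multi-gene operons")

candidates = enumerate_activation_candidates(truth.genome, truth.genes)
guides = select_guides(candidates, truth.operon_map)
covered = covered_via_operon(truth.genes, truth.operon_map, guides)

print(f"{len(guides)} activation guides (one per operon leader / singleton)")
print(f"{len(covered)} genes covered indirectly through their operon leader")
print(f"not designable: {not_designable(candidates) or 'none'}")
for g in guides[:3]:
    # offset_anchor is the guide's PAM-proximal base relative to the start
    # codon: -200 means 200 bp upstream, inside the activation window
    print(f"  {g.guide_id}: {g.spacer} {g.pam_class} at {g.offset_anchor:+d}")
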