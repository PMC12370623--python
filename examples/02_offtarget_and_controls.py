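"""Seed-based off-target screening and non-targeting control generation.

Plants three copies of one spacer into a synthetic genome, shows that the
12-mer-seed + NGG query finds exactly the planted copies, and then draws
non-targeting controls with zero hits anywhere.
"""

from dualguide import (
    build_seed_index,
    generate_nontargeting,
    plant_offtarget,
    query_offtargets,
    synth_genome,
)

truth = synth_genome(n_genes=6, seed=17)
spacer = "ACGTTACGGATCAATTCGAT"
plant_offtarget(truth, spacer, copies=3)

index = build_seed_index(truth.genome)  # every NGG occurrence, both strands
hits = query_offtargets(spacer, index)
print(f"indexed {index.n_occurrences} seed+NGG occurrences in "
      f"{truth.genome.length} bp")
print(f"{len(hits)} hits for the planted spacer (3 copies were planted):")
for h in hits:
    # matched_len >= 12: how far the seed identity extends 5' of the PAM
    print(f"  {h.contig_id}:{h.pam_position} ({h.strand}), matched {h.matched_len} nt")

controls = generate_nontargeting(truth.genome, index, n=5, rng_seed=42)
print("non-targeting controls (zero seed hits each):")
for sp in controls:
    assert not query_offtargets(sp, index)
    print(f"  {sp}")
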