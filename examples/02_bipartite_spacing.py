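"""(A/U)AA core scanning and bipartite-site spacing on printed oligo sequences.

The KH dimer engages two (A/U)AA cores on one RNA only when they are
separated by more than 15 intervening nucleotides; this script scans the
oligos used in the binding assays and a synthetic CLIP set to show where
that threshold bites.
"""

from starbind import (
    TagGeneratorSpec,
    find_bipartite_sites,
    generate_control,
    generate_tags,
    max_separation,
    scan_cores,
    spacing_distribution,
)

SRE4 = "UUUGGGGGUUCAAUAAAAAUUUUCACUAUCCUAUUAACAGUUCCGCCGCUCC"

hits = scan_cores(SRE4)
print(f"SRE-4 cores at 0-based positions {[h.start for h in hits]}, "
      f"max separation {max_separation(hits)} nt")
print("  -> 17 intervening nt: a genuine bipartite site (> 15 nt threshold)\n")

for label, seq in [("(UAAA)x4", "UAAA" * 4), ("(UAAA)x8", "UAAA" * 8)]:
    sites = find_bipartite_sites(seq)
    sep = max(max_separation(scan_cores(seq)), 0)
    verdict = f"site, separation up to {max(s.separation for s in sites)}" if sites else "no site"
    print(f"{label:9s} max core separation {sep:>2d} nt -> {verdict}")
print("  -> only the longer repeat offers two cores a dimer can span,\n"
      "     matching the splicing response of the corresponding inserts\n")

print("linker ladder UAAA-Cn-UAAA (separation tracks linker length):")
for n in (5, 10, 15, 20, 25, 30):
    seq = "UAAA" + "C" * n + "UAAA"
    sep = max_separation(scan_cores(seq))
    has = bool(find_bipartite_sites(seq, max_separation_allowed=None))
    print(f"  C{n:<2d}: max separation {sep:>2d} nt, bipartite site: {has}")

clip = generate_tags(TagGeneratorSpec(n_tags=2000, embed_fraction=0.5, seed=3))
control = generate_control([len(t) for t in clip], seed=4)
d_clip = spacing_distribution(clip, max_distance=50)
d_ctrl = spacing_distribution(control, max_distance=50)
w = slice(20, 31)
fold = d_clip.normalized_count[w].sum() / d_ctrl.normalized_count[w].sum()
print(f"\nsynthetic CLIP vs control, normalized tag fraction with max separation "
      f"20-30 nt:\n  {d_clip.normalized_count[w].sum():.3f} vs "
      f"{d_ctrl.normalized_count[w].sum():.3f}  ({fold:.1f}-fold enrichment)")
print("  -> the embedded-pair spacing window stands out over the random background")
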