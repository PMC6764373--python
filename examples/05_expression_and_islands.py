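"""Transcript coverage, polyA degradation islands, and expression fold
change with the published worked example.

PolyA-selected reads mark transcripts tagged for degradation; deep
contiguous stacks of them ("islands", depth > 500) localise dispensable
regions. Expression is length-normalised: c = reads/length per region,
fold F = c_region / c_background.
"""

import mitokit as mk

config = mk.SimulationConfig(seed=42)
chromosomes, annotations, truth = mk.generate_mitogenome(config)
_, polya, refs = mk.simulate_transcript_alignments(chromosomes, annotations,
                                                   truth, config)
cmap = mk.ConcatMap(chromosomes)

tracks, _ = mk.compute_coverage(polya, refs)
islands, fraction = mk.polya_islands(tracks["mt_concat"], annotations,
                                     min_depth=500, min_len=50,
                                     concat_map=cmap)
print(f"{len(islands)} polyA islands cover {fraction:.2%} of the genome:")
for i in islands:
    print(f"  {i.chrom}:{i.start + 1}-{i.end} depth {i.mean_depth:.0f} "
          f"({', '.join(sorted(i.feature_classes))})")
print("(islands match the planted degradation regions; one sits in an "
      "intron, the rest are intergenic)")

# the published worked example: region lengths and deduplicated mapped
# read counts in, normalised counts and folds out
bg = mk.expression_from_counts("non-coding region", 1000, 164)
nad6 = mk.expression_from_counts("nad6", 804, 23970, background_norm=bg.normalized)
rbcl = mk.expression_from_counts("rbcL C-terminus", 231, 573,
                                 background_norm=bg.normalized)
print("\nexpression fold change (L, N -> c = N/L, F = c/c_bg):")
for r in (nad6, bg, rbcl):
    fold = f"F={r.fold:.2f}" if r.fold is not None else "background"
    print(f"  {r.name}: L={r.length} N={r.n_reads:,} c={r.normalized:.3f} {fold}")
print("nad6 is ~180-fold over background; the mitochondrial rbcL C-terminus"
      " ~15-fold -- expressed, but far below the control gene")
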