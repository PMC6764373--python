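"""Baiting, greedy overlap assembly, circularity, homology filtering,
gap closing and polishing, each against construction or brute-force
oracles."""

import numpy as np
import pytest

import mitokit as mk
from mitokit._seq import canonical_kmer, least_rotation, revcomp
from mitokit.bait_assemble import Contig, HomologyFilterParams, OverlapParams

from conftest import random_dna


# ---------------------------------------------------------------------------
# baiting


def brute_force_baited(read: str, baits: mk.BaitSet) -> bool:
    read_kmers = {canonical_kmer(read[i : i + baits.k])
                  for i in range(len(read) - baits.k + 1)}
    return len(read_kmers & baits.kmers) >= baits.min_hits


def test_read_identical_to_bait_is_baited(rng):
    bait = random_dna(rng, 200)
    baits = mk.build_bait_set([bait], k=32, min_hits=1)
    assert mk.bait_reads([("r", bait)], baits) == [("r", bait)]


def test_disjoint_kmer_sets_not_baited():
    baits = mk.build_bait_set(["C" * 100], k=32, min_hits=1)
    assert mk.bait_reads([("r", "A" * 100)], baits) == []


def test_exact_block_yields_predicted_shared_kmer_count(rng):
    """An embedded 81-nt bait block contributes exactly 50 distinct 32-mers:
    baited at n=50, not at n=51."""
    block = random_dna(rng, 81)
    read = random_dna(rng, 60).replace("N", "A") + block + random_dna(rng, 60)
    # guard: the block's 32-mers must be distinct for the arithmetic to hold
    assert len({block[i : i + 32] for i in range(50)}) == 50
    at50 = mk.build_bait_set([block], k=32, min_hits=50)
    at51 = mk.build_bait_set([block], k=32, min_hits=51)
    assert mk.bait_reads([("r", read)], at50)
    assert not mk.bait_reads([("r", read)], at51)


def test_baiting_agrees_with_brute_force_oracle(rng):
    baits = mk.build_bait_set([random_dna(rng, 300), random_dna(rng, 150)],
                              k=21, min_hits=3)
    pool = []
    for i in range(40):
        seq = random_dna(rng, 120)
        if i % 3 == 0:  # splice in a bait fragment sometimes
            frag = random_dna(rng, 40)
            seq = seq[:40] + frag + seq[80:]
        pool.append((f"r{i}", seq))
    got = {rid for rid, _ in mk.bait_reads(pool, baits)}
    want = {rid for rid, seq in pool if brute_force_baited(seq, baits)}
    assert got == want


def test_reads_shorter_than_k_never_baited():
    baits = mk.build_bait_set(["A" * 50], k=32)
    assert mk.bait_reads([("r", "A" * 20)], baits) == []


# ---------------------------------------------------------------------------
# greedy assembly


def test_single_read_passes_through(rng):
    seq = random_dna(rng, 1200)
    contigs = mk.greedy_assemble([("r", seq)])
    assert len(contigs) == 1 and contigs[0].sequence == seq
    assert contigs[0].member_read_ids == ["r"]


def test_two_reads_merge_at_sufficient_overlap(rng):
    union = random_dna(rng, 1800)
    r1, r2 = union[:1500], union[300:]
    contigs = mk.greedy_assemble([("a", r1), ("b", r2)],
                                 OverlapParams(min_overlap=1000))
    assert len(contigs) == 1 and contigs[0].sequence == union
    strict = mk.greedy_assemble([("a", r1), ("b", r2)],
                                OverlapParams(min_overlap=1300))
    assert len(strict) == 2


def test_reverse_orientation_overlaps_are_merged(rng):
    union = random_dna(rng, 1800)
    contigs = mk.greedy_assemble([("a", union[:1500]), ("b", revcomp(union[300:]))],
                                 OverlapParams(min_overlap=1000))
    assert len(contigs) == 1
    assert contigs[0].sequence in (union, revcomp(union))


def test_read_membership_is_conserved(long_reads):
    reads = long_reads.long_reads[:60]
    contigs = mk.greedy_assemble(reads)
    members = [rid for c in contigs for rid in c.member_read_ids]
    assert sorted(members) == sorted(rid for rid, _ in reads)


# ---------------------------------------------------------------------------
# circularity


def test_random_linear_contig_is_not_circular(rng):
    seq = random_dna(rng, 5000)
    # construction guard: no >=100 suffix-prefix repeat, by exhaustive scan
    assert all(seq[-o:] != seq[:o] for o in range(100, 2500))
    circular, out = mk.test_circularity(Contig("c", seq))
    assert not circular and out == seq


def test_end_redundant_contig_is_trimmed_and_rotated(rng):
    s = random_dna(rng, 5000)
    circular, out = mk.test_circularity(Contig("c", s + s[:500]))
    assert circular
    assert len(out) == 5000
    assert out == least_rotation(s)


def test_short_contig_not_circular():
    circular, out = mk.test_circularity(Contig("c", "ACGT" * 40),
                                        min_end_overlap=100)
    assert not circular


def test_circularity_is_idempotent_after_trimming(rng):
    s = random_dna(rng, 5000)
    _, trimmed = mk.test_circularity(Contig("c", s + s[:500]))
    again, out = mk.test_circularity(Contig("c", trimmed, circular=True))
    assert again and out == trimmed


# ---------------------------------------------------------------------------
# homology filter


def test_exact_substring_hits_cover_the_contig(rng):
    ref = random_dna(rng, 6000)
    contig = Contig("c", ref[1000:3000])
    kept, removed = mk.homology_filter([contig], [ref], mode="exclude_covered")
    assert removed == [contig]  # 100% covered >= 0.9
    kept, removed = mk.homology_filter([contig], [ref], mode="retain_hits")
    assert kept == [contig]


def test_unrelated_contig_has_no_hit(rng):
    ref = random_dna(rng, 1000)
    contig = Contig("c", random_dna(rng, 1000))
    kept, removed = mk.homology_filter([contig], [ref], mode="retain_hits")
    assert removed == [contig]


def test_coverage_threshold_controls_exclusion(rng):
    ref = random_dna(rng, 6000)
    # contig 95% covered by reference material
    contig = Contig("c", ref[:1900] + random_dna(rng, 100))
    params = HomologyFilterParams(plastid_exclusion_coverage=0.9)
    _, removed = mk.homology_filter([contig], [ref], params, "exclude_covered")
    assert removed == [contig]
    params = HomologyFilterParams(plastid_exclusion_coverage=0.99)
    kept, _ = mk.homology_filter([contig], [ref], params, "exclude_covered")
    assert kept == [contig]


# ---------------------------------------------------------------------------
# iterative loop edge cases


def test_empty_read_pool_returns_empty():
    assert mk.iterative_bait_assemble([], ["A" * 100]) == []


# ---------------------------------------------------------------------------
# gap closing


def test_gap_closed_exactly_with_spanning_reads(genome, long_reads):
    chroms, _, _ = genome
    seq = chroms[0].sequence
    gapped = mk.CircularChromosome("chr1", seq[:5000] + "N" * 100 + seq[5100:])
    patched, report = mk.close_gaps([gapped], long_reads.long_reads)
    assert patched[0].sequence == seq
    assert report == [{"chrom": "chr1", "start": 5000, "length": 100,
                       "closed": True}]


def test_assembly_without_gaps_unchanged(genome, long_reads):
    chroms, _, _ = genome
    patched, report = mk.close_gaps([chroms[1]], long_reads.long_reads)
    assert patched[0].sequence == chroms[1].sequence and report == []


def test_unspanned_gap_reported_unresolved(rng, long_reads):
    foreign = random_dna(rng, 8000)
    gapped = mk.CircularChromosome("x", foreign[:4000] + "N" * 50 + foreign[4050:])
    patched, report = mk.close_gaps([gapped], long_reads.long_reads)
    assert patched[0].sequence == gapped.sequence
    assert report[0]["closed"] is False


# ---------------------------------------------------------------------------
# polishing


def _tile_alignments(seq, read_len=200, step=20):
    return [mk.AlignmentRecord(f"t{i}", "chr", i, "+", [("M", min(read_len, len(seq) - i))],
                               seq=seq[i : i + read_len])
            for i in range(0, len(seq) - 50, step)]


def test_planted_substitutions_all_corrected(rng):
    truth = random_dna(rng, 3000)
    corrupt = list(truth)
    # keep planted errors inside the fully tiled interior (uniform depth)
    planted = sorted(rng.choice(np.arange(200, 2800), size=10, replace=False))
    for p in planted:
        corrupt[p] = "A" if corrupt[p] != "A" else "C"
    assembly = [mk.CircularChromosome("chr", "".join(corrupt), circular=False)]
    alignments = _tile_alignments(truth)
    polished, changes = mk.polish_consensus(assembly, alignments)
    assert polished[0].sequence == truth
    assert sorted(c["pos"] for c in changes) == [int(p) for p in planted]


def test_no_alignments_leaves_assembly_unchanged(rng):
    assembly = [mk.CircularChromosome("chr", random_dna(rng, 500))]
    polished, changes = mk.polish_consensus(assembly, [])
    assert polished[0].sequence == assembly[0].sequence and changes == []


def test_below_min_depth_never_changed(rng):
    truth = random_dna(rng, 300)
    corrupt = truth[:150] + ("A" if truth[150] != "A" else "C") + truth[151:]
    assembly = [mk.CircularChromosome("chr", corrupt, circular=False)]
    alignments = [mk.AlignmentRecord(f"r{i}", "chr", 100, "+", [("M", 100)],
                                     seq=truth[100:200]) for i in range(4)]
    polished, changes = mk.polish_consensus(assembly, alignments, min_depth=5)
    assert polished[0].sequence == corrupt and changes == []
    polished, changes = mk.polish_consensus(assembly, alignments, min_depth=4)
    assert polished[0].sequence == truth and len(changes) == 1
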