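"""Shared-region discovery, join-path enumeration, spanning-read support
and repeat-mediated conformation counting."""

import pytest

import mitokit as mk
from mitokit._seq import revcomp
from mitokit.chromosome_structure import SharedRegion

from conftest import random_dna


def plant_pair(rng, block_len=188, mismatches=0, inverted=False,
               la=10000, lb=8000, pos_a=4000, pos_b=2500):
    """Two chromosomes sharing one planted block; flanking bases are forced
    to differ so the planted extent is the maximal match."""
    a = list(random_dna(rng, la))
    b = list(random_dna(rng, lb))
    block = random_dna(rng, block_len)
    a[pos_a : pos_a + block_len] = block
    copy = list(revcomp(block) if inverted else block)
    step = max(30, block_len // (mismatches + 1))
    for m in range(mismatches):
        p = 30 + m * step
        copy[p] = "A" if copy[p] != "A" else "C"
    b[pos_b : pos_b + block_len] = copy
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if not inverted:
        b[pos_b - 1] = next(x for x in "ACGT" if x != a[pos_a - 1])
        b[pos_b + block_len] = next(x for x in "ACGT" if x != a[pos_a + block_len])
    else:
        b[pos_b + block_len] = next(x for x in "ACGT"
                                    if x != comp[a[pos_a - 1]])
        b[pos_b - 1] = next(x for x in "ACGT"
                            if x != comp[a[pos_a + block_len]])
    return (mk.CircularChromosome("A", "".join(a)),
            mk.CircularChromosome("B", "".join(b)))


# ---------------------------------------------------------------------------
# find_shared_regions


def test_identical_planted_block_found_exactly(rng):
    ca, cb = plant_pair(rng)
    regions = mk.find_shared_regions(ca, cb)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start_a, r.start_b, r.length) == (4000, 2500, 188)
    assert r.identity == 100.0 and r.orientation == "same"


def test_imperfect_block_identity_computed(rng):
    ca, cb = plant_pair(rng, mismatches=2)
    regions = mk.find_shared_regions(ca, cb)
    assert len(regions) == 1
    r = regions[0]
    assert r.length == 188
    assert r.identity == pytest.approx(100 * 186 / 188, abs=1e-6)


def test_inverted_block_reported_with_orientation(rng):
    ca, cb = plant_pair(rng, inverted=True)
    regions = mk.find_shared_regions(ca, cb)
    assert len(regions) == 1
    r = regions[0]
    assert r.orientation == "inverted"
    assert (r.start_a, r.start_b, r.length) == (4000, 2500, 188)


def test_unrelated_sequences_share_nothing(rng):
    ca = mk.CircularChromosome("A", random_dna(rng, 10000))
    cb = mk.CircularChromosome("B", random_dna(rng, 10000))
    assert mk.find_shared_regions(ca, cb, min_len=30) == []


def test_truth_regions_recovered_exactly(genome):
    chroms, _, truth = genome
    regions = mk.find_shared_regions(chroms[0], chroms[1])
    found = {(r.start_a, r.start_b, r.length, r.orientation) for r in regions}
    want = {(r["start_a"], r["start_b"], r["length"], r["orientation"])
            for r in truth.shared_regions}
    assert found == want
    assert [r.start_a for r in regions] == sorted(r.start_a for r in regions)


# ---------------------------------------------------------------------------
# join paths


def test_four_paths_with_expected_lengths(rng):
    ca, cb = plant_pair(rng)
    region = mk.find_shared_regions(ca, cb)[0]
    paths = mk.enumerate_join_paths(region, [ca, cb], flank=500)
    assert set(paths) == {"ref_a", "ref_b", "chimera_ab", "chimera_ba"}
    assert all(len(p) == 2 * 500 + region.length for p in paths.values())
    assert paths["ref_a"] in ca.sequence * 2
    assert paths["ref_b"] in cb.sequence * 2
    assert paths["chimera_ab"] not in ca.sequence * 2
    assert paths["chimera_ab"] not in cb.sequence * 2


def test_flank_wraps_the_circular_origin(rng):
    ca, cb = plant_pair(rng, pos_a=10)
    region = SharedRegion("A", 10, "B", 2500, 188, 100.0)
    paths = mk.enumerate_join_paths(region, [ca, cb], flank=500)
    assert len(paths["ref_a"]) == 1188
    assert paths["ref_a"] in ca.sequence * 2


def test_invalid_region_coordinates_rejected(rng):
    ca, cb = plant_pair(rng)
    bad = SharedRegion("A", 9990, "B", 2500, 188, 100.0)
    with pytest.raises(ValueError):
        mk.enumerate_join_paths(bad, [ca, cb])


# ---------------------------------------------------------------------------
# spanning support


def test_reference_reads_support_only_reference_paths(rng):
    ca, cb = plant_pair(rng)
    region = mk.find_shared_regions(ca, cb)[0]
    paths = mk.enumerate_join_paths(region, [ca, cb], flank=500)
    reads = []
    for start in range(3500, 4100, 60):  # spanning the block on A
        reads.append((f"a{start}", ca.sequence[start : start + 700]))
    support = mk.count_spanning_reads(reads, paths, region.length, flank=500)
    assert support["chimera_ab"] == 0 and support["chimera_ba"] == 0
    assert support["ref_a"] > 0
    # brute-force expectation: reads covering block +/- 20 on both sides
    expected = sum(1 for s in range(3500, 4100, 60)
                   if s <= 4000 - 20 and s + 700 >= 4188 + 20)
    assert support["ref_a"] == expected


def test_chimeric_reads_support_the_chimeric_path(rng):
    ca, cb = plant_pair(rng)
    region = mk.find_shared_regions(ca, cb)[0]
    paths = mk.enumerate_join_paths(region, [ca, cb], flank=500)
    chimera = paths["chimera_ab"]
    reads = [(f"c{i}", chimera[i : i + 600]) for i in range(0, 500, 45)]
    support = mk.count_spanning_reads(reads, paths, region.length, flank=500)
    expected = sum(1 for i in range(0, 500, 45)
                   if i <= 500 - 20 and i + 600 >= 500 + 188 + 20)
    assert support["chimera_ab"] == expected > 0
    assert support["ref_a"] == 0 and support["ref_b"] == 0


def test_read_equal_to_block_supports_nothing(rng):
    ca, cb = plant_pair(rng)
    region = mk.find_shared_regions(ca, cb)[0]
    paths = mk.enumerate_join_paths(region, [ca, cb], flank=500)
    block = ca.sequence[4000:4188]
    support = mk.count_spanning_reads([("blk", block)], paths, region.length,
                                      flank=500)
    assert all(v == 0 for v in support.values())


# ---------------------------------------------------------------------------
# candidate classification


def test_classification_bookkeeping_partitions_regions():
    regions = [SharedRegion("A", i * 100, "B", i * 90, 50, 100.0)
               for i in range(106)]
    regions += [SharedRegion("A", 20000 + i * 500, "B", 11000 + i * 400,
                             200, 100.0) for i in range(5)]
    cands, counts = mk.classify_join_candidates(regions, read_length=101,
                                                chimeric_support=[0] * 111)
    assert counts == {"total": 111, "excluded": 106, "candidate": 5,
                      "supported": 0, "verdict": "no master circle"}
    assert counts["excluded"] + counts["candidate"] + counts["supported"] == \
        counts["total"]


def test_single_short_unsupported_region_excluded():
    region = SharedRegion("A", 10, "B", 20, 50, 100.0)
    cands, counts = mk.classify_join_candidates([region], 101, [0])
    assert cands[0].status == "excluded"


def test_any_chimeric_support_means_master_circle():
    region = SharedRegion("A", 10, "B", 20, 50, 100.0)
    _, counts = mk.classify_join_candidates([region], 101, [3])
    assert counts["verdict"] == "master circle present"


# ---------------------------------------------------------------------------
# alternative conformations


def test_inversion_mixture_counted_exactly(genome, default_config):
    chroms, _, truth = genome
    rep = dict(truth.repeat_loci["inverted"], kind="inverted")
    reads, labels = mk.simulate_conformation_reads(
        chroms[0], rep, n_reference=5, n_alternative=3, config=default_config)
    report = mk.detect_alternative_conformations(reads, rep, chroms[0])
    assert report.support == {"reference": 5, "inverted": 3}
    assert report.ambiguous == 0


def test_subcircle_junction_reads_counted(genome, default_config):
    chroms, _, truth = genome
    rep = dict(truth.repeat_loci["direct"], kind="direct")
    reads, _ = mk.simulate_conformation_reads(
        chroms[0], rep, n_reference=4, n_alternative=6, config=default_config,
        arrangement="subcircles")
    report = mk.detect_alternative_conformations(reads, rep, chroms[0])
    assert report.support == {"single_circle": 4, "subcircles": 6}


def test_no_spanning_reads_is_indeterminate(genome):
    chroms, _, truth = genome
    rep = dict(truth.repeat_loci["inverted"], kind="inverted")
    report = mk.detect_alternative_conformations([("r", "ACGT" * 100)], rep,
                                                 chroms[0])
    assert report.support == {"reference": 0, "inverted": 0}
    assert report.verdict == "indeterminate"


def test_overlapping_repeat_copies_rejected(genome):
    chroms, _, _ = genome
    rep = {"starts": [100, 200], "length": 400, "kind": "inverted"}
    with pytest.raises(ValueError):
        mk.detect_alternative_conformations([], rep, chroms[0])
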