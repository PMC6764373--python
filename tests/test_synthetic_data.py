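"""The simulator's self-consistency: every planted structure must be
independently verifiable against the generated sequences, and outputs must
be byte-deterministic under a fixed seed."""

import json

import numpy as np
import pytest

import mitokit as mk
from mitokit._seq import gc_fraction, revcomp


def test_generation_is_deterministic(default_config, genome, tmp_path):
    chroms, annotations, truth = genome
    chroms2, annotations2, truth2 = mk.generate_mitogenome(mk.SimulationConfig())
    assert [c.sequence for c in chroms2] == [c.sequence for c in chroms]
    assert annotations2 == annotations
    a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
    mk.write_fasta(a, chroms)
    mk.write_fasta(b, chroms2)
    assert a.read_bytes() == b.read_bytes()
    t1 = json.loads(truth.to_json())
    t1["planted_junctions"] = truth2.planted_junctions  # supports filled later
    assert json.dumps(t1, sort_keys=True) == \
        json.dumps(json.loads(truth2.to_json()), sort_keys=True)


def test_chromosome_lengths_match_request(genome, default_config):
    chroms, _, _ = genome
    assert [c.length for c in chroms] == list(default_config.chr_lengths)


def test_truth_shared_regions_verifiable_by_substring_scan(genome):
    chroms, _, truth = genome
    seqs = {c.id: c.sequence for c in chroms}
    for r in truth.shared_regions:
        a = seqs[r["chrom_a"]][r["start_a"] : r["start_a"] + r["length"]]
        b = seqs[r["chrom_b"]][r["start_b"] : r["start_b"] + r["length"]]
        if r["orientation"] == "inverted":
            b = revcomp(b)
        matches = sum(x == y for x, y in zip(a, b))
        assert matches / r["length"] * 100 == pytest.approx(r["identity"])
        assert matches / r["length"] >= 0.95


def test_repeats_and_plastid_segment_planted_as_recorded(genome):
    chroms, _, truth = genome
    seq = chroms[0].sequence
    d = truth.repeat_loci["direct"]
    s1, s2 = d["starts"]
    assert seq[s1 : s1 + d["length"]] == seq[s2 : s2 + d["length"]]
    i = truth.repeat_loci["inverted"]
    s1, s2 = i["starts"]
    assert seq[s2 : s2 + i["length"]] == revcomp(seq[s1 : s1 + i["length"]])
    p = truth.plastid_segments[0]
    gc = gc_fraction(seq[p["start"] : p["end"]])
    assert 0.374 <= gc <= 0.394


def test_editing_sites_written_into_exons(genome):
    chroms, _, truth = genome
    seqs = {c.id: c.sequence for c in chroms}
    exon_spans = [(e["chrom"], e["start"], e["end"])
                  for g in truth.gene_models for e in g["exons"]]
    for site in truth.editing_sites:
        assert seqs[site["chrom"]][site["pos"]] == site["genomic"]
        assert any(c == site["chrom"] and s <= site["pos"] < e
                   for c, s, e in exon_spans)


def test_no_shared_regions_when_none_requested():
    cfg = mk.SimulationConfig(seed=11, n_shared_regions=0)
    chroms, _, truth = mk.generate_mitogenome(cfg)
    assert truth.shared_regions == []
    assert mk.find_shared_regions(chroms[0], chroms[1]) == []


def test_infeasible_packing_names_the_chromosome():
    cfg = mk.SimulationConfig(chr_lengths=(6200, 3100))
    with pytest.raises(ValueError, match="chr"):
        mk.generate_mitogenome(cfg)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        mk.SimulationConfig(chr_lengths=(2000, 15000)).validate()
    with pytest.raises(ValueError):
        mk.SimulationConfig(shared_len_range=(30, 400)).validate()
    with pytest.raises(ValueError):
        mk.SimulationConfig(coverage=-1).validate()


# ---------------------------------------------------------------------------
# genomic reads


def test_error_free_reads_are_exact_circular_substrings(genome, long_reads):
    chroms, _, _ = genome
    doubled = {c.id: c.sequence * 2 for c in chroms}
    assert long_reads.long_reads
    for rid, seq in long_reads.long_reads:
        hit = any(seq in d or revcomp(seq) in d for d in doubled.values())
        assert hit, f"read {rid} is not a circular substring"


def test_paired_reads_are_exact_and_inserts_match_the_distribution(genome,
                                                                   default_config):
    chroms, _, _ = genome
    rs = mk.simulate_genomic_reads(chroms, default_config)
    assert len(rs.pairs) >= 500
    doubled = {c.id: c.sequence * 2 for c in chroms}
    inserts = []
    for rid, r1, r2 in rs.pairs[:300]:
        chrom, start, _strand, ins = rs.placements[rid]
        inserts.append(ins)
        assert r1 in doubled[chrom]
        assert revcomp(r2) in doubled[chrom]
    inserts = [rs.placements[rid][3] for rid, _, _ in rs.pairs]
    se = default_config.insert_sd / np.sqrt(len(inserts))
    assert abs(np.mean(inserts) - default_config.insert_mean) < 3 * se


def test_zero_coverage_gives_empty_read_set(genome):
    chroms, _, _ = genome
    cfg = mk.SimulationConfig(coverage=0)
    rs = mk.simulate_genomic_reads(chroms, cfg)
    assert not rs.pairs and not rs.long_reads


def test_mean_depth_tracks_configured_coverage(genome):
    chroms, _, _ = genome
    cfg = mk.SimulationConfig(coverage=20)
    rs = mk.simulate_genomic_reads(chroms, cfg)
    total = sum(c.length for c in chroms)
    depth = len(rs.pairs) * 2 * cfg.read_len_short / total
    assert abs(depth - cfg.coverage) / cfg.coverage < 0.1


def test_read_simulation_is_deterministic(genome, default_config):
    chroms, _, _ = genome
    a = mk.simulate_genomic_reads(chroms, default_config, long_reads=True)
    b = mk.simulate_genomic_reads(chroms, default_config, long_reads=True)
    assert a.long_reads == b.long_reads and a.placements == b.placements


# ---------------------------------------------------------------------------
# transcript alignments


def test_transcript_truth_round_trip(genome, transcripts, default_config):
    """Junctions extracted from the emitted alignments reproduce the truth
    junction table exactly at min_support=1."""
    chroms, _, _ = genome
    spliced, _, _, truth = transcripts
    cmap = mk.ConcatMap(chroms)
    junctions, qc = mk.extract_junctions(spliced, cmap, min_support=1)
    assert qc["rejected_out_of_range"] == 0
    found = {(j.donor.chrom, j.donor.pos, j.acceptor.chrom, j.acceptor.pos): j.support
             for j in junctions}
    want = {(j["donor"]["chrom"], j["donor"]["pos"],
             j["acceptor"]["chrom"], j["acceptor"]["pos"]): j["support"]
            for j in truth.planted_junctions}
    assert found == want
    assert any(j.cross_chromosomal for j in junctions)


def test_editing_mismatches_only_at_truth_sites(genome, transcripts):
    chroms, _, _ = genome
    spliced, _, _, truth = transcripts
    cmap = mk.ConcatMap(chroms)
    concat = cmap.concatenated_sequence(chroms)
    mismatch_positions = set()
    for rec in spliced:
        rp, qp = rec.pos, 0
        for op, n in rec.cigar:
            if op == "M":
                for t in range(n):
                    if rec.seq[qp + t] != concat[rp + t]:
                        mismatch_positions.add(rp + t)
                rp += n
                qp += n
            elif op == "N":
                rp += n
    truth_sites = {cmap.to_concat(e["chrom"], e["pos"]) for e in truth.editing_sites}
    assert mismatch_positions == truth_sites


def test_degradation_regions_reach_configured_depth(transcripts, genome,
                                                    default_config):
    chroms, _, _ = genome
    _, polya, refs, truth = transcripts
    cmap = mk.ConcatMap(chroms)
    tracks, _ = mk.compute_coverage(polya, refs)
    depth = tracks["mt_concat"].depth
    for region in truth.degradation_regions:
        c0 = cmap.to_concat(region["chrom"], region["start"])
        c1 = c0 + (region["end"] - region["start"])
        assert depth[c0:c1].min() >= default_config.degradation_depth
        assert depth[c0 - 1] == 0 and depth[c1] == 0


def test_no_genes_means_no_spliced_alignments():
    cfg = mk.SimulationConfig(seed=3, n_genes=0, n_trans_spliced_genes=0,
                              editing_sites=0)
    chroms, anns, truth = mk.generate_mitogenome(cfg)
    spliced, _, _ = mk.simulate_transcript_alignments(chroms, anns, truth, cfg)
    assert not any(op == "N" for rec in spliced for op, _ in rec.cigar)
    assert spliced == []
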