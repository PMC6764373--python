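"""Splice junctions, hotspots and guide-RNA candidates.

Junctions are read off the skip (N) operations of spliced alignments over
the concatenated pseudo-chromosome and lifted back to per-chromosome
coordinates; a junction whose donor and acceptor lift to different
chromosomes is a cross-chromosomal (trans-splicing) event. Organelle
group-II splicing does not follow GT-AG reliably, so donor/acceptor are
defined at alignment level: the exonic bases flanking the skip, 0-based.

Hotspots capture the observation that organellar splice events cluster at
loci spread over hundreds to thousands of bases rather than exact sites.
The guide search asks whether the two halves of the mature sequence
across a junction also occur elsewhere in the genome, i.e. whether an
intra-chromosomal splice could generate a guide RNA for the junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from intervaltree import IntervalTree

from ._seq import revcomp
from .sequence_io import AlignmentRecord, Annotation, CircularChromosome, ConcatMap


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos: int
    strand: str = "+"


@dataclass
class SpliceJunction:
    donor: Locus
    acceptor: Locus
    support: int
    cross_chromosomal: bool = False
    in_cds: bool = False


@dataclass
class SpliceHotspot:
    members: list[SpliceJunction]
    donor_window: tuple[str, int, int]
    acceptor_window: tuple[str, int, int]

    @property
    def total_support(self) -> int:
        return sum(j.support for j in self.members)


@dataclass
class GuideCandidate:
    junction: SpliceJunction
    half5: tuple[str, int, int, str]  # chrom, start, end (0-based), strand
    half3: tuple[str, int, int, str]
    mismatches5: int
    mismatches3: int

    @staticmethod
    def describe_locus(locus: tuple[str, int, int, str]) -> str:
        """1-based report; minus-strand loci in decreasing coordinates."""
        chrom, start, end, strand = locus
        if strand == "+":
            return f"{chrom}:{start + 1}-{end}"
        return f"{chrom}:{end}-{start + 1}"


# ---------------------------------------------------------------------------
# junction extraction


def extract_junctions(alignments: list[AlignmentRecord], concat_map: ConcatMap,
                      min_support: int = 10, forward_only: bool = False
                      ) -> tuple[list[SpliceJunction], dict]:
    """Aggregate skip operations into junctions; lift to chromosome space.

    Returns (junctions, qc) where qc tallies alignments whose skip ran past
    the reference end. ``forward_only`` drops reverse-strand alignments,
    reproducing a forward-strand SAM pre-filter.
    """
    counts: dict[tuple, int] = {}
    qc = {"rejected_out_of_range": 0, "alignments_seen": 0}
    for rec in alignments:
        qc["alignments_seen"] += 1
        if forward_only and rec.strand != "+":
            continue
        rp = rec.pos
        bad = False
        events = []
        for op, n in rec.cigar:
            if op == "N":
                donor, acceptor = rp - 1, rp + n
                if acceptor >= concat_map.total:
                    bad = True
                    break
                events.append((donor, acceptor))
                rp += n
            elif op in "MD":
                rp += n
        if bad or rp > concat_map.total:
            qc["rejected_out_of_range"] += 1
            continue
        for donor, acceptor in events:
            key = (donor, acceptor, rec.strand)
            counts[key] = counts.get(key, 0) + 1
    junctions = []
    for (donor, acceptor, strand), support in sorted(counts.items()):
        if support < min_support:
            continue
        dc, dp = concat_map.from_concat(donor)
        ac, ap = concat_map.from_concat(acceptor)
        junctions.append(SpliceJunction(Locus(dc, dp, strand), Locus(ac, ap, strand),
                                        support, cross_chromosomal=dc != ac))
    return junctions, qc


# ---------------------------------------------------------------------------
# hotspot clustering


def cluster_hotspots(junctions: list[SpliceJunction], window: int = 1000
                     ) -> list[SpliceHotspot]:
    """Single-linkage clustering: two junctions join a hotspot when both
    their donor and their acceptor positions fall within ``window`` on the
    same chromosome pair and strand. Sorted by total support, descending."""
    g = nx.Graph()
    g.add_nodes_from(range(len(junctions)))
    for i in range(len(junctions)):
        ji = junctions[i]
        for j in range(i + 1, len(junctions)):
            jj = junctions[j]
            if (ji.donor.chrom, ji.acceptor.chrom, ji.donor.strand) != \
                    (jj.donor.chrom, jj.acceptor.chrom, jj.donor.strand):
                continue
            if abs(ji.donor.pos - jj.donor.pos) <= window \
                    and abs(ji.acceptor.pos - jj.acceptor.pos) <= window:
                g.add_edge(i, j)
    hotspots = []
    for comp in nx.connected_components(g):
        members = [junctions[i] for i in sorted(comp)]
        dc = members[0].donor.chrom
        ac = members[0].acceptor.chrom
        dpos = [m.donor.pos for m in members]
        apos = [m.acceptor.pos for m in members]
        hotspots.append(SpliceHotspot(members,
                                      (dc, min(dpos), max(dpos) + 1),
                                      (ac, min(apos), max(apos) + 1)))
    hotspots.sort(key=lambda h: (-h.total_support, h.donor_window))
    return hotspots


# ---------------------------------------------------------------------------
# summary


def summarize_counts(total: int, n_in_cds: int, n_cross: int) -> dict:
    """Percentage arithmetic over junction counts (two- and one-decimal)."""
    if total == 0:
        return {"total": 0, "n_in_cds": 0, "n_cross": 0,
                "pct_in_cds": None, "pct_cross": None,
                "pct_in_cds_1dp": None, "pct_cross_1dp": None,
                "undefined": True}
    return {
        "total": total, "n_in_cds": n_in_cds, "n_cross": n_cross,
        "pct_in_cds": round(100.0 * n_in_cds / total, 2),
        "pct_cross": round(100.0 * n_cross / total, 2),
        "pct_in_cds_1dp": round(100.0 * n_in_cds / total, 1),
        "pct_cross_1dp": round(100.0 * n_cross / total, 1),
        "undefined": False,
    }


def classify_and_summarize(junctions: list[SpliceJunction],
                           annotations: list[Annotation]) -> dict:
    """Flag junctions inside coding sequence (donor or acceptor endpoint in
    any CDS interval) and report in-CDS / cross-chromosomal fractions."""
    trees: dict[str, IntervalTree] = {}
    for a in annotations:
        if a.feature_type == "CDS":
            trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end)
    for j in junctions:
        j.in_cds = bool(
            (j.donor.chrom in trees and trees[j.donor.chrom][j.donor.pos])
            or (j.acceptor.chrom in trees and trees[j.acceptor.chrom][j.acceptor.pos])
        )
    return summarize_counts(len(junctions),
                            sum(j.in_cds for j in junctions),
                            sum(j.cross_chromosomal for j in junctions))


# ---------------------------------------------------------------------------
# guide-RNA search


def _hamming_scan(haystack: str, needle: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where needle matches with <= max_mismatch."""
    n, m = len(haystack), len(needle)
    if n < m:
        return []
    hs = np.frombuffer(haystack.encode(), dtype=np.uint8)
    nd = np.frombuffer(needle.encode(), dtype=np.uint8)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mism += hs[j : n - m + 1 + j] != nd[j]
    return [(int(i), int(mism[i])) for i in np.nonzero(mism <= max_mismatch)[0]]


def guide_rna_search(junction: SpliceJunction,
                     chromosomes: list[CircularChromosome],
                     window: int = 54, split: int = 28, max_mismatch: int = 1,
                     exclusion_slop: int = 5) -> list[GuideCandidate]:
    """Search for loci that could generate a guide RNA for a junction.

    The mature sequence across the junction (``split`` exonic bases ending
    at the donor plus ``window - split`` bases from the acceptor) is cut in
    two and each half is searched genome-wide on both strands with up to
    ``max_mismatch`` mismatches, excluding the junction's own donor and
    acceptor loci. Every (5'-half locus, 3'-half locus) pair is reported.
    """
    seqs = {c.id: c.sequence for c in chromosomes}
    half3_len = window - split
    d, a = junction.donor, junction.acceptor
    if d.pos - split + 1 < 0 or a.pos + half3_len > len(seqs[a.chrom]):
        raise ValueError("window exceeds the available exon context")
    half5 = seqs[d.chrom][d.pos - split + 1 : d.pos + 1]
    half3 = seqs[a.chrom][a.pos : a.pos + half3_len]
    own = {(d.chrom, d.pos - split + 1), (a.chrom, a.pos)}

    def search(pattern: str) -> list[tuple[str, int, int, str, int]]:
        hits = []
        for cid, seq in seqs.items():
            for pos, mm in _hamming_scan(seq, pattern, max_mismatch):
                hits.append((cid, pos, pos + len(pattern), "+", mm))
            for pos, mm in _hamming_scan(seq, revcomp(pattern), max_mismatch):
                hits.append((cid, pos, pos + len(pattern), "-", mm))
        return hits

    def is_own(hit, origin_set) -> bool:
        cid, start = hit[0], hit[1]
        return any(cid == oc and abs(start - op) <= exclusion_slop
                   for oc, op in origin_set)

    h5 = [h for h in search(half5) if not is_own(h, own)]
    h3 = [h for h in search(half3) if not is_own(h, own)]
    out = []
    for c5 in h5:
        for c3 in h3:
            out.append(GuideCandidate(junction, c5[:4], c3[:4], c5[4], c3[4]))
    return out
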