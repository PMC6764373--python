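"""Inter-chromosomal structure: shared regions, master-circle tests,
alternative conformations at long repeats.

A multichromosomal mitogenome is only credible if no sequencing read ever
joins its chromosomes. The test implemented here enumerates every short
region the chromosomes share, extracts the four flank-block-flank "join
paths" through each (two reference, two chimeric), and counts reads that
span a path with uniquely anchored sequence on both sides of the block.
Chimeric spanning support would be evidence for a fused master circle.

Long repeats within one chromosome can likewise mediate inversions
(inverted repeat) or a split into subgenomic circles (direct repeat);
:func:`detect_alternative_conformations` counts long-read support for each
arrangement at such a repeat pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from ._seq import circular_slice, hamming_identity, revcomp
from .sequence_io import CircularChromosome


@dataclass
class SharedRegion:
    chrom_a: str
    start_a: int
    chrom_b: str
    start_b: int
    length: int
    identity: float
    orientation: str = "same"  # or "inverted"

    @property
    def end_a(self) -> int:
        return self.start_a + self.length

    @property
    def end_b(self) -> int:
        return self.start_b + self.length


@dataclass
class JoinCandidate:
    region: SharedRegion
    status: str  # excluded | candidate | supported
    paths: dict[str, str] = field(default_factory=dict)
    spanning_support: dict[str, int] = field(default_factory=dict)
    flank: int = 500


@dataclass
class ConformationReport:
    repeat: dict
    labels: tuple[str, str]
    support: dict[str, int]
    ambiguous: int = 0

    @property
    def verdict(self) -> str:
        a, b = self.labels
        if self.support[a] == 0 and self.support[b] == 0:
            return "indeterminate"
        return f"{self.support[a]}:{self.support[b]} ({a}:{b})"


# ---------------------------------------------------------------------------
# shared-region discovery


def _max_scoring_subsegment(matches: list[bool], penalty: float
                            ) -> tuple[int, int, int]:
    """Kadane over +1/-penalty scores; returns (start, end, n_matches)."""
    best = (0.0, 0, 0)
    cur = 0.0
    cur_start = 0
    best_s = best_e = 0
    for i, m in enumerate(matches):
        score = 1.0 if m else -penalty
        if cur <= 0:
            cur = score
            cur_start = i
        else:
            cur += score
        if cur > best[0]:
            best = (cur, cur_start, i + 1)
            best_s, best_e = cur_start, i + 1
    n_match = sum(matches[best_s:best_e])
    return best_s, best_e, n_match


def find_shared_regions(chrom_a: CircularChromosome, chrom_b: CircularChromosome,
                        min_len: int = 30, min_identity: float = 95.0
                        ) -> list[SharedRegion]:
    """Maximal near-exact matches between two chromosomes, both orientations.

    Exact k-mer anchors (k = max(15, min_len//2)) are grouped per diagonal,
    extended with mismatch tolerance while overall identity stays above the
    threshold, then trimmed to the maximal-scoring segment so that reported
    boundaries end on matching bases. Substitution-level imperfection is
    handled; indel-containing duplications are outside this finder's model.
    """
    a, b = chrom_a.sequence, chrom_b.sequence
    if not a or not b:
        raise ValueError("empty sequence")
    k = max(15, min_len // 2)
    t = min_identity / 100.0
    penalty = t / (1.0 - t) if t < 1.0 else float(len(a) + len(b))
    a_idx: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        a_idx.setdefault(a[i : i + k], []).append(i)

    regions: list[SharedRegion] = []
    for orientation, q in (("same", b), ("inverted", revcomp(b))):
        diagonals: dict[int, list[int]] = {}
        for i in range(len(q) - k + 1):
            for p in a_idx.get(q[i : i + k], ()):
                diagonals.setdefault(p - i, []).append(i)
        for d, qpos in diagonals.items():
            qpos.sort()
            clusters: list[tuple[int, int]] = []
            # at the identity floor, exact k-mer seeds recur every ~k+4 bases,
            # so a generous merge distance cannot bridge unrelated matches
            # without the trim step cutting them apart again
            gap_limit = max(2 * k, min_len, 8 * k)
            cs, prev = qpos[0], qpos[0]
            for i in qpos[1:]:
                if i - prev > gap_limit:
                    clusters.append((cs, prev + k))
                    cs = i
                prev = i
            clusters.append((cs, prev + k))
            for qs, qe in clusters:
                # extend left
                while qs > 0 and qs + d > 0:
                    span = qe - (qs - 1)
                    m = sum(q[j] == a[j + d] for j in range(qs - 1, qe))
                    if m / span < t:
                        break
                    qs -= 1
                # extend right
                while qe < len(q) and qe + d < len(a):
                    span = (qe + 1) - qs
                    m = sum(q[j] == a[j + d] for j in range(qs, qe + 1))
                    if m / span < t:
                        break
                    qe += 1
                matches = [q[j] == a[j + d] and q[j] != "N"
                           for j in range(qs, qe)]
                off_s, off_e, n_match = _max_scoring_subsegment(matches, penalty)
                s, e = qs + off_s, qs + off_e
                length = e - s
                if length < min_len:
                    continue
                identity = 100.0 * n_match / length
                if identity < min_identity:
                    continue
                if orientation == "same":
                    start_b = s
                else:
                    start_b = len(b) - e
                regions.append(SharedRegion(chrom_a.id, s + d, chrom_b.id,
                                            start_b, length, identity, orientation))
    # deduplicate / merge overlapping same-diagonal reports
    uniq: dict[tuple, SharedRegion] = {}
    for r in regions:
        key = (r.orientation, r.start_a, r.start_b, r.length)
        uniq[key] = r
    merged = sorted(uniq.values(), key=lambda r: (r.start_a, r.start_b))
    out: list[SharedRegion] = []
    for r in merged:
        if out:
            p = out[-1]
            same_diag = (p.orientation == r.orientation
                         and (r.start_a - r.start_b == p.start_a - p.start_b
                              if r.orientation == "same"
                              else r.start_a + r.start_b + r.length
                              == p.start_a + p.start_b + p.length))
            if same_diag and r.start_a < p.end_a:
                continue  # contained/overlapping duplicate of the same match
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# join paths and spanning support


def enumerate_join_paths(region: SharedRegion,
                         chromosomes: list[CircularChromosome],
                         flank: int = 500) -> dict[str, str]:
    """The four flank-block-flank sequences through a shared region.

    ``ref_a``/``ref_b`` follow one chromosome throughout; ``chimera_ab``
    and ``chimera_ba`` switch chromosomes at the block, as a master-circle
    join would. Inverted-orientation regions are handled by working on the
    reverse complement of chromosome b. Flanks wrap circular origins.
    """
    by_id = {c.id: c for c in chromosomes}
    A = by_id[region.chrom_a].sequence
    B = by_id[region.chrom_b].sequence
    L = region.length
    if not (0 <= region.start_a and region.end_a <= len(A)
            and 0 <= region.start_b and region.end_b <= len(B)):
        raise ValueError("region coordinates invalid")
    sa = region.start_a
    if region.orientation == "same":
        Bw, sb = B, region.start_b
    else:
        Bw = revcomp(B)
        sb = len(B) - region.end_b
    left_a = circular_slice(A, sa - flank, flank)
    right_a = circular_slice(A, sa + L, flank)
    shared_a = A[sa : sa + L]
    left_b = circular_slice(Bw, sb - flank, flank)
    right_b = circular_slice(Bw, sb + L, flank)
    shared_b = Bw[sb : sb + L]
    return {
        "ref_a": left_a + shared_a + right_a,
        "ref_b": left_b + shared_b + right_b,
        "chimera_ab": left_a + shared_a + right_b,
        "chimera_ba": left_b + shared_b + right_a,
    }


def _read_spans_path(read_seq: str, path: str, flank: int, region_len: int,
                     anchor: int, min_identity: float) -> bool:
    """True when the read covers the shared block plus a matched anchor on
    both sides of it, at the required identity."""
    shared = path[flank : flank + region_len]
    left_anchor = path[flank - anchor : flank]
    right_anchor = path[flank + region_len : flank + region_len + anchor]
    t = min_identity / 100.0
    for rseq in (read_seq, revcomp(read_seq)):
        if len(rseq) < region_len + 2 * anchor:
            continue
        res = edlib.align(shared, rseq, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        if 1.0 - res["editDistance"] / region_len < t:
            continue
        for s, e in res["locations"][:8]:
            if s is None or s < anchor or e + 1 + anchor > len(rseq):
                continue
            if hamming_identity(rseq[s - anchor : s], left_anchor) < t:
                continue
            if hamming_identity(rseq[e + 1 : e + 1 + anchor], right_anchor) < t:
                continue
            return True
    return False


def count_spanning_reads(reads: list[tuple[str, str]], paths: dict[str, str],
                         region_len: int, flank: int = 500, anchor: int = 20,
                         min_identity: float = 95.0) -> dict[str, int]:
    """Spanning-read support per join path.

    A read supports a path when it aligns across the full shared block with
    at least ``anchor`` matched bases on both sides. A read equal to the
    block alone supports nothing. Reads without any exact 15-mer from the
    block are skipped outright.
    """
    if anchor >= flank:
        raise ValueError("anchor must be smaller than flank")
    pre_k = 15
    block = next(iter(paths.values()))[flank : flank + region_len]
    block_kmers = {block[i : i + pre_k] for i in range(max(1, len(block) - pre_k + 1))}
    block_kmers |= {revcomp(km) for km in block_kmers}
    support = {label: 0 for label in paths}
    for _rid, seq in reads:
        if not any(seq[i : i + pre_k] in block_kmers
                   for i in range(0, max(1, len(seq) - pre_k + 1), 4)):
            continue
        for label, path in paths.items():
            if _read_spans_path(seq, path, flank, region_len, anchor, min_identity):
                support[label] += 1
    return support


def classify_join_candidates(regions: list[SharedRegion], read_length: int,
                             chimeric_support: list[int]
                             ) -> tuple[list[JoinCandidate], dict]:
    """Master-circle bookkeeping over all shared regions.

    A region is *excluded* when it is shorter than the read length and no
    chimeric read spans it (reads of that length could have resolved it and
    none did); *candidate* when it is at least as long as the read length
    (unresolvable by those reads) with zero chimeric support; *supported*
    when any chimeric read spans it. The verdict is "master circle present"
    iff any region is supported.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if len(chimeric_support) != len(regions):
        raise ValueError("one support count per region required")
    cands: list[JoinCandidate] = []
    for region, sup in zip(regions, chimeric_support):
        if sup >= 1:
            status = "supported"
        elif region.length >= read_length:
            status = "candidate"
        else:
            status = "excluded"
        cands.append(JoinCandidate(region, status,
                                   spanning_support={"chimeric": sup}))
    counts = {
        "total": len(cands),
        "excluded": sum(c.status == "excluded" for c in cands),
        "candidate": sum(c.status == "candidate" for c in cands),
        "supported": sum(c.status == "supported" for c in cands),
    }
    counts["verdict"] = ("master circle present" if counts["supported"]
                         else "no master circle")
    return cands, counts


def master_circle_test(chromosomes: list[CircularChromosome],
                       reads: list[tuple[str, str]], read_length: int,
                       min_len: int = 30, min_identity: float = 95.0,
                       flank: int = 500, anchor: int = 20
                       ) -> tuple[list[JoinCandidate], dict]:
    """End-to-end master-circle test on a two-chromosome genome."""
    regions = find_shared_regions(chromosomes[0], chromosomes[1],
                                  min_len, min_identity)
    chim = []
    cands: list[JoinCandidate] = []
    for region in regions:
        flank_eff = min(flank, min(c.length for c in chromosomes) // 2 - 1)
        paths = enumerate_join_paths(region, chromosomes, flank_eff)
        support = count_spanning_reads(reads, paths, region.length, flank_eff,
                                       anchor)
        chim.append(support["chimera_ab"] + support["chimera_ba"])
        cands.append(JoinCandidate(region, "", paths, support, flank_eff))
    classified, counts = classify_join_candidates(regions, read_length, chim)
    for full, cls in zip(cands, classified):
        full.status = cls.status
    return cands, counts


# ---------------------------------------------------------------------------
# alternative conformations at long repeats


def detect_alternative_conformations(long_reads: list[tuple[str, str]],
                                     repeat: dict,
                                     chromosome: CircularChromosome,
                                     anchor: int = 100,
                                     min_identity: float = 90.0
                                     ) -> ConformationReport:
    """Count long-read support for the reference arrangement versus the
    repeat-mediated alternative.

    For an inverted repeat the alternative flips the segment between the
    two copies; for a direct repeat the alternative is a split into two
    subgenomic circles. ``repeat`` needs keys ``starts`` (two copy starts),
    ``length`` and ``kind`` ("inverted" or "direct"). A read is assigned to
    an arrangement when it spans a repeat copy with ``anchor`` matched
    bases on both sides consistent with that arrangement only.
    """
    s1, s2 = sorted(repeat["starts"])
    rep = repeat["length"]
    kind = repeat.get("kind", "inverted")
    if s1 + rep > s2:
        raise ValueError("repeat copies overlap")
    seq = chromosome.sequence

    def window(source: str, start: int) -> str:
        return circular_slice(source, start - anchor, rep + 2 * anchor)

    ref_windows = [window(seq, s1), window(seq, s2)]
    if kind == "inverted":
        labels = ("reference", "inverted")
        alt = seq[: s1 + rep] + revcomp(seq[s1 + rep : s2]) + seq[s2:]
        alt_windows = [window(alt, s1), window(alt, s2)]
    elif kind == "direct":
        labels = ("single_circle", "subcircles")
        sub1 = seq[s1:s2]
        sub2 = seq[s2:] + seq[:s1]
        alt_windows = [window(sub1, 0), window(sub2, 0)]
    else:
        raise ValueError(f"unknown repeat kind {kind!r}")

    support = {labels[0]: 0, labels[1]: 0}
    ambiguous = 0
    for _rid, read_seq in long_reads:
        spans_ref = any(_read_spans_path(read_seq, w, anchor, rep, anchor,
                                         min_identity) for w in ref_windows)
        spans_alt = any(_read_spans_path(read_seq, w, anchor, rep, anchor,
                                         min_identity) for w in alt_windows)
        if spans_ref and not spans_alt:
            support[labels[0]] += 1
        elif spans_alt and not spans_ref:
            support[labels[1]] += 1
        elif spans_ref and spans_alt:
            ambiguous += 1
    return ConformationReport(repeat, labels, support, ambiguous)
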