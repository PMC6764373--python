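"""Containers and IO for genomes, annotations and alignments.

Coordinates are 0-based half-open everywhere in memory; human-readable
reports use 1-based inclusive. SAM is consumed and produced as text via
pysam. The concatenated-coordinate map (:class:`ConcatMap`) joins several
chromosomes into one pseudo-chromosome, the frame in which spliced
alignments over a multichromosomal genome are expressed.

The module also houses :func:`map_reads`, a deliberately small
seed-and-extend read mapper (exact k-mer seeds, edlib verification) that
stands in for a production short/long-read mapper at desk scale. Circular
references are searched across the origin by doubling the sequence and
normalising positions modulo the length.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import edlib
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

# ---------------------------------------------------------------------------
# containers


@dataclass
class CircularChromosome:
    """A chromosome-scale DNA sequence, circular unless stated otherwise."""

    id: str
    sequence: str
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Annotation:
    """A located feature. Features spanning a circle's origin are split
    into two records sharing a name."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    feature_type: str = "gene"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.start}..{self.end} for {self.name!r}")


@dataclass
class AlignmentRecord:
    """One read alignment; cigar is a list of (op, length) with op in
    M/I/D/N/S. ``seq`` is carried when known so pileups can call bases."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    cigar: list[tuple[str, int]]
    seq: str | None = None
    mate_chrom: str | None = None
    mate_pos: int | None = None
    proper_pair: bool = False
    identity: float | None = None

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MDN")

    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    @property
    def end(self) -> int:
        return self.pos + self.reference_span()


class ConcatMap:
    """Invertible map between per-chromosome and concatenated coordinates."""

    def __init__(self, chromosomes: list[CircularChromosome]):
        if not chromosomes:
            raise ValueError("need at least one chromosome")
        ids = [c.id for c in chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids")
        self.ids = ids
        self.lengths = {c.id: c.length for c in chromosomes}
        self.offsets: dict[str, int] = {}
        off = 0
        for c in chromosomes:
            self.offsets[c.id] = off
            off += c.length
        self.total = off
        #: concatenated positions at which a new chromosome starts (excl. 0)
        self.boundaries = [self.offsets[i] for i in ids[1:]]

    def to_concat(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.offsets[chrom] + pos

    def from_concat(self, pos: int) -> tuple[str, int]:
        if not 0 <= pos < self.total:
            raise ValueError(f"concatenated position {pos} out of range")
        for cid in reversed(self.ids):
            if pos >= self.offsets[cid]:
                return cid, pos - self.offsets[cid]
        raise AssertionError("unreachable")

    def lift_interval(self, start: int, end: int) -> tuple[list[tuple[str, int, int]], bool]:
        """Lift a concatenated interval back; flags cross-chromosomal spans."""
        if not 0 <= start < end <= self.total:
            raise ValueError("interval out of range")
        pieces: list[tuple[str, int, int]] = []
        pos = start
        while pos < end:
            cid, local = self.from_concat(pos)
            stop = min(end, self.offsets[cid] + self.lengths[cid])
            pieces.append((cid, local, local + (stop - pos)))
            pos = stop
        return pieces, len(pieces) > 1

    def concatenated_sequence(self, chromosomes: list[CircularChromosome]) -> str:
        return "".join(c.sequence for c in chromosomes)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def write_fasta(path, chromosomes: list[CircularChromosome]) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id,
                  description="circular" if c.circular else "linear")
        for c in chromosomes
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path, circular: bool = True) -> list[CircularChromosome]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        if "circular" in rec.description:
            circ = True
        elif "linear" in rec.description:
            circ = False
        else:
            circ = circular
        out.append(CircularChromosome(rec.id, str(rec.seq).upper(), circ))
    return out


def write_fastq(path, reads: list[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


# ---------------------------------------------------------------------------
# GFF3 / BED

_GFF_SOURCE = "mitokit"


def write_gff3(path, annotations: list[Annotation]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.chrom}\t{_GFF_SOURCE}\t{a.feature_type}\t{a.start + 1}\t{a.end}\t.\t"
                f"{a.strand}\t.\tName={a.name}\n"
            )


def read_gff3(path) -> list[Annotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = \
                line.rstrip("\n").split("\t")
            name = ""
            for kv in attrs.split(";"):
                if kv.startswith("Name="):
                    name = kv[5:]
            out.append(Annotation(chrom, int(start) - 1, int(end), strand, ftype, name))
    return out


def write_bed(path, intervals: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out


# ---------------------------------------------------------------------------
# SAM text

_OP2INT = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}
_INT2OP = {v: k for k, v in _OP2INT.items()}


def write_sam(path, records: list[AlignmentRecord], references: dict[str, int]) -> None:
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": name, "LN": length} for name, length in references.items()]}
    )
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            seg.reference_name = rec.chrom
            seg.reference_start = rec.pos
            seg.flag = 16 if rec.strand == "-" else 0
            seg.cigartuples = [(_OP2INT[op], n) for op, n in rec.cigar]
            if rec.seq is not None:
                seg.query_sequence = rec.seq
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            seg.mapping_quality = 60
            out.write(seg)


def read_sam(path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        refs = dict(zip(fh.references, fh.lengths))
        for seg in fh:
            if seg.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    chrom=seg.reference_name,
                    pos=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=[(_INT2OP[op], n) for op, n in seg.cigartuples],
                    seq=seg.query_sequence,
                )
            )
    return records, refs


def sam_text(records: list[AlignmentRecord], references: dict[str, int]) -> str:
    buf = io.StringIO()
    header = "@HD\tVN:1.6\tSO:unsorted\n" + "".join(
        f"@SQ\tSN:{n}\tLN:{ln}\n" for n, ln in references.items()
    )
    buf.write(header)
    for rec in records:
        cig = "".join(f"{n}{op}" for op, n in rec.cigar)
        flag = 16 if rec.strand == "-" else 0
        seq = rec.seq or "*"
        qual = "I" * len(seq) if rec.seq else "*"
        buf.write(
            f"{rec.read_id}\t{flag}\t{rec.chrom}\t{rec.pos + 1}\t60\t{cig}\t*\t0\t0\t{seq}\t{qual}\n"
        )
    return buf.getvalue()


def deduplicate(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Drop alignments duplicating (chrom, pos, strand, cigar, mate pos)."""
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.chrom, r.pos, r.strand, tuple(r.cigar), r.mate_pos)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# read mapping


@dataclass
class MapParams:
    seed_k: int = 15
    min_identity: float = 0.9
    circular: bool = True


@dataclass
class MappingResult:
    alignments: list[AlignmentRecord]
    unmapped: list[str] = field(default_factory=list)


def _edlib_cigar_to_sam(cigar: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            op = "M" if ch in "=X" else ch
            if out and out[-1][0] == op:
                out[-1] = (op, out[-1][1] + int(num))
            else:
                out.append((op, int(num)))
            num = ""
    return out


class _RefIndex:
    """Exact k-mer index over (optionally doubled) reference sequences."""

    def __init__(self, chromosomes: list[CircularChromosome], k: int, circular: bool):
        self.k = k
        self.chroms = {c.id: c for c in chromosomes}
        self.search_seq: dict[str, str] = {}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for c in chromosomes:
            seq = c.sequence + c.sequence if (circular and c.circular) else c.sequence
            self.search_seq[c.id] = seq
            limit = c.length if (circular and c.circular) else max(0, len(seq) - k + 1)
            for i in range(limit):
                self.index.setdefault(seq[i : i + k], []).append((c.id, i))


def _align_candidate(read: str, ref: str, cand: int, min_identity: float):
    """edlib-verify a candidate placement; returns (pos, cigar, identity)."""
    pad = max(8, len(read) // 20)
    lo = max(0, cand - pad)
    window = ref[lo : cand + len(read) + pad]
    res = edlib.align(read, window, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    identity = 1.0 - res["editDistance"] / len(read)
    if identity < min_identity:
        return None
    start, _end = res["locations"][0]
    return lo + start, _edlib_cigar_to_sam(res["cigar"]), identity


def map_reads(reads: list[tuple[str, str]], reference: list[CircularChromosome],
              params: MapParams | None = None) -> MappingResult:
    """Map reads by exact-seed lookup plus edlib extension.

    Each reported alignment has identity >= ``min_identity`` over the read;
    both strands are searched, circular references across the origin, and
    ties are broken by lowest (chromosome id, position).
    """
    params = params or MapParams()
    k = params.seed_k
    idx = _RefIndex(reference, k, params.circular)
    result = MappingResult([])
    for rid, seq in reads:
        if len(seq) < k:
            result.unmapped.append(rid)
            continue
        best = None  # (identity-, chrom, pos, strand, cigar)
        for strand, rseq in (("+", seq), ("-", revcomp(seq))):
            step = max(k, (len(rseq) - k) // 15 or k)
            candidates: set[tuple[str, int]] = set()
            for off in range(0, len(rseq) - k + 1, step):
                for cid, hit in idx.index.get(rseq[off : off + k], ()):
                    candidates.add((cid, max(0, hit - off)))
            for cid, cand in sorted(candidates):
                hit = _align_candidate(rseq, idx.search_seq[cid], cand,
                                       params.min_identity)
                if hit is None:
                    continue
                pos, cigar, identity = hit
                L = idx.chroms[cid].length
                if params.circular and idx.chroms[cid].circular and pos >= L:
                    pos -= L
                key = (-identity, cid, pos, strand)
                if best is None or key < best[0]:
                    best = (key, AlignmentRecord(rid, cid, pos, strand, cigar,
                                                 seq=rseq, identity=identity))
        if best is None:
            result.unmapped.append(rid)
        else:
            result.alignments.append(best[1])
    return result
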