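"""Synthetic two-chromosome mitogenomes with full ground truth.

The generator emulates, at one-tenth scale, the structural repertoire of a
multichromosomal grass mitochondrial genome: two circular chromosomes, a
dozen short (sometimes imperfect) regions shared between them, one long
direct repeat and one inverted repeat on chromosome 1, multi-exon genes
including one whose exons are split across chromosomes, a plastid-derived
segment with chloroplast-like GC, C->U (optionally G->A) editing sites,
and polyA-tagged degradation regions. Every planted structure is recorded
in a :class:`GroundTruth` that downstream stages are tested against.

Shared-region copies are planted with a guaranteed mismatching base
immediately outside each copy and with divergence mismatches kept >= 25 bp
from the copy ends, so the planted boundaries are unambiguous and exactly
recoverable. PolyA degradation regions have lengths that are multiples of
the short-read length and are covered in exact read layers, giving a
rectangular depth profile whose edges coincide with the truth interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._seq import revcomp, circular_slice
from .sequence_io import Annotation, AlignmentRecord, CircularChromosome, ConcatMap

_BASES = np.array(list("ACGT"))
_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: interior margin (bp) kept mismatch-free at shared-region ends
_SHARED_EDGE_MARGIN = 25


@dataclass
class SimulationConfig:
    seed: int = 42
    chr_lengths: tuple[int, ...] = (30000, 15000)
    n_shared_regions: int = 12
    shared_len_range: tuple[int, int] = (30, 360)
    shared_mismatch_rate: float = 0.02
    direct_repeat_len: int = 1500
    inverted_repeat_len: int = 400
    n_genes: int = 8
    n_trans_spliced_genes: int = 1
    plastid_segment_len: int = 1000
    plastid_gc_target: float = 0.384
    mito_gc_target: float = 0.435
    editing_sites: int = 20
    gtoa_fraction: float = 0.0
    degradation_regions: int = 4
    degradation_depth: int = 600
    read_len_short: int = 120
    insert_mean: int = 400
    insert_sd: int = 40
    long_read_mean: int = 2000
    long_read_sd: int = 200
    error_rate: float = 0.0
    coverage: float = 20.0

    def validate(self) -> None:
        if any(L <= 2 * self.direct_repeat_len for L in self.chr_lengths):
            raise ValueError("every chromosome must exceed twice the direct repeat length")
        lo, hi = self.shared_len_range
        if not (0 < lo <= hi <= 360):
            raise ValueError("shared_len_range must lie within (0, 360]")
        for name in ("plastid_gc_target", "mito_gc_target"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0,1)")
        if self.error_rate < 0 or self.coverage < 0:
            raise ValueError("error_rate and coverage must be non-negative")


@dataclass
class GroundTruth:
    """The simulator's lossless record of every planted structure."""

    shared_regions: list[dict] = field(default_factory=list)
    repeat_loci: dict = field(default_factory=dict)
    gene_models: list[dict] = field(default_factory=list)
    planted_junctions: list[dict] = field(default_factory=list)
    editing_sites: list[dict] = field(default_factory=list)
    degradation_regions: list[dict] = field(default_factory=list)
    plastid_segments: list[dict] = field(default_factory=list)
    conformation_mix: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# sequence construction helpers


def _exact_gc_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Sequence whose GC count is exactly round(gc*n) (then shuffled)."""
    n_gc = round(gc * n)
    arr = np.concatenate([
        rng.choice(np.array(list("GC")), size=n_gc),
        rng.choice(np.array(list("AT")), size=n - n_gc),
    ])
    rng.shuffle(arr)
    return arr


class _Placer:
    """Reserves non-overlapping intervals on one chromosome."""

    def __init__(self, chrom_name: str, length: int, rng: np.random.Generator,
                 margin: int = 40):
        self.name = chrom_name
        self.length = length
        self.rng = rng
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def _free(self, start: int, end: int) -> bool:
        m = self.margin
        return all(end + m <= s or e + m <= start for s, e in self.taken)

    def reserve(self, length: int, tries: int = 400) -> int:
        if length + 2 * self.margin >= self.length:
            raise ValueError(f"feature of {length} bp cannot fit on {self.name}")
        for _ in range(tries):
            start = int(self.rng.integers(self.margin, self.length - length - self.margin))
            if self._free(start, start + length):
                self.taken.append((start, start + length))
                return start
        raise ValueError(f"infeasible packing: no room for {length} bp on {self.name}")

    def reserve_at(self, start: int, length: int) -> int:
        if not self._free(start, start + length):
            raise ValueError(f"infeasible packing at {start} on {self.name}")
        self.taken.append((start, start + length))
        return start

    def reserve_chain(self, lengths: list[int], gaps: list[int],
                      tries: int = 400) -> list[int]:
        """Reserve several intervals with fixed spacing (an exon chain)."""
        total = sum(lengths) + sum(gaps)
        if total + 2 * self.margin >= self.length:
            raise ValueError(f"infeasible packing: {total} bp chain on {self.name}")
        for _ in range(tries):
            start = int(self.rng.integers(self.margin, self.length - total - self.margin))
            starts = []
            cur = start
            for ln, gp in zip(lengths, gaps + [0]):
                starts.append(cur)
                cur += ln + gp
            if all(self._free(s, s + ln) for s, ln in zip(starts, lengths)):
                for s, ln in zip(starts, lengths):
                    self.taken.append((s, s + ln))
                return starts
        raise ValueError(f"infeasible packing: no room for exon chain on {self.name}")


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# genome generation


def generate_mitogenome(config: SimulationConfig
                        ) -> tuple[list[CircularChromosome], list[Annotation], GroundTruth]:
    """Build the toy mitogenome, its annotations, and the ground truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    names = [f"chr{i + 1}" for i in range(len(config.chr_lengths))]
    seqs = [_exact_gc_seq(rng, L, config.mito_gc_target) for L in config.chr_lengths]
    placers = [_Placer(n, L, rng) for n, L in zip(names, config.chr_lengths)]
    truth = GroundTruth()
    annotations: list[Annotation] = []

    # --- long repeats on chromosome 1
    dr = config.direct_repeat_len
    d1 = placers[0].reserve(dr)
    d2 = placers[0].reserve(dr)
    d1, d2 = sorted((d1, d2))
    seqs[0][d2:d2 + dr] = seqs[0][d1:d1 + dr]
    ir = config.inverted_repeat_len
    i1 = placers[0].reserve(ir)
    i2 = placers[0].reserve(ir)
    i1, i2 = sorted((i1, i2))
    seqs[0][i2:i2 + ir] = np.array(list(revcomp("".join(seqs[0][i1:i1 + ir]))))
    truth.repeat_loci = {
        "direct": {"chrom": names[0], "starts": [d1, d2], "length": dr},
        "inverted": {"chrom": names[0], "starts": [i1, i2], "length": ir},
    }
    for kind, locus in truth.repeat_loci.items():
        for j, s in enumerate(locus["starts"]):
            annotations.append(Annotation(names[0], s, s + locus["length"], "+",
                                          "repeat", f"{kind}_repeat_{j + 1}"))

    # --- plastid-derived segment (chloroplast-like GC) on chromosome 1
    pl = config.plastid_segment_len
    ps = placers[0].reserve(pl)
    seqs[0][ps:ps + pl] = _exact_gc_seq(rng, pl, config.plastid_gc_target)
    truth.plastid_segments.append({"chrom": names[0], "start": ps, "end": ps + pl})
    annotations.append(Annotation(names[0], ps, ps + pl, "+", "plastid_derived",
                                  "plastid_segment_1"))

    # --- shared regions copied chr1 -> chr2 (every fourth one inverted)
    lo, hi = config.shared_len_range
    for i in range(config.n_shared_regions):
        length = int(rng.integers(lo, hi + 1))
        sa = placers[0].reserve(length)
        sb = placers[1].reserve(length)
        inverted = i % 4 == 3
        src = seqs[0][sa:sa + length].copy()
        copy = np.array(list(revcomp("".join(src)))) if inverted else src.copy()
        # divergence only in the interior, away from the planted ends, and
        # spaced out so the copies stay locally near-exact
        m = min(_SHARED_EDGE_MARGIN, max(0, length // 2 - 1))
        interior = length - 2 * m
        spacing = 30
        mism = 0
        if interior > 0:
            want = int(rng.binomial(interior, config.shared_mismatch_rate))
            feasible = max(0, (interior + spacing) // (spacing + 1))
            n_mm = min(want, feasible)
            if n_mm > 0:
                # sorted positions with pairwise gaps >= spacing
                slack = interior - (n_mm - 1) * spacing
                raw = np.sort(rng.choice(slack, size=n_mm, replace=False))
                for j, r in enumerate(raw):
                    p = m + int(r) + j * spacing
                    copy[p] = _mutate_base(rng, copy[p])
                    mism += 1
        seqs[1][sb:sb + length] = copy
        # guard bases: the diagonal continuation must mismatch just outside
        a, b = seqs[0], seqs[1]
        if not inverted:
            if sb > 0 and sa > 0 and b[sb - 1] == a[sa - 1]:
                b[sb - 1] = _mutate_base(rng, a[sa - 1])
            if sb + length < len(b) and sa + length < len(a) \
                    and b[sb + length] == a[sa + length]:
                b[sb + length] = _mutate_base(rng, a[sa + length])
        else:
            if sb + length < len(b) and sa > 0 \
                    and b[sb + length] == _COMP1[a[sa - 1]]:
                b[sb + length] = _mutate_base(rng, _COMP1[a[sa - 1]])
            if sb > 0 and sa + length < len(a) \
                    and b[sb - 1] == _COMP1[a[sa + length]]:
                b[sb - 1] = _mutate_base(rng, _COMP1[a[sa + length]])
        truth.shared_regions.append({
            "chrom_a": names[0], "start_a": sa, "chrom_b": names[1], "start_b": sb,
            "length": length, "identity": 100.0 * (length - mism) / length,
            "orientation": "inverted" if inverted else "same",
        })

    # --- gene models (all + strand); one gene trans-spliced across chromosomes
    n_cis = config.n_genes - config.n_trans_spliced_genes
    homes = [0 if g < max(1, round(n_cis * 0.7)) else 1 for g in range(n_cis)]
    gene_plans = [("cis", h) for h in homes] + \
                 [("trans", None)] * config.n_trans_spliced_genes
    for g, (kind, home) in enumerate(gene_plans):
        name = f"gene{g + 1}" if kind == "cis" else f"transgene{g + 1}"
        n_exons = int(rng.integers(2, 4))
        exons: list[dict] = []
        if kind == "cis":
            lengths = [int(rng.integers(150, 400)) for _ in range(n_exons)]
            gaps = [int(rng.integers(350, 900)) for _ in range(n_exons - 1)]
            starts = placers[home].reserve_chain(lengths, gaps)
            exons = [{"chrom": names[home], "start": s, "end": s + ln}
                     for s, ln in zip(starts, lengths)]
        else:
            # exon(s) on chr1 then a final exon on chr2: the junction between
            # them crosses the concatenation boundary
            lengths = [int(rng.integers(150, 400)) for _ in range(n_exons - 1)]
            gaps = [int(rng.integers(350, 900)) for _ in range(n_exons - 2)]
            starts = placers[0].reserve_chain(lengths, gaps)
            exons = [{"chrom": names[0], "start": s, "end": s + ln}
                     for s, ln in zip(starts, lengths)]
            elen = int(rng.integers(150, 400))
            start = placers[1].reserve(elen)
            exons.append({"chrom": names[1], "start": start, "end": start + elen})
        truth.gene_models.append({"name": name, "strand": "+", "exons": exons})
        for chrom in {e["chrom"] for e in exons}:
            sub = [e for e in exons if e["chrom"] == chrom]
            annotations.append(Annotation(chrom, min(e["start"] for e in sub),
                                          max(e["end"] for e in sub), "+", "gene", name))
        for j, e in enumerate(exons):
            annotations.append(Annotation(e["chrom"], e["start"], e["end"], "+",
                                          "exon", f"{name}.exon{j + 1}"))
            annotations.append(Annotation(e["chrom"], e["start"], e["end"], "+",
                                          "CDS", f"{name}.cds{j + 1}"))
        for j in range(len(exons) - 1):
            truth.planted_junctions.append({
                "gene": name,
                "donor": {"chrom": exons[j]["chrom"], "pos": exons[j]["end"] - 1},
                "acceptor": {"chrom": exons[j + 1]["chrom"], "pos": exons[j + 1]["start"]},
                "support": 0,
            })

    # --- editing sites inside exons (C->U, optionally G->A)
    exon_pool = [(e["chrom"], p)
                 for gm in truth.gene_models for e in gm["exons"]
                 for p in range(e["start"] + 2, e["end"] - 2)]
    picks = rng.choice(len(exon_pool), size=min(config.editing_sites, len(exon_pool)),
                       replace=False)
    n_gtoa = round(config.gtoa_fraction * len(picks))
    for j, pi in enumerate(sorted(int(x) for x in picks)):
        chrom, pos = exon_pool[pi]
        ci = names.index(chrom)
        if j < n_gtoa:
            genomic, edited = "G", "A"
        else:
            genomic, edited = "C", "T"
        seqs[ci][pos] = genomic
        truth.editing_sites.append({"chrom": chrom, "pos": pos,
                                    "genomic": genomic, "edited": edited})

    # --- polyA degradation regions: lengths are read-length multiples; one
    #     sits inside an intron of a chr1 gene, the rest are intergenic
    rl = config.read_len_short
    placed_in_intron = False
    for d in range(config.degradation_regions):
        length = rl * int(rng.integers(2, 4))
        start = None
        chrom_i = 0
        if not placed_in_intron:
            for gm in truth.gene_models:
                ex = gm["exons"]
                for j in range(len(ex) - 1):
                    if ex[j]["chrom"] != names[0] or ex[j + 1]["chrom"] != names[0]:
                        continue
                    gap_lo, gap_hi = ex[j]["end"], ex[j + 1]["start"]
                    pad = placers[0].margin + 1
                    if gap_hi - gap_lo >= length + 2 * pad:
                        try:
                            start = placers[0].reserve_at(gap_lo + pad, length)
                        except ValueError:
                            continue  # intron already hosts another feature
                        placed_in_intron = True
                        break
                if start is not None:
                    break
        if start is None:
            chrom_i = int(rng.integers(0, 2))
            start = placers[chrom_i].reserve(length)
        truth.degradation_regions.append({
            "chrom": names[chrom_i], "start": start, "end": start + length,
            "depth": config.degradation_depth,
        })

    chromosomes = [CircularChromosome(n, "".join(s)) for n, s in zip(names, seqs)]
    annotations.sort(key=lambda a: (a.chrom, a.start, a.feature_type, a.name))
    return chromosomes, annotations, truth


# ---------------------------------------------------------------------------
# genomic reads


@dataclass
class GenomicReadSet:
    """Simulated reads plus the truth placement of each read."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    long_reads: list[tuple[str, str]] = field(default_factory=list)
    placements: dict[str, tuple[str, int, str, int]] = field(default_factory=dict)

    def all_sequences(self) -> list[tuple[str, str]]:
        out = [(f"{rid}/1", r1) for rid, r1, _ in self.pairs]
        out += [(f"{rid}/2", r2) for rid, _, r2 in self.pairs]
        out += list(self.long_reads)
        return out


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for p in hits:
        arr[p] = _mutate_base(rng, arr[p])
    return "".join(arr)


def build_master_circle(chr_a: CircularChromosome, chr_b: CircularChromosome,
                        region: dict) -> CircularChromosome:
    """Fuse two circles through a shared region into one chimeric circle.

    Positive control for the master-circle test: reads from this molecule
    contain both chimeric join paths through the shared block.
    """
    sa, sb, L = region["start_a"], region["start_b"], region["length"]
    a, b = chr_a.sequence, chr_b.sequence
    if region.get("orientation", "same") == "inverted":
        sb = len(b) - sb - L
        b = revcomp(b)
    fused = (a[:sa] + a[sa:sa + L] + b[sb + L:] + b[:sb] + b[sb:sb + L] + a[sa + L:])
    return CircularChromosome(f"{chr_a.id}+{chr_b.id}", fused)


def simulate_genomic_reads(chromosomes: list[CircularChromosome],
                           config: SimulationConfig, *,
                           long_reads: bool = False,
                           seed_tag: int = 2) -> GenomicReadSet:
    """Uniform circular read sampling: paired-end short reads by default,
    single-molecule long reads when ``long_reads`` is set."""
    config.validate()
    rng = np.random.default_rng([config.seed, seed_tag, int(long_reads)])
    out = GenomicReadSet()
    if config.coverage == 0:
        return out
    counter = 0
    for chrom in chromosomes:
        L, seq = chrom.length, chrom.sequence
        if long_reads:
            n = max(1, round(config.coverage * L / config.long_read_mean))
            for _ in range(n):
                rlen = max(300, round(rng.normal(config.long_read_mean,
                                                 config.long_read_sd)))
                rlen = min(rlen, L)
                start = int(rng.integers(0, L))
                strand = "+" if rng.random() < 0.5 else "-"
                frag = circular_slice(seq, start, rlen)
                if strand == "-":
                    frag = revcomp(frag)
                rid = f"long{counter:06d}"
                counter += 1
                out.long_reads.append((rid, _apply_errors(rng, frag, config.error_rate)))
                out.placements[rid] = (chrom.id, start, strand, rlen)
        else:
            rl = config.read_len_short
            n = max(1, round(config.coverage * L / (2 * rl)))
            for _ in range(n):
                ins = max(2 * rl, round(rng.normal(config.insert_mean, config.insert_sd)))
                ins = min(ins, L)
                start = int(rng.integers(0, L))
                r1 = circular_slice(seq, start, rl)
                r2 = revcomp(circular_slice(seq, start + ins - rl, rl))
                rid = f"pair{counter:06d}"
                counter += 1
                out.pairs.append((rid,
                                  _apply_errors(rng, r1, config.error_rate),
                                  _apply_errors(rng, r2, config.error_rate)))
                out.placements[rid] = (chrom.id, start, "+", ins)
    return out


def simulate_conformation_reads(chrom: CircularChromosome, repeat: dict,
                                n_reference: int, n_alternative: int,
                                config: SimulationConfig, *,
                                arrangement: str = "inverted",
                                seed_tag: int = 5
                                ) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Long reads spanning a repeat copy, drawn from a mixture of the
    reference arrangement and an alternative one.

    ``arrangement="inverted"`` recombines the two inverted-repeat copies,
    flipping the segment between them; ``"subcircles"`` splits the circle
    at the two direct-repeat copies into two subgenomic circles. Returns
    the reads and a read-id -> {reference, alternative} truth label map.
    """
    rng = np.random.default_rng([config.seed, seed_tag])
    starts, rep_len = repeat["starts"], repeat["length"]
    s1, s2 = sorted(starts)
    if s1 + rep_len > s2:
        raise ValueError("repeat copies overlap")
    seq = chrom.sequence
    if arrangement == "inverted":
        alt_seqs = [seq[:s1 + rep_len] + revcomp(seq[s1 + rep_len:s2]) + seq[s2:]]
        alt_copy_starts = [[s1, s2]]
    elif arrangement == "subcircles":
        alt_seqs = [seq[s1:s2], seq[s2:] + seq[:s1]]
        alt_copy_starts = [[0], [0]]
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    reads: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    rlen = config.long_read_mean

    def span_read(source: str, copy_start: int, rid: str) -> str:
        margin = (rlen - rep_len) // 2
        jitter = int(rng.integers(-margin // 3, margin // 3 + 1))
        start = copy_start - margin + jitter
        frag = circular_slice(source, start % len(source), min(rlen, len(source)))
        return _apply_errors(rng, frag, config.error_rate)

    for i in range(n_reference):
        copy = [s1, s2][int(rng.integers(0, 2))]
        rid = f"conf_ref{i:04d}"
        reads.append((rid, span_read(seq, copy, rid)))
        labels[rid] = "reference"
    for i in range(n_alternative):
        which = int(rng.integers(0, len(alt_seqs)))
        copy = alt_copy_starts[which][int(rng.integers(0, len(alt_copy_starts[which])))]
        rid = f"conf_alt{i:04d}"
        reads.append((rid, span_read(alt_seqs[which], copy, rid)))
        labels[rid] = "alternative"
    return reads, labels


# ---------------------------------------------------------------------------
# transcript alignments


def simulate_transcript_alignments(chromosomes: list[CircularChromosome],
                                   annotations: list[Annotation],
                                   truth: GroundTruth,
                                   config: SimulationConfig
                                   ) -> tuple[list[AlignmentRecord],
                                              list[AlignmentRecord],
                                              dict[str, int]]:
    """Emit truth spliced/edited transcript alignments and polyA-tagged
    degradation reads over the concatenated reference.

    Returns (spliced records, polyA records, SAM reference dict). Junction
    support counts in ``truth.planted_junctions`` are updated to the exact
    number of emitted reads spanning each junction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    cmap = ConcatMap(chromosomes)
    concat_name = "mt_concat"
    refs = {concat_name: cmap.total}
    seqs = {c.id: c.sequence for c in chromosomes}
    rl = config.read_len_short

    spliced: list[AlignmentRecord] = []
    junction_index = {(j["donor"]["chrom"], j["donor"]["pos"],
                       j["acceptor"]["chrom"], j["acceptor"]["pos"]): j
                      for j in truth.planted_junctions}
    for j in truth.planted_junctions:
        j["support"] = 0

    edits = {(e["chrom"], e["pos"]): e["edited"] for e in truth.editing_sites}
    counter = 0
    for gm in truth.gene_models:
        exons = gm["exons"]
        segs = [(cmap.to_concat(e["chrom"], e["start"]),
                 cmap.to_concat(e["chrom"], e["end"] - 1) + 1, e) for e in exons]
        if any(segs[k][0] >= segs[k + 1][0] for k in range(len(segs) - 1)):
            raise AssertionError("exons must ascend in concatenated coordinates")
        tx = []
        for e in exons:
            piece = list(seqs[e["chrom"]][e["start"]:e["end"]])
            for p in range(e["start"], e["end"]):
                if (e["chrom"], p) in edits:
                    piece[p - e["start"]] = edits[(e["chrom"], p)]
            tx.append("".join(piece))
        tx_seq = "".join(tx)
        tx_len = len(tx_seq)
        if tx_len < rl:
            continue
        n_reads = max(1, round(config.coverage * tx_len / rl))
        # transcript offset of each exon
        offsets = np.cumsum([0] + [len(t) for t in tx])
        for _ in range(n_reads):
            t0 = int(rng.integers(0, tx_len - rl + 1))
            t1 = t0 + rl
            cigar: list[tuple[str, int]] = []
            pos0 = None
            prev_end = None
            for k, (cs, ce, e) in enumerate(segs):
                e0, e1 = offsets[k], offsets[k + 1]
                ov0, ov1 = max(t0, e0), min(t1, e1)
                if ov0 >= ov1:
                    continue
                g0 = cs + (ov0 - e0)
                if pos0 is None:
                    pos0 = g0
                else:
                    gap = g0 - prev_end
                    cigar.append(("N", gap))
                    donor_c, donor_p = cmap.from_concat(prev_end - 1)
                    acc_c, acc_p = cmap.from_concat(g0)
                    key = (donor_c, donor_p, acc_c, acc_p)
                    if key in junction_index:
                        junction_index[key]["support"] += 1
                cigar.append(("M", ov1 - ov0))
                prev_end = g0 + (ov1 - ov0)
            rid = f"tx{counter:06d}"
            counter += 1
            read_seq = _apply_errors(rng, tx_seq[t0:t1], config.error_rate)
            spliced.append(AlignmentRecord(rid, concat_name, pos0, "+", cigar,
                                           seq=read_seq))

    polya: list[AlignmentRecord] = []
    counter = 0
    for region in truth.degradation_regions:
        c0 = cmap.to_concat(region["chrom"], region["start"])
        length = region["end"] - region["start"]
        per_layer = length // rl
        for _layer in range(region["depth"]):
            for j in range(per_layer):
                pos = c0 + j * rl
                chrom_seq = seqs[region["chrom"]]
                s_local = region["start"] + j * rl
                read_seq = chrom_seq[s_local:s_local + rl]
                rid = f"polyA{counter:07d}"
                counter += 1
                polya.append(AlignmentRecord(rid, concat_name, pos, "+",
                                             [("M", rl)],
                                             seq=_apply_errors(rng, read_seq,
                                                               config.error_rate)))
    return spliced, polya, refs
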