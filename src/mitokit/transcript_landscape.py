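"""Transcript coverage, polyA degradation islands, expression fold-change.

Coverage counts reference-consuming aligned bases (M and D; skips add
nothing). PolyA-selected reads mark transcripts tagged for degradation,
so contiguous deep stacks of them ("islands") localise dispensable
regions; islands are maximal runs above a depth threshold and are
annotated with the feature classes they overlap. Expression is a
length-normalised fold change: c = N/L per region, F =
c_region / c_background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .sequence_io import AlignmentRecord, Annotation, CircularChromosome, ConcatMap


@dataclass
class CoverageTrack:
    chrom: str
    depth: np.ndarray

    @property
    def completeness(self) -> float:
        if len(self.depth) == 0:
            return 0.0
        return float((self.depth > 0).sum()) / len(self.depth)

    def log10(self) -> np.ndarray:
        return np.log10(self.depth + 1.0)


@dataclass
class PolyAIsland:
    chrom: str
    start: int
    end: int
    mean_depth: float
    feature_classes: set[str] = field(default_factory=set)


@dataclass
class ExpressionReport:
    name: str
    length: int
    n_reads: int
    normalized: float          # c = N / L, unrounded
    fold: float | None = None  # F = c / c_background; None if undefined

    @property
    def normalized_2dp(self) -> float:
        return round(self.normalized, 2)

    @property
    def fold_2dp(self) -> float | None:
        return None if self.fold is None else round(self.fold, 2)


# ---------------------------------------------------------------------------
# coverage


def compute_coverage(alignments: list[AlignmentRecord],
                     references: dict[str, int] | list[CircularChromosome]
                     ) -> tuple[dict[str, CoverageTrack], dict]:
    """Per-base depth per reference; alignments running past the reference
    end are rejected and tallied in the returned QC dict."""
    if not isinstance(references, dict):
        references = {c.id: c.length for c in references}
    delta = {name: np.zeros(L + 1, dtype=np.int64) for name, L in references.items()}
    qc = {"rejected_out_of_range": 0}
    for rec in alignments:
        if rec.chrom not in delta:
            continue
        L = references[rec.chrom]
        if rec.end > L:
            qc["rejected_out_of_range"] += 1
            continue
        rp = rec.pos
        d = delta[rec.chrom]
        for op, n in rec.cigar:
            if op in "MD":
                d[rp] += 1
                d[rp + n] -= 1
                rp += n
            elif op == "N":
                rp += n
    tracks = {name: CoverageTrack(name, np.cumsum(d[:-1]))
              for name, d in delta.items()}
    return tracks, qc


# ---------------------------------------------------------------------------
# polyA islands


_CLASSES_BY_FEATURE = {
    "repeat": "repeat",
    "plastid_derived": "plastid_derived",
    "pseudogene": "pseudogene",
}


def _island_classes(chrom: str, start: int, end: int,
                    gene_trees: dict[str, IntervalTree],
                    exon_trees: dict[str, IntervalTree],
                    other_trees: dict[str, IntervalTree]) -> set[str]:
    classes: set[str] = set()
    for iv in other_trees.get(chrom, IntervalTree())[start:end]:
        classes.add(iv.data)
    in_exon = bool(exon_trees.get(chrom, IntervalTree())[start:end])
    in_gene = bool(gene_trees.get(chrom, IntervalTree())[start:end])
    if in_exon:
        classes.add("gene_copy")
    if in_gene and not in_exon:
        classes.add("intron")
    if not classes:
        classes.add("intergenic")
    return classes


def polya_islands(track: CoverageTrack, annotations: list[Annotation],
                  min_depth: int = 500, min_len: int = 50,
                  concat_map: ConcatMap | None = None
                  ) -> tuple[list[PolyAIsland], float]:
    """Maximal runs of depth >= ``min_depth`` and length >= ``min_len``.

    When the track lives on a concatenated pseudo-chromosome, pass the
    concat map so islands are lifted (and split at boundaries) back to
    chromosome coordinates before annotation. Returns (islands, fraction
    of the track covered by islands).
    """
    depth = track.depth
    mask = depth >= min_depth
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = edges.reshape(-1, 2)

    gene_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    other_trees: dict[str, IntervalTree] = {}
    for a in annotations:
        if a.feature_type == "gene":
            gene_trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end)
        elif a.feature_type in ("exon", "CDS"):
            exon_trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end)
        elif a.feature_type in _CLASSES_BY_FEATURE:
            other_trees.setdefault(a.chrom, IntervalTree()).addi(
                a.start, a.end, _CLASSES_BY_FEATURE[a.feature_type])

    islands: list[PolyAIsland] = []
    covered = 0
    for s, e in runs:
        s, e = int(s), int(e)
        if e - s < min_len:
            continue
        covered += e - s
        mean_depth = float(depth[s:e].mean())
        if concat_map is not None:
            pieces, _cross = concat_map.lift_interval(s, e)
        else:
            pieces = [(track.chrom, s, e)]
        for chrom, ps, pe in pieces:
            classes = _island_classes(chrom, ps, pe, gene_trees, exon_trees,
                                      other_trees)
            islands.append(PolyAIsland(chrom, ps, pe, mean_depth, classes))
    fraction = covered / len(depth) if len(depth) else 0.0
    return islands, fraction


# ---------------------------------------------------------------------------
# expression


def expression_from_counts(name: str, length: int, n_reads: int,
                           background_norm: float | None = None) -> ExpressionReport:
    """Length-normalised count (and fold change against a background rate
    when one is supplied); the worked-example entry point when N and L are
    known."""
    if length <= 0:
        raise ValueError("region length must be positive")
    c = n_reads / length
    fold = None
    if background_norm is not None:
        fold = c / background_norm if background_norm > 0 else None
    return ExpressionReport(name, length, n_reads, c, fold)


def expression_fold(alignments: list[AlignmentRecord], region: Annotation,
                    background: Annotation
                    ) -> tuple[ExpressionReport, ExpressionReport]:
    """Fold change of a region against a background region.

    A read counts toward a region when its alignment start lies inside the
    region's interval (deduplicate alignments upstream). Returns (region
    report, background report); the background's fold is 1 by definition,
    or None when its read count is zero (fold undefined, flagged by None).
    """
    def count(a: Annotation) -> int:
        return sum(1 for r in alignments
                   if r.chrom == a.chrom and a.start <= r.pos < a.end)

    n_bg = count(background)
    bg = expression_from_counts(background.name, background.end - background.start,
                                n_bg)
    bg.fold = 1.0 if n_bg > 0 else None
    reg = expression_from_counts(region.name, region.end - region.start,
                                 count(region),
                                 background_norm=bg.normalized if n_bg else None)
    return reg, bg
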