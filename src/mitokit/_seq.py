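"""Low-level sequence primitives shared across modules.

All coordinates are 0-based half-open. Circular sequences are handled by
index arithmetic modulo length; the doubled-sequence trick used in several
modules lives here too.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_set(seq: str, k: int) -> set[str]:
    """Distinct canonical k-mers of ``seq`` (empty if seq shorter than k)."""
    return {canonical_kmer(seq[i : i + k]) for i in range(len(seq) - k + 1)}


def gc_fraction(seq: str) -> float:
    """GC over unambiguous bases only; raises on all-N / empty input."""
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / (gc + at)


def circular_slice(seq: str, start: int, length: int) -> str:
    """Substring of a circular sequence, wrapping the origin as needed."""
    n = len(seq)
    if length > n:
        raise ValueError("slice longer than the circle")
    start %= n
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def hamming_identity(a: str, b: str) -> float:
    """Fraction of identical positions; N never matches anything."""
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if not a:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return m / len(a)


def least_rotation(seq: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm, O(n))."""
    s = seq + seq
    n = len(seq)
    f = [-1] * len(s)
    k = 0
    for j in range(1, len(s)):
        sj = s[j]
        i = f[j - k - 1]
        while i != -1 and sj != s[k + i + 1]:
            if sj < s[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s[k + i + 1]:
            if sj < s[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s[k : k + n]


def canonical_circular(seq: str) -> str:
    """Orientation- and rotation-invariant representative of a circle.

    The lexicographic minimum over both strands' minimal rotations, so two
    assemblies of the same circle compare equal regardless of start point
    and strand.
    """
    return min(least_rotation(seq), least_rotation(revcomp(seq)))
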