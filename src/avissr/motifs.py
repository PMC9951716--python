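"""Repeat-motif normalization.

Microsatellite motifs that are circular permutations of one another, or of
each other's reverse complement, describe the same repeat array read from a
different phase or strand.  All counting in this package therefore happens on
*canonical* motifs: the lexicographically smallest string among the rotations
of a motif and the rotations of its reverse complement (so poly-T runs are
poly-A runs, (GA)n is (AG)n, and so on).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MAX_MOTIF_LEN = 6


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G; N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if *motif* is not a tandem repetition of a shorter unit.

    "AC" is primitive; "ACAC" is not (it is (AC)2).  Mononucleotides are
    always primitive.
    """
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def rotations(motif: str) -> list[str]:
    """All circular permutations of *motif* (including itself)."""
    return [motif[i:] + motif[:i] for i in range(len(motif))]


@lru_cache(maxsize=None)
def canonical_motif(motif: str) -> str:
    """Canonical representative of *motif*'s rotation/reverse-complement class.

    Parameters
    ----------
    motif
        A primitive repeat unit of length 1-6 over ``ACGT``.

    Returns
    -------
    str
        The lexicographically smallest string among all rotations of
        ``motif`` and all rotations of ``reverse_complement(motif)``.
        Idempotent, and invariant under rotation and reverse complementation
        of the input.

    Raises
    ------
    ValueError
        If the motif contains characters outside ACGT, is empty or longer
        than 6 bases, or is not primitive.
    """
    if not motif or len(motif) > MAX_MOTIF_LEN:
        raise ValueError(f"motif length must be 1-{MAX_MOTIF_LEN}, got {motif!r}")
    if any(b not in BASES for b in motif):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    return min(rotations(motif) + rotations(reverse_complement(motif)))


@lru_cache(maxsize=None)
def canonical_classes(k: int) -> tuple[str, ...]:
    """Sorted canonical representatives of all primitive k-mer classes."""
    if not 1 <= k <= MAX_MOTIF_LEN:
        raise ValueError(f"motif length must be 1-{MAX_MOTIF_LEN}, got {k}")
    reps = {
        canonical_motif("".join(p))
        for p in product(BASES, repeat=k)
        if is_primitive("".join(p))
    }
    return tuple(sorted(reps))


def motif_class_count(k: int) -> int:
    """Number of distinct canonical motif classes among primitive k-mers."""
    return len(canonical_classes(k))
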