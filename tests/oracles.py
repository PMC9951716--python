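"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package internals: the perfect-SSR
oracle is regex-based with explicit restart-rescan, the motif-class oracle
counts connected components of the rotation/reverse-complement graph, and
the region oracle labels loci by per-base majority from a minimal GFF3 line
parse.
"""

from __future__ import annotations

import re
from itertools import product

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _primitive(m: str) -> bool:
    return all(not (len(m) % d == 0 and m == m[:d] * (len(m) // d))
               for d in range(1, len(m)))


def regex_perfect_oracle(seq: str, min_repeats=(12, 7, 5, 4, 4, 4)):
    """All perfect SSR loci by regex scan with leftmost-longest restart.

    Returns (start, end, motif, repeats) tuples sorted by start.
    """
    seq = seq.upper()
    patterns = [
        (p, re.compile(r"([ACGT]{%d})\1{%d,}" % (p, min_repeats[p - 1] - 1)))
        for p in range(1, 7)
    ]
    loci = []
    offset = 0
    while True:
        best = None
        for p, pat in patterns:
            for m in pat.finditer(seq, offset):
                motif = m.group(1)
                if not _primitive(motif):
                    continue
                reps = (m.end() - m.start()) // p
                cand = (m.start(), -(reps * p), p, motif, reps)
                if best is None or cand[:3] < best[:3]:
                    best = cand
                break  # leftmost passing run for this period
        if best is None:
            break
        start, neglen, p, motif, reps = best
        loci.append((start, start - neglen, motif, reps))
        offset = start - neglen
    return loci


def class_count_oracle(k: int) -> int:
    """Canonical motif classes for length k, via graph connected components."""
    kmers = ["".join(p) for p in product("ACGT", repeat=k) if
             _primitive("".join(p))]
    index = {m: i for i, m in enumerate(kmers)}
    parent = list(range(len(kmers)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for m in kmers:
        union(index[m], index[m[1:] + m[0]])
        union(index[m], index[_revcomp(m)])
    return len({find(i) for i in range(len(kmers))})


def per_base_region_oracle(gff3_path, seq_lengths):
    """Per-base region labels (0=intergenic,1=intron,2=exon,3=CDS) per seq.

    Introns are gene spans minus exons; precedence is encoded by the label
    ordering (higher wins).
    """
    arrays = {sid: np.zeros(n, dtype=np.int8) for sid, n in
              seq_lengths.items()}
    genes, exons, cds = [], [], []
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            sid, ftype, start, end = f[0], f[2], int(f[3]) - 1, int(f[4])
            if ftype == "gene":
                genes.append((sid, start, end))
            elif ftype == "exon":
                exons.append((sid, start, end))
            elif ftype == "CDS":
                cds.append((sid, start, end))
    for sid, s, e in genes:
        arrays[sid][s:e] = np.maximum(arrays[sid][s:e], 1)
    for sid, s, e in exons:
        arrays[sid][s:e] = np.maximum(arrays[sid][s:e], 2)
    for sid, s, e in cds:
        arrays[sid][s:e] = np.maximum(arrays[sid][s:e], 3)
    return arrays


ORACLE_LABELS = {0: "intergenic", 1: "intron", 2: "exon", 3: "CDS"}


def majority_region(arrays, seq_id, start, end) -> str:
    counts = np.bincount(arrays[seq_id][start:end], minlength=4)
    return ORACLE_LABELS[int(np.argmax(counts))]


def repeat_rich_sequence(rng: np.random.Generator, length: int,
                         n_runs: int = 8) -> str:
    """Random background with planted near-threshold repeat runs.

    Runs are drawn around the detection thresholds (some below, some above,
    some with non-primitive units or N interruptions) to exercise every
    boundary of the scanner.
    """
    thresholds = (12, 7, 5, 4, 4, 4)
    parts = []
    total = 0
    while total < length:
        parts.append("".join(rng.choice(list("ACGT"),
                                        size=int(rng.integers(40, 200)))))
        total += len(parts[-1])
        if len(parts) % 2 and n_runs > 0:
            k = int(rng.integers(1, 7))
            motif = "".join(rng.choice(list("ACGT"), size=k))
            reps = thresholds[k - 1] + int(rng.integers(-3, 5))
            run = motif * max(reps, 1)
            if rng.random() < 0.1:
                run = run[:len(run) // 2] + "N" + run[len(run) // 2:]
            parts.append(run)
            total += len(run)
            n_runs -= 1
    return "".join(parts)[:length]
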