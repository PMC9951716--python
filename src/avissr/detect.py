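"""Microsatellite detection.

Three locus classes are reported, following the standard trichotomy of
genome-wide SSR surveys:

* **perfect** (P-SSR): an uninterrupted tandem array of a primitive 1-6 bp
  motif with at least 12/7/5/4/4/4 copies for mono- through hexanucleotide
  units respectively;
* **imperfect** (I-SSR): a repeat array disrupted by substitutions or short
  indels, found by seed-and-extend from a sub-threshold pure run;
* **compound** (C-SSR): two or more perfect arrays separated by short
  (default <= 10 bp) spacers, merged into one genomic locus.

Coordinates are 0-based half-open internally; TSV/BED exports state their
convention in the header.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motifs import canonical_motif, is_primitive

_VALID = frozenset("ACGTN")
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class DetectorParams:
    """Tunable thresholds of the detector.

    ``min_repeats[k-1]`` is the minimum copy number for a perfect array of a
    k-nucleotide motif; the defaults (12, 7, 5, 4, 4, 4) are the standard
    survey thresholds for mono- through hexanucleotide repeats.  Imperfect
    search uses a seed-and-extend scheme: a pure run with at least
    ``seed_min_repeats`` copies and ``seed_min_length`` bases is extended
    outward, scoring +1 per matching base, -``mismatch_penalty`` per
    substitution and -``gap_penalty`` per indel base, stopping after more
    than ``max_consecutive_edits`` consecutive edited positions; the locus is
    reported when the total score reaches ``min_score`` and at least one edit
    occurred.  ``compound_max_gap`` is the largest spacer joining adjacent
    perfect arrays into a compound locus.
    """

    min_repeats: tuple[int, ...] = (12, 7, 5, 4, 4, 4)
    compound_max_gap: int = 10
    seed_min_repeats: int = 3
    seed_min_length: int = 8
    max_consecutive_edits: int = 3
    mismatch_penalty: int = 1
    gap_penalty: int = 2
    min_score: int = 10

    def __post_init__(self) -> None:
        if len(self.min_repeats) != 6:
            raise ValueError("min_repeats needs one threshold per motif length 1-6")
        ints = (*self.min_repeats, self.compound_max_gap, self.seed_min_repeats,
                self.seed_min_length, self.max_consecutive_edits,
                self.mismatch_penalty, self.gap_penalty, self.min_score)
        if any(int(v) != v or v <= 0 for v in ints):
            raise ValueError("all detector thresholds must be positive integers")

    def min_length(self, motif_len: int) -> int:
        """Minimum perfect-locus length in bases for a motif of this length."""
        return motif_len * self.min_repeats[motif_len - 1]


@dataclass
class SSRLocus:
    """One detected repeat locus (0-based half-open coordinates).

    ``repeats`` is the repeat copy number (RCN): for perfect loci it is
    exactly ``(end - start) / motif_len``; for imperfect loci the copy
    number of the underlying array estimated as ``round(length / motif_len)``;
    for compound loci the summed RCN of the members.
    """

    seq_id: str
    start: int
    end: int
    ssr_type: str  # "perfect" | "imperfect" | "compound"
    motif: str
    canonical: str
    repeats: int
    score: int | None = None
    n_edits: int | None = None
    members: tuple["SSRLocus", ...] = ()
    in_compound: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus end must exceed start ({self.start}, {self.end})")

    @property
    def motif_len(self) -> int:
        # compound motifs are joined with "+"; use the first member's unit
        return len(self.members[0].motif) if self.members else len(self.motif)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        pos = next(i for i, b in enumerate(seq) if b in bad)
        raise ValueError(
            f"invalid character {seq[pos]!r} at position {pos}; expected A/C/G/T/N"
        )
    return seq


def _true_runs(mask: np.ndarray) -> np.ndarray:
    """Start/end (half-open) pairs of maximal True runs in a boolean array."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate(([0], mask.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return edges.reshape(-1, 2)


def _period_candidates(seq: str, arr: np.ndarray, valid: np.ndarray,
                       min_repeats_for, max_period: int = 6):
    """Maximal tandem runs per period, as (start, period, char_end, repeats).

    A period-p candidate covers the maximal stretch where ``seq[j] ==
    seq[j-p]``; its locus spans whole motif copies only (partial trailing
    copies are truncated).  Non-primitive motifs are skipped -- such runs are
    found at their shortest period instead.
    """
    n = arr.size
    out = []
    for p in range(1, max_period + 1):
        if n <= p:
            break
        thr = min_repeats_for(p)
        eq = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
        for s, e in _true_runs(eq):
            char_len = e - s + p
            repeats = char_len // p
            if repeats < thr:
                continue
            motif = seq[s:s + p]
            if is_primitive(motif):
                out.append((int(s), p, int(e) + p, int(repeats)))
    return out


def find_perfect_ssrs(
    sequence: str,
    params: DetectorParams | None = None,
    seq_id: str = "seq",
) -> list[SSRLocus]:
    """All maximal perfect SSR loci in *sequence*, sorted by start.

    A locus is a maximal tandem array of a primitive 1-6 bp motif with at
    least ``params.min_repeats`` copies; runs containing N are broken at the
    N.  Runs reportable under several motif lengths are reported at the
    shortest primitive period, and overlaps between maximal runs of different
    periods are resolved leftmost-longest, the loser being re-evaluated on
    the remaining suffix.  Reported loci never share a base.
    """
    params = params or DetectorParams()
    seq = _validate_sequence(sequence)
    if not seq:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, _BASE_CODES)

    # heap key: (start, -locus_length, period) => leftmost, longest, shortest unit
    heap = []
    for s, p, char_end, repeats in _period_candidates(
        seq, arr, valid, lambda p: params.min_repeats[p - 1]
    ):
        heapq.heappush(heap, (s, -(repeats * p), p, char_end))

    loci: list[SSRLocus] = []
    frontier = 0
    while heap:
        s, neglen, p, char_end = heapq.heappop(heap)
        if s < frontier:
            # overlap with an accepted locus: rescan the suffix of this run
            s2 = frontier
            repeats = (char_end - s2) // p
            if repeats >= params.min_repeats[p - 1]:
                motif = seq[s2:s2 + p]
                if is_primitive(motif):
                    heapq.heappush(heap, (s2, -(repeats * p), p, char_end))
            continue
        length = -neglen
        motif = seq[s:s + p]
        loci.append(SSRLocus(
            seq_id=seq_id, start=s, end=s + length, ssr_type="perfect",
            motif=motif, canonical=canonical_motif(motif), repeats=length // p,
        ))
        frontier = s + length
    return loci


# ---------------------------------------------------------------------------
# imperfect (seed-and-extend)
# ---------------------------------------------------------------------------

def _extend(seq, start_pos, phase0, motif, params, direction):
    """Greedy scored extension from one seed boundary.

    Returns (best_pos, best_score, best_edits): the extension boundary
    (exclusive for +1, inclusive-start for -1) trimmed back to the
    maximal-score position, which is always a matching base.
    """
    p = len(motif)
    n = len(seq)
    j = start_pos
    phase = phase0
    score = 0
    edits = 0
    consec = 0
    best = (start_pos, 0, 0)

    def expected(ph):
        return motif[ph % p]

    def looks_ahead(jj, ph, k=3):
        """Matches among the next k sequence positions under phase ph."""
        cnt = 0
        for t in range(k):
            idx = jj + t * direction
            if not (0 <= idx < n):
                break
            if seq[idx] == expected(ph + t * direction):
                cnt += 1
            else:
                break
        return cnt

    while 0 <= j < n if direction > 0 else j - 1 >= 0:
        idx = j if direction > 0 else j - 1
        if not (0 <= idx < n):
            break
        base = seq[idx]
        if base == expected(phase):
            score += 1
            j += direction
            phase += direction
            consec = 0
            if score > best[1]:
                best = (j, score, edits)
            continue
        # classify the edit by a short lookahead under each hypothesis
        sub = looks_ahead(idx + direction, phase + direction)
        dele = looks_ahead(idx, phase + direction)
        ins = looks_ahead(idx + direction, phase)
        choice = max((("sub", sub), ("del", dele), ("ins", ins)),
                     key=lambda kv: kv[1])[0]
        if choice == "sub":
            score -= params.mismatch_penalty
            j += direction
            phase += direction
        elif choice == "del":
            score -= params.gap_penalty
            phase += direction
        else:  # insertion in the sequence relative to the array
            score -= params.gap_penalty
            j += direction
        edits += 1
        consec += 1
        if consec > params.max_consecutive_edits:
            break
    return best


def find_imperfect_ssrs(
    sequence: str,
    perfect_loci: Sequence[SSRLocus] | None = None,
    params: DetectorParams | None = None,
    seq_id: str = "seq",
) -> list[SSRLocus]:
    """Imperfect SSR loci by seed-and-extend, sorted by start.

    Seeds are maximal pure runs with >= ``seed_min_repeats`` copies and
    >= ``seed_min_length`` bases (above-threshold perfect runs included:
    a perfect array flanked by near-copies yields an imperfect locus too).
    A locus is reported when its score reaches ``min_score`` and at least
    one edit occurred; edit-free runs are the province of
    :func:`find_perfect_ssrs` (*perfect_loci*, when given, is only used for
    that bookkeeping contract and not re-derived here).  Overlapping
    extensions are deduplicated keeping the best-scoring (then longest,
    then leftmost) locus.
    """
    params = params or DetectorParams()
    seq = _validate_sequence(sequence)
    if not seq:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, _BASE_CODES)

    def seed_thr(p):
        return max(params.seed_min_repeats, -(-params.seed_min_length // p))

    raw: list[tuple[int, int, int, int, int]] = []  # (start,end,score,edits,p)
    for s, p, char_end, repeats in _period_candidates(seq, arr, valid, seed_thr):
        seed_len = repeats * p
        motif = seq[s:s + p]
        # phase -1: the base left of the seed should be the motif's last char
        left = _extend(seq, s, -1, motif, params, direction=-1)
        right = _extend(seq, s + seed_len, seed_len, motif, params, direction=+1)
        start = left[0]
        end = right[0]
        score = seed_len + left[1] + right[1]
        edits = left[2] + right[2]
        if edits >= 1 and score >= params.min_score:
            raw.append((start, end, score, edits, p))

    # deduplicate overlapping calls: best score, then longest, then leftmost
    raw.sort(key=lambda r: (-r[2], -(r[1] - r[0]), r[0], r[4]))
    accepted: list[tuple[int, int, int, int, int]] = []
    for cand in raw:
        if all(cand[1] <= a[0] or cand[0] >= a[1] for a in accepted):
            accepted.append(cand)
    accepted.sort()

    loci = []
    for start, end, score, edits, p in accepted:
        motif = seq[start:start + p]
        if not is_primitive(motif):  # pragma: no cover - seeds are primitive
            continue
        loci.append(SSRLocus(
            seq_id=seq_id, start=start, end=end, ssr_type="imperfect",
            motif=motif, canonical=canonical_motif(motif),
            repeats=max(1, round((end - start) / p)),
            score=score, n_edits=edits,
        ))
    return loci


def find_compound_ssrs(
    perfect_loci: Sequence[SSRLocus],
    params: DetectorParams | None = None,
) -> list[SSRLocus]:
    """Merge chains of nearby perfect loci into compound loci.

    Maximal chains of >= 2 perfect loci on one sequence, each adjacent pair
    separated by <= ``compound_max_gap`` bases, become a single compound
    locus spanning the chain.  Member loci are kept in ``members`` and
    flagged ``in_compound=True`` in place, so per-genome type proportions
    can count each genomic locus once.
    """
    params = params or DetectorParams()
    by_seq: dict[str, list[SSRLocus]] = {}
    for loc in perfect_loci:
        by_seq.setdefault(loc.seq_id, []).append(loc)

    compounds = []
    for seq_id, loci in by_seq.items():
        loci = sorted(loci, key=lambda l: l.start)
        chain = [loci[0]] if loci else []
        for loc in loci[1:]:
            if loc.start - chain[-1].end <= params.compound_max_gap:
                chain.append(loc)
            else:
                if len(chain) >= 2:
                    compounds.append(_make_compound(chain))
                chain = [loc]
        if len(chain) >= 2:
            compounds.append(_make_compound(chain))
    return sorted(compounds, key=lambda l: (l.seq_id, l.start))


def _make_compound(chain: list[SSRLocus]) -> SSRLocus:
    for member in chain:
        member.in_compound = True
    return SSRLocus(
        seq_id=chain[0].seq_id,
        start=chain[0].start,
        end=chain[-1].end,
        ssr_type="compound",
        motif="+".join(m.motif for m in chain),
        canonical="+".join(m.canonical for m in chain),
        repeats=sum(m.repeats for m in chain),
        members=tuple(chain),
    )


def shadowed_by_compound(locus: SSRLocus, compounds: Sequence[SSRLocus]) -> bool:
    """True if an imperfect call mostly lies within a compound locus span.

    A seed inside one member of a compound locus can extend across the
    spacer into the next member, re-describing the same genomic locus as a
    single interrupted array (possibly grabbing a flanking base or two).
    Calls with at least half their span inside a compound locus are
    suppressed so each genomic locus is reported once.
    """
    for c in compounds:
        if c.seq_id != locus.seq_id:
            continue
        overlap = min(locus.end, c.end) - max(locus.start, c.start)
        if 2 * overlap >= locus.length_bp:
            return True
    return False


def detect_all(
    sequence: str,
    params: DetectorParams | None = None,
    seq_id: str = "seq",
) -> list[SSRLocus]:
    """Run perfect, compound and imperfect detection on one sequence.

    Returns all loci sorted by (start, type); perfect members of compound
    loci carry ``in_compound=True``, and imperfect calls contained within a
    compound span are dropped (see :func:`shadowed_by_compound`).
    """
    params = params or DetectorParams()
    perfect = find_perfect_ssrs(sequence, params, seq_id=seq_id)
    compound = find_compound_ssrs(perfect, params)
    imperfect = [
        l for l in find_imperfect_ssrs(sequence, perfect, params, seq_id=seq_id)
        if not shadowed_by_compound(l, compound)
    ]
    return sorted(perfect + compound + imperfect,
                  key=lambda l: (l.start, l.ssr_type))


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["seq_id", "start_1based", "end", "ssr_type", "motif",
               "canonical_motif", "motif_len", "repeats", "length_bp",
               "score", "n_edits", "in_compound"]


def loci_to_frame(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """Loci as a DataFrame with 1-based inclusive coordinates (TSV surface)."""
    rows = [
        (l.seq_id, l.start + 1, l.end, l.ssr_type, l.motif, l.canonical,
         l.motif_len, l.repeats, l.length_bp, l.score, l.n_edits,
         l.in_compound)
        for l in loci
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def frame_to_loci(frame: pd.DataFrame) -> list[SSRLocus]:
    """Inverse of :func:`loci_to_frame` (members of compounds are not rebuilt)."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(SSRLocus(
            seq_id=row.seq_id, start=int(row.start_1based) - 1, end=int(row.end),
            ssr_type=row.ssr_type, motif=row.motif, canonical=row.canonical_motif,
            repeats=int(row.repeats),
            score=None if pd.isna(row.score) else int(row.score),
            n_edits=None if pd.isna(row.n_edits) else int(row.n_edits),
            in_compound=bool(row.in_compound),
        ))
    return out


def write_loci_tsv(loci: Iterable[SSRLocus], path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path) -> list[SSRLocus]:
    return frame_to_loci(pd.read_csv(path, sep="\t"))


def write_bed6(loci: Iterable[SSRLocus], path) -> None:
    """BED6 export (0-based half-open; name=canonical motif, score=RCN)."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.seq_id}\t{l.start}\t{l.end}\t"
                     f"{l.canonical}\t{l.repeats}\t+\n")
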