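"""Synthetic genomes with planted microsatellites and known ground truth.

The generator emits FASTA + GFF3 + a truth table so every downstream stage
(detection, region assignment, statistics, phylogenetic PCA) can be tested
without external genome downloads.  Its guarantees:

* every planted locus appears verbatim at its stated coordinates;
* the non-repetitive background is rejection-sampled so it contains no run
  the perfect-SSR thresholds would report, and no spurious imperfect call;
* planted loci are separated by at least ``min_spacing`` (default 20 bp) of
  background so compound merging never occurs unless requested;
* identical seeds give byte-identical outputs.

Flanking bases of each planted array are constrained so the array cannot be
extended by the detector (the truth table is exact, not approximate), and
the remaining background is re-drawn wherever a scan still finds an
unplanted locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import (DetectorParams, find_compound_ssrs, find_imperfect_ssrs,
                     find_perfect_ssrs)
from .motifs import BASES, canonical_motif, is_primitive

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ["seq_id", "start", "end", "ssr_type", "motif",
                 "canonical_motif", "repeats", "region_label"]

_GUARD = 4            # flanking bases fixed to block array extension
_MIN_EDIT_MARGIN = 3  # unedited bases required at each end of an imperfect array
_MIN_EDIT_SEP = 4     # minimum spacing between edits of one imperfect array


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class PlantSpec:
    """One microsatellite to plant.

    ``position`` is the 0-based start of the construct.  For imperfect
    plants, ``edits`` disrupt the perfect array ``motif * repeats``: each is
    ``("sub", offset, base)``, ``("ins", offset, base)`` (base inserted
    before *offset*) or ``("del", offset)``, with offsets in the coordinates
    of the unedited array.  For compound plants, a second perfect array
    ``second_motif * second_repeats`` follows after ``gap`` background bases.
    """

    seq_id: str
    position: int
    ssr_type: str  # "perfect" | "imperfect" | "compound"
    motif: str
    repeats: int
    edits: tuple = ()
    gap: int | None = None
    second_motif: str | None = None
    second_repeats: int | None = None

    def validate(self, params: DetectorParams) -> None:
        if self.ssr_type not in ("perfect", "imperfect", "compound"):
            raise ValueError(f"unknown ssr_type {self.ssr_type!r}")
        _check_motif(self.motif)
        p = len(self.motif)
        if self.ssr_type == "perfect":
            if self.repeats < params.min_repeats[p - 1]:
                raise ValueError(
                    f"perfect plant {self.motif}x{self.repeats} below the "
                    f"class threshold {params.min_repeats[p - 1]}")
        elif self.ssr_type == "imperfect":
            self._validate_edits(params)
        else:
            if self.second_motif is None or self.second_repeats is None \
                    or self.gap is None:
                raise ValueError("compound plant needs gap and second motif")
            _check_motif(self.second_motif)
            q = len(self.second_motif)
            if self.repeats < params.min_repeats[p - 1] \
                    or self.second_repeats < params.min_repeats[q - 1]:
                raise ValueError("compound members must each meet the "
                                 "perfect-SSR threshold")
            if not 4 <= self.gap <= params.compound_max_gap:
                raise ValueError(
                    f"compound gap must be in [4, {params.compound_max_gap}] "
                    f"so the members stay separable, got {self.gap}")

    def _validate_edits(self, params: DetectorParams) -> None:
        p = len(self.motif)
        L = p * self.repeats
        if not self.edits:
            raise ValueError("imperfect plant needs at least one edit")
        offsets = []
        for e in self.edits:
            op = e[0]
            off = e[1]
            if op not in ("sub", "ins", "del"):
                raise ValueError(f"unknown edit op {op!r}")
            if op == "del" and p == 1:
                raise ValueError("a deletion in a mononucleotide array is "
                                 "invisible; use a substitution")
            if not _MIN_EDIT_MARGIN <= off <= L - 1 - _MIN_EDIT_MARGIN:
                raise ValueError(f"edit offset {off} too close to array ends")
            if op in ("sub", "ins"):
                base = e[2]
                if base not in BASES:
                    raise ValueError(f"edit base {base!r} not in ACGT")
                if base == self.motif[off % p]:
                    raise ValueError(
                        f"{op} of {base} at offset {off} does not disrupt "
                        f"the array")
            offsets.append(off)
        if sorted(offsets) != offsets or len(set(offsets)) != len(offsets):
            raise ValueError("edit offsets must be strictly increasing")
        if any(b - a < _MIN_EDIT_SEP for a, b in zip(offsets, offsets[1:])):
            raise ValueError(f"edits must be >= {_MIN_EDIT_SEP} bases apart")
        # no unedited segment may itself pass the perfect threshold
        bounds = [-1] + offsets + [L]
        segments = [b - a - 1 for a, b in zip(bounds, bounds[1:])]
        max_len = params.min_length(p) - 1
        if any(s > max_len for s in segments):
            raise ValueError(
                "an unedited segment of the imperfect array would itself be "
                f"a perfect locus (max allowed {max_len} bases)")
        seed_len = max(params.seed_min_length, params.seed_min_repeats * p)
        if max(segments) < seed_len:
            raise ValueError(
                f"imperfect array needs one pure segment of >= {seed_len} "
                "bases to be detectable")

    def build(self) -> "_Construct":
        """Render the plant into sequence text plus flank constraints."""
        p = len(self.motif)
        if self.ssr_type in ("perfect", "imperfect"):
            chars = list(self.motif * self.repeats)
            phases = list(np.arange(len(chars)) % p)
            for e in sorted(self.edits, key=lambda e: -e[1]):
                if e[0] == "sub":
                    chars[e[1]] = e[2]
                elif e[0] == "ins":
                    chars.insert(e[1], e[2])
                    phases.insert(e[1], phases[e[1]])
                else:
                    del chars[e[1]]
                    del phases[e[1]]
            text = "".join(chars)
            return _Construct(self, [(_SegmentRole.ARRAY, text)],
                              motif_left=self.motif,
                              motif_right=self.motif,
                              phase_right=int(phases[-1]))
        first = self.motif * self.repeats
        second = self.second_motif * self.second_repeats
        return _Construct(self, [(_SegmentRole.ARRAY, first),
                                 (_SegmentRole.GAP, self.gap),
                                 (_SegmentRole.ARRAY, second)],
                          motif_left=self.motif,
                          motif_right=self.second_motif,
                          phase_right=len(self.second_motif) - 1)


class _SegmentRole:
    ARRAY = "array"
    GAP = "gap"


@dataclass
class _Construct:
    plant: PlantSpec
    parts: list          # (role, text | gap length)
    motif_left: str      # unit at the 5' boundary of the construct
    motif_right: str     # unit at the 3' boundary
    phase_right: int     # motif index of the construct's last base

    @property
    def length(self) -> int:
        return sum(len(t) if r == _SegmentRole.ARRAY else t
                   for r, t in self.parts)


@dataclass
class GeneSpec:
    """A gene model: ordered exons and CDS intervals, 0-based half-open."""

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def validate(self, seq_length: int) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        for (s, e) in self.exons:
            if not 0 <= s < e <= seq_length:
                raise ValueError(f"gene {self.gene_id}: exon {s}-{e} out of "
                                 "bounds")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: exons must be "
                                 "ordered and non-overlapping")
        for (s, e) in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"gene {self.gene_id}: CDS {s}-{e} not "
                                 "contained in an exon")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]


@dataclass
class GenomeSpec:
    """Full description of one synthetic genome."""

    n_sequences: int
    seq_length: int
    background_gc: float = 0.42
    plants: list[PlantSpec] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)
    rng_seed: int = 0
    detector_params: DetectorParams = field(default_factory=DetectorParams)
    min_spacing: int = 20

    def seq_ids(self) -> list[str]:
        return [f"seq{i + 1}" for i in range(self.n_sequences)]

    def validate(self) -> None:
        if self.n_sequences < 1 or self.seq_length < 100:
            raise ValueError("need >= 1 sequence of >= 100 bp")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")
        ids = set(self.seq_ids())
        for g in self.genes:
            if g.seq_id not in ids:
                raise ValueError(f"gene {g.gene_id}: unknown seq {g.seq_id}")
            g.validate(self.seq_length)
        placed: dict[str, list[tuple[int, int, PlantSpec]]] = {}
        for plant in self.plants:
            if plant.seq_id not in ids:
                raise ValueError(f"plant at {plant.position}: unknown seq "
                                 f"{plant.seq_id}")
            plant.validate(self.detector_params)
            length = plant.build().length
            lo, hi = plant.position, plant.position + length
            if lo < _GUARD or hi > self.seq_length - _GUARD:
                raise ValueError(
                    f"plant {plant.motif} at {plant.seq_id}:{lo} does not fit "
                    "within sequence bounds (guard flanks included)")
            placed.setdefault(plant.seq_id, []).append((lo, hi, plant))
        for seq_id, spans in placed.items():
            spans.sort()
            for (l1, h1, p1), (l2, h2, p2) in zip(spans, spans[1:]):
                if l2 - h1 < self.min_spacing:
                    raise ValueError(
                        f"planted loci overlap or are closer than "
                        f"{self.min_spacing} bp on {seq_id}: "
                        f"{p1.motif} at {l1}-{h1} vs {p2.motif} at {l2}-{h2}")


def _check_motif(motif: str) -> None:
    if not motif or len(motif) > 6 or any(b not in BASES for b in motif):
        raise ValueError(f"motif must be 1-6 bases over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    """In-memory result of :func:`generate_genome`."""

    spec: GenomeSpec
    sequences: dict[str, str]
    truth: pd.DataFrame

    def write(self, out_dir) -> tuple[Path, Path, Path]:
        """Write genome.fa / genome.gff3 / truth.tsv; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "genome.fa"
        gff = out / "genome.gff3"
        truth = out / "truth.tsv"
        records = [SeqRecord(Seq(s), id=sid, description="")
                   for sid, s in self.sequences.items()]
        with open(fasta, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        write_gff3(self.spec.genes, gff)
        # truth coordinates are 0-based half-open (BED-like)
        self.truth.to_csv(truth, sep="\t", index=False)
        return fasta, gff, truth


def _gc_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _draw_base(rng, gc: float, forbidden=frozenset()) -> str:
    allowed = [b for b in BASES if b not in forbidden]
    if not allowed:
        raise RuntimeError("no base satisfies the flank constraints")
    w = np.array([_gc_probs(gc)["ACGT".index(b)] for b in allowed])
    if w.sum() == 0:
        w = np.ones(len(allowed))
    return allowed[int(rng.choice(len(allowed), p=w / w.sum()))]


def _flank_constraints(construct: _Construct, start: int) -> dict[int, frozenset]:
    """Disallowed bases around one construct so the detector cannot extend it.

    Each guard base excludes the characters that would continue the repeat
    array under a straight, one-base-inserted or one-base-deleted alignment;
    compound gap bases additionally exclude the straight continuations from
    both flanking members.
    """
    cons: dict[int, set] = {}
    ml, mr = construct.motif_left, construct.motif_right
    pl, pr = len(ml), len(mr)

    def left_expected(i):   # i bases left of the construct start
        return ml[(-i) % pl]

    def right_expected(i):  # i bases right of the construct end
        return mr[(construct.phase_right + i) % pr]

    end = start + construct.length
    for i in range(1, _GUARD + 1):
        pos = start - i
        full = {left_expected(i - 1), left_expected(i), left_expected(i + 1)}
        cons.setdefault(pos, set()).update(
            full if len(full) < 4 else {left_expected(i)})
        pos = end + i - 1
        full = {right_expected(i - 1), right_expected(i), right_expected(i + 1)}
        cons.setdefault(pos, set()).update(
            full if len(full) < 4 else {right_expected(i)})

    # compound gap: block continuation from the left member and
    # back-extension of the right member
    offset = start
    for idx, (role, item) in enumerate(construct.parts):
        if role == _SegmentRole.ARRAY:
            offset += len(item)
            continue
        gap = item
        left_arr = construct.parts[idx - 1][1]
        right_arr = construct.parts[idx + 1][1]
        lm = construct.plant.motif
        rm = construct.plant.second_motif
        lphase = (len(left_arr) - 1) % len(lm)
        for i in range(1, gap + 1):
            pos = offset + i - 1
            d = gap - i + 1  # distance to the right member's start
            excl = {lm[(lphase + i) % len(lm)],
                    lm[(lphase + i - 1) % len(lm)],
                    lm[(lphase + i + 1) % len(lm)],
                    rm[(-d) % len(rm)]}
            if len(excl) == 4:
                excl = {lm[(lphase + i) % len(lm)], rm[(-d) % len(rm)]}
            cons.setdefault(pos, set()).update(excl)
        offset += gap
    return {k: frozenset(v) for k, v in cons.items()}


def _truth_rows(spec: GenomeSpec):
    """Expected loci per plant: truth-table rows + allowed detection spans."""
    rows = []
    allowed_perfect: dict[str, set] = {}
    allowed_imperfect: dict[str, set] = {}
    compound_spans: dict[str, list] = {}
    for plant in spec.plants:
        construct = plant.build()
        start, end = plant.position, plant.position + construct.length
        p = len(plant.motif)
        if plant.ssr_type == "perfect":
            repeats = plant.repeats
            allowed_perfect.setdefault(plant.seq_id, set()).add((start, end))
        elif plant.ssr_type == "imperfect":
            repeats = max(1, round((end - start) / p))
            allowed_imperfect.setdefault(plant.seq_id, set()).add((start, end))
        else:
            repeats = plant.repeats + plant.second_repeats
            m1 = (start, start + p * plant.repeats)
            m2 = (end - len(plant.second_motif) * plant.second_repeats, end)
            allowed_perfect.setdefault(plant.seq_id, set()).update([m1, m2])
            compound_spans.setdefault(plant.seq_id, []).append((start, end))
        canonical = canonical_motif(plant.motif)
        if plant.ssr_type == "compound":
            canonical = canonical + "+" + canonical_motif(plant.second_motif)
            motif = plant.motif + "+" + plant.second_motif
        else:
            motif = plant.motif
        rows.append({
            "seq_id": plant.seq_id, "start": start, "end": end,
            "ssr_type": plant.ssr_type, "motif": motif,
            "canonical_motif": canonical, "repeats": repeats,
            "region_label": _region_of(spec, plant.seq_id, (start + end) // 2),
        })
    return rows, allowed_perfect, allowed_imperfect, compound_spans


def _region_of(spec: GenomeSpec, seq_id: str, point: int) -> str:
    """Midpoint region label computed directly from the gene specs."""
    label = "intergenic"
    for g in spec.genes:
        if g.seq_id != seq_id:
            continue
        if any(s <= point < e for s, e in g.cds):
            return "CDS"
        if any(s <= point < e for s, e in g.exons):
            label = "exon_noncoding"
        elif label == "intergenic" and any(s <= point < e
                                           for s, e in g.introns):
            label = "intron"
    return label


def generate_genome(spec: GenomeSpec, out_dir=None) -> SyntheticGenome:
    """Generate a synthetic genome per *spec*.

    Deterministic for a fixed ``spec.rng_seed``.  Raises on overlapping or
    non-primitive plants (see :meth:`GenomeSpec.validate`), and RuntimeError
    if the background cannot be cleaned of spurious loci (which indicates an
    inconsistent spec, not bad luck -- the rejection loop is generous).
    When *out_dir* is given, FASTA/GFF3/truth TSV files are written there.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    params = spec.detector_params
    rows, allowed_perfect, allowed_imperfect, compound_spans = _truth_rows(spec)

    sequences: dict[str, str] = {}
    for seq_id in spec.seq_ids():
        plants = [p for p in spec.plants if p.seq_id == seq_id]
        constructs = [(p.position, p.build()) for p in plants]
        fixed = np.zeros(spec.seq_length, dtype=bool)
        chars = rng.choice(list(BASES), size=spec.seq_length,
                           p=_gc_probs(spec.background_gc)).tolist()
        constraints: dict[int, frozenset] = {}
        for pos, construct in constructs:
            offset = pos
            for role, item in construct.parts:
                if role == _SegmentRole.ARRAY:
                    for i, ch in enumerate(item):
                        chars[offset + i] = ch
                        fixed[offset + i] = True
                    offset += len(item)
                else:
                    offset += item
            for cpos, excl in _flank_constraints(construct, pos).items():
                if 0 <= cpos < spec.seq_length:
                    constraints[cpos] = excl
        for cpos, excl in constraints.items():
            if chars[cpos] in excl:
                chars[cpos] = _draw_base(rng, spec.background_gc, excl)

        ok_p = allowed_perfect.get(seq_id, set())
        ok_i = allowed_imperfect.get(seq_id, set())
        ok_c = compound_spans.get(seq_id, [])
        for _round in range(60):
            seq = "".join(chars)
            spurious = []
            for loc in find_perfect_ssrs(seq, params, seq_id=seq_id):
                if (loc.start, loc.end) not in ok_p:
                    spurious.append(loc)
            for loc in find_imperfect_ssrs(seq, params=params, seq_id=seq_id):
                if (loc.start, loc.end) in ok_i:
                    continue
                # calls mostly inside a compound span are suppressed by
                # detect_all (same rule as shadowed_by_compound)
                if any(2 * (min(loc.end, e) - max(loc.start, s))
                       >= loc.length_bp for s, e in ok_c):
                    continue
                spurious.append(loc)
            if not spurious:
                break
            for loc in spurious:
                lo = max(0, loc.start - 3)
                hi = min(spec.seq_length, loc.end + 3)
                targets = [i for i in range(lo, hi) if not fixed[i]]
                if not targets:
                    raise RuntimeError(
                        f"spurious locus {loc.ssr_type} {loc.start}-{loc.end} "
                        f"on {seq_id} cannot be removed: no background bases "
                        "in its span (inconsistent plant layout)")
                for i in targets:
                    chars[i] = _draw_base(rng, spec.background_gc,
                                          constraints.get(i, frozenset()))
        else:
            raise RuntimeError(f"background rejection did not converge on "
                               f"{seq_id}")
        sequences[seq_id] = "".join(chars)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["seq_id", "start"]).reset_index(drop=True)
    genome = SyntheticGenome(spec=spec, sequences=sequences, truth=truth)
    if out_dir is not None:
        genome.write(out_dir)
    return genome


def write_gff3(genes, path) -> None:
    """GFF3 (1-based inclusive) with a gene -> mRNA -> exon/CDS hierarchy."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.seq_id, g.span[0])):
            s, e = g.span
            gid, tid = g.gene_id, f"{g.gene_id}.t1"
            fh.write(f"{g.seq_id}\tavissr\tgene\t{s + 1}\t{e}\t.\t"
                     f"{g.strand}\t.\tID={gid}\n")
            fh.write(f"{g.seq_id}\tavissr\tmRNA\t{s + 1}\t{e}\t.\t"
                     f"{g.strand}\t.\tID={tid};Parent={gid}\n")
            for i, (xs, xe) in enumerate(g.exons):
                fh.write(f"{g.seq_id}\tavissr\texon\t{xs + 1}\t{xe}\t.\t"
                         f"{g.strand}\t.\tID={tid}.exon{i + 1};Parent={tid}\n")
            cds = g.cds if g.strand == "+" else list(reversed(g.cds))
            phase, cum = 0, 0
            for i, (cs, ce) in enumerate(cds):
                phase = (3 - cum % 3) % 3
                fh.write(f"{g.seq_id}\tavissr\tCDS\t{cs + 1}\t{ce}\t.\t"
                         f"{g.strand}\t{phase}\tID={tid}.cds{i + 1};"
                         f"Parent={tid}\n")
                cum += ce - cs


def read_truth_tsv(path) -> pd.DataFrame:
    """Read a truth table written by :meth:`SyntheticGenome.write`."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# randomized study designs
# ---------------------------------------------------------------------------

def _random_primitive_motif(rng, k: int) -> str:
    while True:
        m = "".join(rng.choice(list(BASES), size=k))
        if is_primitive(m):
            return m


def _random_plant(rng, params: DetectorParams, seq_id: str, position: int,
                  ssr_type: str) -> PlantSpec:
    """A randomized but always-valid plant of the requested type."""
    if ssr_type == "perfect":
        k = int(rng.integers(1, 7))
        motif = _random_primitive_motif(rng, k)
        repeats = params.min_repeats[k - 1] + int(rng.integers(0, 7))
        return PlantSpec(seq_id, position, "perfect", motif, repeats)
    if ssr_type == "imperfect":
        k = int(rng.integers(1, 4))
        motif = _random_primitive_motif(rng, k)
        # 30-base array with two interior disruptions splitting it into
        # pure segments of 8-10 bases: each detectable as a seed, none a
        # perfect locus on its own
        repeats = {1: 30, 2: 15, 3: 10}[k]
        L = k * repeats
        offsets = [int(rng.integers(9, 11)), L - 1 - int(rng.integers(9, 11))]
        edits = []
        for off in offsets:
            ops = ["sub"] if k == 1 else ["sub", "sub", "ins", "del"]
            op = ops[int(rng.integers(len(ops)))]
            if op == "del":
                edits.append(("del", off))
            else:
                avoid = motif[off % k]
                base = str(rng.choice([b for b in BASES if b != avoid]))
                edits.append((op, off, base))
        return PlantSpec(seq_id, position, "imperfect", motif, repeats,
                         edits=tuple(edits))
    k1, k2 = int(rng.integers(2, 4)), int(rng.integers(2, 4))
    m1 = _random_primitive_motif(rng, k1)
    m2 = _random_primitive_motif(rng, k2)
    return PlantSpec(
        seq_id, position, "compound", m1,
        params.min_repeats[k1 - 1] + int(rng.integers(0, 4)),
        gap=int(rng.integers(4, params.compound_max_gap + 1)),
        second_motif=m2,
        second_repeats=params.min_repeats[k2 - 1] + int(rng.integers(0, 4)),
    )


def _layout_genes(rng, seq_id: str, seq_length: int, n_genes: int,
                  start_index: int) -> list[GeneSpec]:
    """Evenly spaced multi-exon genes with UTR-bearing first/last exons."""
    genes = []
    slot = seq_length // max(n_genes, 1)
    for i in range(n_genes):
        n_exons = int(rng.integers(3, 6))
        pos = i * slot + int(rng.integers(200, 400))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(250, 450))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(400, 900))
        if exons[-1][1] > (i + 1) * slot - 100 or exons[-1][1] > seq_length:
            continue
        # CDS starts/ends mid-way through the terminal exons (UTR flanks)
        cds = [list(x) for x in exons]
        cds[0][0] = (exons[0][0] + exons[0][1]) // 2
        cds[-1][1] = (exons[-1][0] + exons[-1][1]) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneSpec(
            gene_id=f"gene{start_index + len(genes) + 1}", seq_id=seq_id,
            strand=strand, exons=exons, cds=[tuple(c) for c in cds]))
    return genes


def random_genome_spec(
    n_sequences: int = 2,
    seq_length: int = 60_000,
    background_gc: float = 0.42,
    n_perfect: int = 30,
    n_imperfect: int = 12,
    n_compound: int = 8,
    genes_per_seq: int = 4,
    rng_seed: int = 0,
    params: DetectorParams | None = None,
) -> GenomeSpec:
    """A randomized, always-valid genome spec spanning all locus classes.

    Plants are spread over CDS, non-coding exon, intron and intergenic
    compartments in rotation; defaults give 50 planted loci on 2 x 60 kb
    sequences with 42% background GC (the ballpark of an avian genome).
    """
    params = params or DetectorParams()
    rng = np.random.default_rng(rng_seed)
    seq_ids = [f"seq{i + 1}" for i in range(n_sequences)]

    genes: list[GeneSpec] = []
    for seq_id in seq_ids:
        genes.extend(_layout_genes(rng, seq_id, seq_length, genes_per_seq,
                                   start_index=len(genes)))

    # candidate placement intervals per compartment
    regions: dict[str, list[tuple[str, int, int]]] = {
        "CDS": [], "exon_noncoding": [], "intron": [], "intergenic": []}
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in seq_ids}
    for g in genes:
        for s, e in g.cds:
            regions["CDS"].append((g.seq_id, s, e))
        regions["exon_noncoding"].append((g.seq_id, g.exons[0][0],
                                          g.cds[0][0]))
        regions["exon_noncoding"].append((g.seq_id, g.cds[-1][1],
                                          g.exons[-1][1]))
        for s, e in g.introns:
            regions["intron"].append((g.seq_id, s, e))
        occupied[g.seq_id].append(g.span)
    for seq_id in seq_ids:
        spans = sorted(s for s in occupied[seq_id])
        prev = 0
        for s, e in spans + [(seq_length, seq_length)]:
            if s - prev > 400:
                regions["intergenic"].append((seq_id, prev + 50, s - 50))
            prev = max(prev, e)

    order = (["perfect"] * n_perfect + ["imperfect"] * n_imperfect
             + ["compound"] * n_compound)
    cycle = ["intergenic", "intron", "CDS", "exon_noncoding"]
    plants: list[PlantSpec] = []
    placed: dict[str, list[tuple[int, int]]] = {s: [] for s in seq_ids}
    spacing = 20
    for i, ssr_type in enumerate(order):
        target = cycle[i % len(cycle)]
        done = False
        for _attempt in range(400):
            pool = regions[target] or regions["intergenic"]
            seq_id, lo, hi = pool[int(rng.integers(len(pool)))]
            plant = _random_plant(rng, params, seq_id,
                                  position=0, ssr_type=ssr_type)
            length = plant.build().length
            if hi - lo < length + 2 * _GUARD + 2:
                continue
            pos = int(rng.integers(lo + _GUARD, hi - length - _GUARD))
            if any(pos - spacing < e and s < pos + length + spacing
                   for s, e in placed[seq_id]):
                continue
            plant.position = pos
            plants.append(plant)
            placed[seq_id].append((pos, pos + length))
            done = True
            break
        if not done:
            raise RuntimeError(
                f"could not place a {ssr_type} plant in {target}; increase "
                "seq_length or reduce plant counts")

    spec = GenomeSpec(
        n_sequences=n_sequences, seq_length=seq_length,
        background_gc=background_gc, plants=plants, genes=genes,
        rng_seed=int(rng.integers(2**31)), detector_params=params,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------

def generate_tree(n_taxa: int, rng_seed: int = 0) -> str:
    """Ultrametric pure-birth (Yule) tree with unit depth, as Newick.

    Tips are labelled t1..tn; deterministic for a fixed seed.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    rng = np.random.default_rng(rng_seed)

    class _Node:
        __slots__ = ("time", "children", "label")

        def __init__(self, time):
            self.time = time
            self.children = []
            self.label = None

    root = _Node(0.0)
    active = [_Node(None), _Node(None)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active[k]
        node.time = t
        node.children = [_Node(None), _Node(None)]
        active[k:k + 1] = node.children
    depth = t + rng.exponential(1.0 / n_taxa)
    for i, leaf in enumerate(active):
        leaf.time = depth
        leaf.label = f"t{i + 1}"

    def newick(node, parent_time):
        bl = (node.time - parent_time) / depth
        if not node.children:
            return f"{node.label}:{bl:.8f}"
        inner = ",".join(newick(c, node.time) for c in node.children)
        return f"({inner}):{bl:.8f}"

    inner = ",".join(newick(c, 0.0) for c in root.children)
    return f"({inner});"


def simulate_bm_traits(tree, n_traits: int, evo_cov=None,
                       rng_seed: int = 0) -> pd.DataFrame:
    """Brownian-motion trait matrix on a tree (matrix-normal sampling).

    Rows (species) covary by the tree VCV C; columns (traits) by *evo_cov*
    (default identity), i.e. X = L_C Z L_R' with Z iid standard normal.
    *evo_cov* must be symmetric positive-definite.
    """
    from .phylopca import tree_vcv

    vcv = tree_vcv(tree)
    n = len(vcv.tips)
    R = np.eye(n_traits) if evo_cov is None else np.asarray(evo_cov, float)
    if R.shape != (n_traits, n_traits) or not np.allclose(R, R.T):
        raise ValueError("evo_cov must be a symmetric n_traits x n_traits "
                         "matrix")
    try:
        Lr = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError("evo_cov must be positive-definite") from None
    Lc = np.linalg.cholesky(vcv.matrix + 1e-12 * np.eye(n))
    rng = np.random.default_rng(rng_seed)
    Z = rng.standard_normal((n, n_traits))
    X = Lc @ Z @ Lr.T
    return pd.DataFrame(X, index=vcv.tips,
                        columns=[f"x{j + 1}" for j in range(n_traits)])
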