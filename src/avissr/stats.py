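"""Summary statistics over detected SSR loci.

All statistics operate on :class:`~avissr.detect.SSRLocus` collections:
type proportions (perfect / imperfect / compound, each genomic locus
counted once), abundance (loci/Mb) and density (bp/Mb), repeat-copy-number
(RCN) histograms, the coefficient of variability of RCN, GC content of the
repeat tracts, and species x canonical-motif preference matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import SSRLocus
from .motifs import canonical_classes

logger = logging.getLogger(__name__)

MB = 1_000_000


def _each_once(loci: Iterable[SSRLocus]) -> list[SSRLocus]:
    """Drop perfect loci absorbed into a compound (one count per genomic locus)."""
    return [l for l in loci if not (l.ssr_type == "perfect" and l.in_compound)]


@dataclass
class TypeProportions:
    """Percentages of perfect/imperfect/compound loci in one genome."""

    perfect: float
    imperfect: float
    compound: float

    def as_dict(self) -> dict[str, float]:
        return {"perfect": self.perfect, "imperfect": self.imperfect,
                "compound": self.compound}


def type_proportions(loci: Sequence[SSRLocus],
                     count_compound_members: bool = False) -> TypeProportions:
    """P/I/C percentages among all loci of one genome.

    Each genomic locus is counted once: perfect loci absorbed into a
    compound contribute only through the compound, unless
    *count_compound_members* is set.  The three percentages sum to 100.
    """
    kept = list(loci) if count_compound_members else _each_once(loci)
    n = len(kept)
    if n == 0:
        raise ValueError("no loci")
    counts = {"perfect": 0, "imperfect": 0, "compound": 0}
    for l in kept:
        counts[l.ssr_type] += 1
    return TypeProportions(*(100.0 * counts[k] / n for k in
                             ("perfect", "imperfect", "compound")))


def abundance_density(loci: Sequence[SSRLocus], genome_length: int,
                      by: str | None = None) -> pd.DataFrame | tuple[float, float]:
    """Abundance (loci/Mb) and density (bp/Mb).

    loci/Mb = count * 1e6 / genome_length; bp/Mb = summed locus length *
    1e6 / genome_length.  With ``by="motif_len"`` or ``by="canonical"``
    returns a per-stratum DataFrame; otherwise a (loci_per_mb, bp_per_mb)
    tuple over all loci.
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be positive, got {genome_length}")
    scale = MB / genome_length
    if by is None:
        return (len(loci) * scale, sum(l.length_bp for l in loci) * scale)
    frame = pd.DataFrame({
        "key": [getattr(l, "motif_len" if by == "motif_len" else "canonical")
                for l in loci],
        "length_bp": [l.length_bp for l in loci],
    })
    grouped = frame.groupby("key")["length_bp"].agg(["count", "sum"])
    out = pd.DataFrame({
        "loci_per_mb": grouped["count"] * scale,
        "bp_per_mb": grouped["sum"] * scale,
    })
    out.index.name = by
    return out


def rcn_histogram(loci: Sequence[SSRLocus]) -> pd.Series:
    """Counts of perfect loci per (motif length class, repeat copy number)."""
    perfect = [l for l in loci if l.ssr_type == "perfect"]
    if not perfect:
        return pd.Series(dtype=int,
                         index=pd.MultiIndex.from_arrays([[], []],
                                                         names=["motif_len",
                                                                "repeats"]))
    frame = pd.DataFrame({"motif_len": [l.motif_len for l in perfect],
                          "repeats": [l.repeats for l in perfect]})
    return frame.value_counts(["motif_len", "repeats"]).sort_index()


def cv_rcn(loci: Sequence[SSRLocus],
           regions: Sequence[str] | None = None) -> pd.DataFrame:
    """Coefficient of variability of RCN, in percent.

    CV = 100 * sd / mean with the sample (n-1) standard deviation, per
    (motif length class, region) cell when *regions* (parallel to *loci*)
    is given, else per motif length class.  Cells with fewer than two loci
    are reported missing (NaN).
    """
    perfect_idx = [i for i, l in enumerate(loci) if l.ssr_type == "perfect"]
    data = {
        "motif_len": [loci[i].motif_len for i in perfect_idx],
        "repeats": [float(loci[i].repeats) for i in perfect_idx],
    }
    keys = ["motif_len"]
    if regions is not None:
        data["region"] = [regions[i] for i in perfect_idx]
        keys.append("region")
    frame = pd.DataFrame(data)

    def cell(g: pd.Series) -> float:
        if len(g) < 2:
            logger.warning("CV cell with <2 loci reported as missing")
            return np.nan
        return 100.0 * g.std(ddof=1) / g.mean()

    out = frame.groupby(keys)["repeats"].agg(n="size", cv_percent=cell)
    return out.reset_index()


def gc_content(loci: Sequence[SSRLocus], sequences: Mapping[str, str],
               regions: Sequence[str] | None = None) -> pd.DataFrame:
    """GC fraction of concatenated locus tracts per (class, region) cell.

    (G+C)/(A+C+G+T) over the genomic spans of the loci in each cell; N
    bases are excluded from the denominator.
    """
    rows = []
    for i, l in enumerate(loci):
        seq = sequences[l.seq_id][l.start:l.end].upper()
        gc = seq.count("G") + seq.count("C")
        atgc = gc + seq.count("A") + seq.count("T")
        rows.append({
            "motif_len": l.motif_len,
            "region": regions[i] if regions is not None else "all",
            "gc": gc, "atgc": atgc,
        })
    frame = pd.DataFrame(rows)
    grouped = frame.groupby(["motif_len", "region"])[["gc", "atgc"]].sum()
    grouped["gc_fraction"] = grouped["gc"] / grouped["atgc"].where(
        grouped["atgc"] > 0)
    return grouped.reset_index()[["motif_len", "region", "gc_fraction"]]


@dataclass
class MotifPreferenceMatrix:
    """Species x canonical-motif abundance and density for one class."""

    motif_len: int
    abundance: pd.DataFrame  # loci/Mb, rows species, columns canonical motifs
    density: pd.DataFrame    # bp/Mb, same shape


def motif_preference(
    loci_by_species: Mapping[str, Sequence[SSRLocus]],
    genome_length_by_species: Mapping[str, int],
    motif_len: int,
    top_n: int | None = None,
) -> MotifPreferenceMatrix:
    """Species x canonical-motif preference matrices for one class.

    Only perfect loci of the given motif length contribute.  Columns cover
    every canonical class of that length; when *top_n* is given (the
    convention for tetra-/penta-/hexanucleotide classes, top 25), columns
    are restricted to the *top_n* motifs by mean abundance across species,
    ties broken lexicographically, and reordered by that ranking.
    """
    motifs = list(canonical_classes(motif_len))
    species = sorted(loci_by_species)
    abundance = pd.DataFrame(0.0, index=species, columns=motifs)
    density = pd.DataFrame(0.0, index=species, columns=motifs)
    for sp in species:
        glen = genome_length_by_species[sp]
        if glen <= 0:
            raise ValueError(f"genome length for {sp} must be positive")
        for l in loci_by_species[sp]:
            if l.ssr_type != "perfect" or l.motif_len != motif_len:
                continue
            abundance.loc[sp, l.canonical] += MB / glen
            density.loc[sp, l.canonical] += l.length_bp * MB / glen
    abundance.index.name = density.index.name = "species"
    if top_n is not None and top_n < len(motifs):
        ranking = (
            abundance.mean(axis=0)
            .to_frame("mean_abundance")
            .sort_values(["mean_abundance"], ascending=False, kind="mergesort")
        )
        # mergesort is stable, so lexicographic column order breaks ties
        keep = list(ranking.index[:top_n])
        abundance = abundance[keep]
        density = density[keep]
    return MotifPreferenceMatrix(motif_len, abundance, density)
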