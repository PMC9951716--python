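"""End-to-end orchestration: detect -> annotate -> stats -> phylo-PCA.

``run_species`` produces a self-contained per-species output directory
(locus table, region assignments, positional profile, summary statistics,
manifest).  ``run_comparative`` assembles species x canonical-motif
preference matrices from those directories only -- no re-detection -- and
runs a phylogenetic PCA per motif-length class.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import stats as sstats
from .annotate import assign_regions, build_annotation_index, positional_profile
from .detect import (DetectorParams, detect_all, loci_to_frame, read_loci_tsv,
                     write_loci_tsv)
from .phylopca import phylo_pca, tree_vcv

logger = logging.getLogger(__name__)

MOTIF_TOP_N = 25      # heat-map column cap for tetra/penta/hexa classes
PROFILE_TOP_N = 30    # gene-end ranks profiled


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_species(
    fasta_path,
    out_dir,
    gff_path=None,
    params: DetectorParams | None = None,
    species_id: str | None = None,
    top_n: int = PROFILE_TOP_N,
) -> Path:
    """Detect and characterize SSRs for one genome; returns the output dir.

    Without a GFF3 file, region-dependent outputs are skipped with a
    warning and detection statistics are still produced.
    """
    params = params or DetectorParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species_id = species_id or Path(fasta_path).stem

    fa = Fasta(str(fasta_path))
    sequences = {name: str(fa[name][:]) for name in fa.keys()}
    genome_length = sum(len(s) for s in sequences.values())

    loci = []
    for seq_id, seq in sequences.items():
        loci.extend(detect_all(seq, params, seq_id=seq_id))
    loci.sort(key=lambda l: (l.seq_id, l.start, l.ssr_type))
    write_loci_tsv(loci, out / "loci.tsv")

    warnings = 0
    regions = None
    if gff_path is not None and Path(gff_path).exists():
        index = build_annotation_index(gff_path)
        regions = assign_regions(loci, index)
        table = loci_to_frame(loci)
        table["region"] = regions
        table.to_csv(out / "loci_regions.tsv", sep="\t", index=False)
        profile = positional_profile(
            [l for l in loci if l.ssr_type == "perfect"], index, top_n=top_n)
        profile.to_csv(out / "positional_profile.tsv", sep="\t")
    else:
        if gff_path is not None:
            logger.warning("GFF %s missing; region statistics skipped",
                           gff_path)
        warnings += 1 if gff_path is not None else 0

    props = sstats.type_proportions(loci)
    pd.DataFrame([props.as_dict()]).to_csv(
        out / "type_proportions.tsv", sep="\t", index=False)
    perfect = [l for l in loci if l.ssr_type == "perfect"]
    sstats.abundance_density(perfect, genome_length, by="motif_len") \
        .to_csv(out / "class_abundance.tsv", sep="\t")
    sstats.rcn_histogram(perfect).rename("count").to_csv(
        out / "rcn_histogram.tsv", sep="\t")
    perfect_regions = None
    if regions is not None:
        perfect_regions = [r for l, r in zip(loci, regions)
                           if l.ssr_type == "perfect"]
    sstats.cv_rcn(perfect, perfect_regions).to_csv(
        out / "cv_rcn.tsv", sep="\t", index=False)
    sstats.gc_content(perfect, sequences, perfect_regions).to_csv(
        out / "gc_content.tsv", sep="\t", index=False)

    manifest = {
        "species_id": species_id,
        "genome_length": genome_length,
        "inputs": {
            "fasta": {"path": str(fasta_path), "sha256": _sha256(fasta_path)},
            "gff": ({"path": str(gff_path), "sha256": _sha256(gff_path)}
                    if gff_path is not None and Path(gff_path).exists()
                    else None),
        },
        "params": asdict(params),
        "n_loci": len(loci),
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def species_motif_matrices(species_dirs, motif_len: int,
                           top_n: int | None = None):
    """Assemble a :class:`MotifPreferenceMatrix` from per-species outputs."""
    loci_by_species = {}
    glen_by_species = {}
    for d in species_dirs:
        d = Path(d)
        manifest = json.loads((d / "manifest.json").read_text())
        sp = manifest["species_id"]
        loci_by_species[sp] = read_loci_tsv(d / "loci.tsv")
        glen_by_species[sp] = manifest["genome_length"]
    return sstats.motif_preference(loci_by_species, glen_by_species,
                                   motif_len, top_n=top_n)


def run_comparative(species_dirs, tree_path, out_dir,
                    mode: str = "cov") -> Path:
    """Cross-species motif-preference matrices + phylo-PCA per class.

    Needs >= 3 species whose ids match the tree's tip labels exactly;
    mismatches raise with the asymmetric difference.  Di-/trinucleotide
    classes use all canonical motifs; longer classes the 25 most abundant.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(species_dirs) < 3:
        raise ValueError("comparative analysis needs >= 3 species")
    vcv = tree_vcv(tree_path)

    for k in range(2, 7):
        top_n = None if k <= 3 else MOTIF_TOP_N
        mats = species_motif_matrices(species_dirs, k, top_n=top_n)
        mats.abundance.to_csv(out / f"abundance_k{k}.tsv", sep="\t")
        mats.density.to_csv(out / f"density_k{k}.tsv", sep="\t")
        result = phylo_pca(mats.abundance, vcv, mode=mode)
        pd.Series(result.eigenvalues,
                  index=result.loadings.columns, name="eigenvalue") \
            .to_csv(out / f"pca_eigenvalues_k{k}.tsv", sep="\t")
        result.loadings.to_csv(out / f"pca_loadings_k{k}.tsv", sep="\t")
        result.scores.to_csv(out / f"pca_scores_k{k}.tsv", sep="\t")
    return out
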