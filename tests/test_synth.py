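import dendropy
import numpy as np
import pytest

from avissr.detect import DetectorParams, find_perfect_ssrs
from avissr.phylopca import phylo_pca, tree_vcv
from avissr.synth import (GenomeSpec, PlantSpec, generate_genome,
                          generate_tree, random_genome_spec,
                          simulate_bm_traits)
from oracles import regex_perfect_oracle


def test_zero_plant_background_is_repeat_free():
    """A brute-force regex scan of a 0-plant genome finds nothing."""
    spec = GenomeSpec(n_sequences=1, seq_length=10_000, rng_seed=5)
    genome = generate_genome(spec)
    seq = genome.sequences["seq1"]
    assert regex_perfect_oracle(seq) == []
    assert find_perfect_ssrs(seq) == []
    assert genome.truth.empty


def test_planted_locus_is_echoed_verbatim():
    plant = PlantSpec("seq1", 1000, "perfect", "AG", 9)
    spec = GenomeSpec(n_sequences=1, seq_length=5000, plants=[plant],
                      rng_seed=1)
    genome = generate_genome(spec)
    row = genome.truth.iloc[0]
    assert (row.start, row.end, row.repeats, row.canonical_motif) == \
        (1000, 1018, 9, "AG")
    assert genome.sequences["seq1"][1000:1018] == "AG" * 9


def test_same_seed_same_bytes(tmp_path):
    spec1 = random_genome_spec(rng_seed=21, n_perfect=8, n_imperfect=3,
                               n_compound=2, seq_length=20_000)
    spec2 = random_genome_spec(rng_seed=21, n_perfect=8, n_imperfect=3,
                               n_compound=2, seq_length=20_000)
    g1 = generate_genome(spec1, out_dir=tmp_path / "a")
    g2 = generate_genome(spec2, out_dir=tmp_path / "b")
    for name in ("genome.fa", "genome.gff3", "truth.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()


def test_overlapping_plants_rejected():
    plants = [PlantSpec("seq1", 1000, "perfect", "AG", 9),
              PlantSpec("seq1", 1010, "perfect", "CT", 8)]
    spec = GenomeSpec(n_sequences=1, seq_length=5000, plants=plants)
    with pytest.raises(ValueError, match="AG at 1000-1018 vs CT at 1010"):
        spec.validate()


def test_non_primitive_plant_motif_rejected():
    with pytest.raises(ValueError, match="not primitive"):
        PlantSpec("seq1", 100, "perfect", "ACAC", 8).validate(DetectorParams())


def test_below_threshold_perfect_plant_rejected():
    with pytest.raises(ValueError, match="threshold"):
        PlantSpec("seq1", 100, "perfect", "AC", 6).validate(DetectorParams())


def test_imperfect_plant_edit_validation():
    params = DetectorParams()
    with pytest.raises(ValueError, match="at least one edit"):
        PlantSpec("s", 0, "imperfect", "A", 20).validate(params)
    with pytest.raises(ValueError, match="does not disrupt"):
        PlantSpec("s", 0, "imperfect", "A", 20,
                  edits=(("sub", 9, "A"),)).validate(params)
    with pytest.raises(ValueError, match="invisible"):
        PlantSpec("s", 0, "imperfect", "A", 20,
                  edits=(("del", 9),)).validate(params)
    with pytest.raises(ValueError, match="perfect locus"):
        PlantSpec("s", 0, "imperfect", "A", 30,
                  edits=(("sub", 14, "C"),)).validate(params)


def test_compound_gap_bounds():
    with pytest.raises(ValueError, match="gap"):
        PlantSpec("s", 0, "compound", "AC", 8, gap=2, second_motif="AG",
                  second_repeats=8).validate(DetectorParams())


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def test_minimal_tree():
    nwk = generate_tree(2, rng_seed=0)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    assert sorted(leaves) == ["t1", "t2"]


def test_tree_too_small_errors():
    with pytest.raises(ValueError):
        generate_tree(1)


def test_yule_tree_shape_and_depth():
    nwk = generate_tree(53, rng_seed=4)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    leaves = list(tree.leaf_node_iter())
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    assert len(leaves) == 53
    assert len(internal) == 52  # binary: n-1 splits
    depths = {round(l.distance_from_root(), 6) for l in leaves}
    assert depths == {1.0}  # ultrametric, unit depth
    assert all(e.length is None or e.length >= 0
               for e in tree.preorder_edge_iter())


def test_tree_determinism():
    assert generate_tree(10, rng_seed=9) == generate_tree(10, rng_seed=9)
    assert generate_tree(10, rng_seed=9) != generate_tree(10, rng_seed=10)


# ---------------------------------------------------------------------------
# Brownian-motion traits
# ---------------------------------------------------------------------------

def test_bm_traits_deterministic():
    nwk = generate_tree(6, rng_seed=1)
    a = simulate_bm_traits(nwk, 3, rng_seed=7)
    b = simulate_bm_traits(nwk, 3, rng_seed=7)
    assert a.equals(b)


def test_bm_traits_bad_cov_rejected():
    nwk = generate_tree(4, rng_seed=1)
    with pytest.raises(ValueError, match="positive-definite"):
        simulate_bm_traits(nwk, 2, evo_cov=[[1.0, 2.0], [2.0, 1.0]],
                           rng_seed=0)
    with pytest.raises(ValueError, match="symmetric"):
        simulate_bm_traits(nwk, 2, evo_cov=[[1.0, 0.5], [0.1, 1.0]],
                           rng_seed=0)


def test_star_tree_traits_uncorrelated():
    """Identity trait covariance on a star tree: columns uncorrelated."""
    star = "(" + ",".join(f"t{i}:1" for i in range(1, 401)) + ");"
    X = simulate_bm_traits(star, 2, rng_seed=3)
    r = np.corrcoef(X.to_numpy().T)[0, 1]
    assert abs(r) < 0.12


def test_gls_contrast_variance_recovers_sigma2():
    """Mean GLS variance of single-trait BM samples ~ sigma^2 (500 reps)."""
    nwk = generate_tree(12, rng_seed=5)
    vcv = tree_vcv(nwk)
    sigma2 = 2.5
    estimates = []
    for rep in range(500):
        X = simulate_bm_traits(nwk, 1, evo_cov=[[sigma2]], rng_seed=1000 + rep)
        res = phylo_pca(X, vcv)
        estimates.append(res.eigenvalues[0])
    assert np.mean(estimates) == pytest.approx(sigma2, rel=0.08)
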