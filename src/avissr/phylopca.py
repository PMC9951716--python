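"""Phylogenetically-informed principal component analysis.

Under Brownian motion on a rooted tree, trait values of the n species are
correlated with covariance proportional to the tree's variance-covariance
matrix C, whose (i, j) entry is the branch length shared from the root by
tips i and j.  The phylogenetic PCA of a species x trait matrix X is the
eigendecomposition of the evolutionary covariance

    a = (1' C^-1 1)^-1  1' C^-1 X          (GLS ancestral mean)
    R = (X - 1a)' C^-1 (X - 1a) / (n - 1)  (evolutionary covariance)

with species scores S = (X - 1a) V where V holds the unit-norm
eigenvectors of R (or of its correlation rescaling in ``mode="corr"``).
On a star tree (C = I) this reduces to ordinary PCA.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)


@dataclass
class TreeVCV:
    """Phylogenetic variance-covariance matrix with its tip ordering."""

    matrix: np.ndarray
    tips: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.tips, columns=self.tips)


def _load_tree(newick) -> dendropy.Tree:
    if isinstance(newick, dendropy.Tree):
        return newick
    text = str(newick)
    if "(" not in text:  # a path rather than serialized newick
        with open(text) as fh:
            text = fh.read()
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc


def tree_vcv(newick) -> TreeVCV:
    """Tree variance-covariance matrix from a Newick string, path, or tree.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip distances.  Tips are ordered as encountered
    in tree traversal.  Missing branch lengths and duplicate tip labels are
    errors.
    """
    tree = _load_tree(newick)
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 tips")
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(l is None for l in labels):
        raise ValueError("every tip must be labelled")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")

    # depth of every node (root edge length, if any, ignored)
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
            continue
        if node.edge.length is None:
            raise ValueError(f"missing branch length above node {node}")
        depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length)

    n = len(leaves)
    C = np.zeros((n, n))
    order = {id(lf): i for i, lf in enumerate(leaves)}
    for i, lf in enumerate(leaves):
        C[i, i] = depth[id(lf)]

    # postorder: tips under each child subtree of a node have that node as MRCA
    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = [order[id(node)]]
            continue
        children = [tips_below[id(ch)] for ch in node.child_nodes()]
        merged: list[int] = []
        for a_idx, a in enumerate(children):
            for b in children[a_idx + 1:]:
                for i in a:
                    for j in b:
                        C[i, j] = C[j, i] = depth[id(node)]
            merged.extend(a)
        tips_below[id(node)] = merged
    return TreeVCV(C, labels)


@dataclass
class PhyloPCAResult:
    """Eigenstructure of the evolutionary covariance of a trait matrix."""

    anc_mean: pd.Series          # GLS ancestral mean per trait
    evo_cov: pd.DataFrame        # R (or its correlation rescaling in corr mode)
    eigenvalues: np.ndarray      # descending
    loadings: pd.DataFrame       # columns PC1..PCm, unit-norm
    scores: pd.DataFrame         # species x components
    mode: str

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]

    @property
    def pc2(self) -> pd.Series:
        return self.scores["PC2"]


def _inv_psd(C: np.ndarray):
    """Inverse of a (near-)PSD matrix, ridging near-singular inputs."""
    try:
        cho = linalg.cho_factor(C)
        return lambda B: linalg.cho_solve(cho, B)
    except linalg.LinAlgError:
        ridge = 1e-8 * np.trace(C) / C.shape[0]
        logger.warning("tree VCV near-singular; adding ridge %.3g", ridge)
        cho = linalg.cho_factor(C + ridge * np.eye(C.shape[0]))
        return lambda B: linalg.cho_solve(cho, B)


def phylo_pca(X, C: TreeVCV | np.ndarray, mode: str = "cov") -> PhyloPCAResult:
    """Phylogenetic PCA of a species x trait matrix.

    Parameters
    ----------
    X
        DataFrame (rows indexed by species) or array.  When both X and C
        carry species labels, rows are aligned to the tree's tip order; a
        mismatch raises with the asymmetric difference.
    C
        :class:`TreeVCV` or plain matrix (identity = ordinary PCA).
    mode
        "cov" (default) eigendecomposes the evolutionary covariance R,
        "corr" its correlation rescaling.

    Component signs follow the convention that the largest-magnitude
    loading of each component is positive.
    """
    if mode not in ("cov", "corr"):
        raise ValueError(f"mode must be 'cov' or 'corr', got {mode!r}")
    if isinstance(C, TreeVCV):
        Cm, tips = C.matrix, C.tips
    else:
        Cm, tips = np.asarray(C, dtype=float), None

    if isinstance(X, pd.DataFrame):
        if tips is not None:
            missing = sorted(set(tips) - set(X.index))
            extra = sorted(set(X.index) - set(tips))
            if missing or extra:
                raise ValueError(
                    f"species/tip mismatch: missing from matrix {missing}, "
                    f"not in tree {extra}")
            X = X.loc[tips]
        species = list(X.index)
        traits = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        species = tips if tips is not None else [f"s{i+1}" for i in
                                                 range(Xm.shape[0])]
        traits = [f"x{j+1}" for j in range(Xm.shape[1])]

    if not np.all(np.isfinite(Xm)):
        raise ValueError("trait matrix contains non-finite entries")
    n, m = Xm.shape
    if Cm.shape != (n, n):
        raise ValueError(f"C is {Cm.shape} but X has {n} rows")
    if n <= m:
        logger.warning("n=%d species <= m=%d traits: covariance is rank "
                       "deficient", n, m)

    solve = _inv_psd(Cm)
    ones = np.ones((n, 1))
    Ci1 = solve(ones)
    a = (Ci1.T @ Xm) / (ones.T @ Ci1)          # 1 x m GLS mean
    Xc = Xm - ones @ a
    R = Xc.T @ solve(Xc) / (n - 1)
    R = (R + R.T) / 2
    if mode == "corr":
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)

    evals, evecs = linalg.eigh(R)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    for j in range(m):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ evecs

    pcs = [f"PC{j+1}" for j in range(m)]
    return PhyloPCAResult(
        anc_mean=pd.Series(a.ravel(), index=traits, name="ancestral_mean"),
        evo_cov=pd.DataFrame(R, index=traits, columns=traits),
        eigenvalues=evals,
        loadings=pd.DataFrame(evecs, index=traits, columns=pcs),
        scores=pd.DataFrame(scores, index=species, columns=pcs),
        mode=mode,
    )
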