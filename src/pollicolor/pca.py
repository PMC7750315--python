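"""Standardized PCA of binned spectra and phylomorphospace projection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError
from .trees import PhyloTree

__all__ = ["PcaResult", "Phylomorphospace", "standardized_pca", "phylomorphospace", "pca_pc1"]


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a covariance PCA."""

    scores: pd.DataFrame        # sample x component
    loadings: pd.DataFrame      # variable x component
    explained_variance: np.ndarray
    column_means: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def cumulative_variance(self, k: int = 2) -> float:
        return float(self.explained_variance[:k].sum())


def _svd_pca(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-centered SVD PCA with a deterministic sign convention.

    Each component is flipped so its largest-|loading| element is positive.
    Returns (scores, loadings, explained_fractions, column_means).
    """
    means = M.mean(axis=0)
    E = M - means
    total = np.sum(E**2)
    if total < 1e-24:
        raise FitError("rank-0 input: all rows identical")
    U, S, Vt = np.linalg.svd(E, full_matrices=False)
    # drop numerically null components
    keep = S > S[0] * 1e-12
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    for comp in range(S.size):
        j = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    scores = U * S
    frac = S**2 / total
    return scores, Vt.T, frac, means


def standardized_pca(binned: pd.DataFrame | np.ndarray) -> PcaResult:
    """PCA on the covariance of a row-centered sample x bin matrix.

    Rows are expected to already have zero mean (output of the mean-centering
    and binning step), so the PCA captures spectral *shape* rather than total
    reflectance.  No per-column rescaling is applied.
    """
    if isinstance(binned, pd.DataFrame):
        M = binned.to_numpy(dtype=float)
        index, columns = binned.index, binned.columns
    else:
        M = np.asarray(binned, dtype=float)
        index = pd.RangeIndex(M.shape[0])
        columns = [f"bin{j}" for j in range(M.shape[1])]
    if M.shape[0] < 2:
        raise FitError("PCA needs at least 2 samples")
    scores, loadings, frac, means = _svd_pca(M)
    comp_names = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=columns, columns=comp_names),
        explained_variance=frac,
        column_means=means,
    )


def pca_pc1(M: np.ndarray) -> np.ndarray:
    """PC1 scores of a plain covariance PCA of M (shared sign convention)."""
    scores, _, frac, _ = _svd_pca(np.asarray(M, dtype=float))
    return scores[:, 0]


@dataclass
class Phylomorphospace:
    """Tip and ancestral-node coordinates of a tree projected into PC space."""

    tip_coords: pd.DataFrame    # species x (PC1, PC2)
    node_coords: pd.DataFrame   # internal node id x (PC1, PC2)
    edges: list[tuple[str, str]]


def phylomorphospace(tree: PhyloTree, species_scores: pd.DataFrame) -> Phylomorphospace:
    """Project a tree into the first two PC axes via BM ancestral estimates.

    ``species_scores`` is indexed by species label with at least columns
    PC1 and PC2; internal node coordinates are joint ML ancestral states under
    BM, estimated independently per axis.
    """
    from .phylo import anc_ml

    missing = [l for l in tree.tip_labels if l not in species_scores.index]
    if missing:
        raise FitError(f"species missing from scores: {missing}")
    names = []
    coords = {}
    for pc in ("PC1", "PC2"):
        if pc not in species_scores.columns:
            raise FitError(f"scores lack column {pc}")
        tipvals = {l: float(species_scores.loc[l, pc]) for l in tree.tip_labels}
        coords[pc] = anc_ml(tree, tipvals)
    n = tree.n_tips
    node_ids = [f"node{idx}" for idx in range(n, tree.n_nodes)]
    tip_coords = pd.DataFrame(
        {pc: coords[pc][:n] for pc in ("PC1", "PC2")}, index=tree.tip_labels
    )
    node_coords = pd.DataFrame(
        {pc: coords[pc][n:] for pc in ("PC1", "PC2")}, index=node_ids
    )

    def name_of(idx: int) -> str:
        return tree.tip_labels[idx] if idx < n else f"node{idx}"

    edges = [
        (name_of(int(tree.parent[i])), name_of(i))
        for i in range(tree.n_nodes)
        if tree.parent[i] >= 0
    ]
    return Phylomorphospace(tip_coords=tip_coords, node_coords=node_coords, edges=edges)
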