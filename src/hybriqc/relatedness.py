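"""Genetic relatedness: dosage encoding, Euclidean distances,
Neighbor-Joining trees and PCA with marker contributions.

Genotypes are encoded as allele-2 dosage fractions (HOM1 -> 0, HET -> 0.5,
HOM2 -> 1, missing absent). Pairwise distance is the unscaled Euclidean
distance over the loci observed in both samples:

    d(i, j) = sqrt( sum_l (v_il - v_jl)^2 )

so two fully homozygous samples differing at k loci are sqrt(k) apart and
distances are bounded by sqrt(panel size) (sqrt(17) ~ 4.12 for the
packaged panel). No rescaling is applied for skipped loci, which keeps
the "number of differing homozygous loci" reading of d^2; this is an
encoding choice of this package, not a property of the data.

Neighbor-Joining follows Saitou & Nei's agglomeration: with m active
nodes, join the pair minimizing Q(i,j) = (m-2) d(i,j) - r_i - r_j (r the
row sums), ties broken towards the lexicographically smallest index pair
so output is deterministic. Negative branch lengths are clamped to zero
with the deficit transferred to the sister branch (raw lengths kept on
each edge as ``raw_length``). NJ reconstructs additive distance matrices
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .genotype_io import GenotypeMatrix, HET, HOM1, HOM2, MISSING

__all__ = [
    "DistanceMatrix", "encode_numeric", "pairwise_distance",
    "neighbor_joining", "tree_to_newick", "flag_related_pairs",
    "PCAResult", "pca", "marker_contributions",
]

_DOSAGE = {int(HOM1): 0.0, int(HET): 0.5, int(HOM2): 1.0, int(MISSING): np.nan}


def encode_numeric(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Dosage encoding (samples x markers): 0 / 0.5 / 1, NaN for missing."""
    values = np.choose(matrix.calls + 1,  # MISSING=-1 -> index 0
                       [np.nan, 0.0, 0.5, 1.0])
    return pd.DataFrame(values, index=pd.Index(matrix.sample_ids, name="sample_id"),
                        columns=matrix.marker_ids)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with shared-locus counts.

    ``values[i, j]`` is NaN (and the pair is listed in
    ``undefined_pairs``) when samples i and j share no non-missing locus.
    """

    sample_ids: list[str]
    values: np.ndarray    # (n, n) float, zero diagonal
    n_shared: np.ndarray  # (n, n) int, loci observed in both samples

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample list")

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.values[i, j]):
                    out.append((self.sample_ids[i], self.sample_ids[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.sample_ids, name="sample_id")
        return pd.DataFrame(self.values, index=idx, columns=self.sample_ids)


def pairwise_distance(numeric: pd.DataFrame) -> DistanceMatrix:
    """Unscaled Euclidean distances with pairwise-complete deletion."""
    if len(numeric) < 2:
        raise ValueError("pairwise distances require at least 2 samples")
    X = numeric.to_numpy(dtype=float)
    mask = np.isfinite(X).astype(float)
    Xz = np.where(np.isfinite(X), X, 0.0)
    sq = Xz ** 2
    # d2[i,j] = sum over shared loci of (x_i - x_j)^2, via masked expansion
    d2 = sq @ mask.T + mask @ sq.T - 2.0 * (Xz @ Xz.T)
    d2 = np.maximum(d2, 0.0)  # numeric noise
    shared = (mask @ mask.T).astype(int)
    d = np.sqrt(d2)
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(sample_ids=list(numeric.index), values=d,
                          n_shared=shared)


# ---------------------------------------------------------------------------
# Neighbor-Joining


def neighbor_joining(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining; returns an unrooted dendropy Tree.

    Requires a complete (all-finite) distance matrix over >= 2 samples.
    Each edge carries its pre-clamp length as ``edge.raw_length``.
    """
    ids = dist.sample_ids
    n = len(ids)
    D = np.array(dist.values, dtype=float)
    if n < 2:
        raise ValueError("Neighbor-Joining requires at least 2 samples")
    off_diag = ~np.eye(n, dtype=bool)
    if not np.isfinite(D[off_diag]).all():
        raise ValueError("incomplete distance matrix: undefined pairwise "
                         "distances present (samples share no called loci)")

    tns = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    nodes = [dendropy.Node(taxon=tns.get_taxon(label=s)) for s in ids]

    def _attach(parent: dendropy.Node, child: dendropy.Node,
                length: float, raw: float) -> None:
        parent.add_child(child)
        child.edge.length = length
        child.edge.raw_length = raw

    if n == 2:
        root = dendropy.Node()
        _attach(root, nodes[0], D[0, 1] / 2.0, D[0, 1] / 2.0)
        _attach(root, nodes[1], D[0, 1] / 2.0, D[0, 1] / 2.0)
        tree.seed_node = root
        return tree

    active = list(range(n))  # indices into D's current (shrinking) order
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=0)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu, ju = np.triu_indices(m, k=1)
        qvals = Q[iu, ju]
        best = int(np.argmin(qvals))  # argmin returns the first (lexicographic) min
        a, b = int(iu[best]), int(ju[best])
        dij = sub[a, b]
        va = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        vb = dij - va
        va_c, vb_c = _clamp_transfer(va, vb)
        new_node = dendropy.Node()
        _attach(new_node, nodes[active[a]], va_c, va)
        _attach(new_node, nodes[active[b]], vb_c, vb)
        # distances from the new node to every other active node
        others = [k for t, k in enumerate(active) if t not in (a, b)]
        d_new = 0.5 * (D[active[a], others] + D[active[b], others] - dij)
        # grow D with a row/column for the new node
        idx_new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[idx_new, others] = d_new
        D[others, idx_new] = d_new
        nodes.append(new_node)
        active = others + [idx_new]

    # resolve the final three nodes around a central vertex
    a, b, c = active
    va = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    vb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    vc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    center = dendropy.Node()
    for idx, v in ((a, va), (b, vb), (c, vc)):
        _attach(center, nodes[idx], max(v, 0.0), v)
    tree.seed_node = center
    return tree


def _clamp_transfer(va: float, vb: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the deficit to its sister."""
    if va < 0.0:
        vb, va = vb + va, 0.0
    if vb < 0.0:
        va, vb = va + vb, 0.0
    return max(va, 0.0), max(vb, 0.0)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def flag_related_pairs(dist: DistanceMatrix, threshold: float = 2.0,
                       restrict_to=None) -> pd.DataFrame:
    """All unordered sample pairs with distance strictly below ``threshold``.

    ``restrict_to`` optionally limits the scan to an iterable of
    (sample_a, sample_b) pairs, e.g. designed parental pairs or every
    female against one male. Sorted ascending by distance.
    """
    ids = dist.sample_ids
    index = {s: i for i, s in enumerate(ids)}
    if restrict_to is None:
        candidates = [(ids[i], ids[j]) for i in range(len(ids))
                      for j in range(i + 1, len(ids))]
    else:
        candidates = [tuple(p) for p in restrict_to]
    rows = []
    for a, b in candidates:
        d = float(dist.values[index[a], index[b]])
        if np.isfinite(d) and d < threshold:
            rows.append({"sample_a": a, "sample_b": b, "distance": d})
    out = pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance"])
    return out.sort_values(["distance", "sample_a", "sample_b"],
                           ignore_index=True)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Centered (unscaled) PCA of mean-imputed dosages.

    scores: sample x component; loadings: marker x component (orthonormal
    right singular vectors); eigenvalues: per-component variances;
    variance_explained: percent per component, summing to 100 over all
    components. Component signs are fixed so each loading vector's
    largest-magnitude entry is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    column_means: pd.Series
    imputed: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(numeric: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a dosage matrix; missing values mean-imputed per marker.

    The full decomposition is always computed (so explained-variance
    shares are normalized over everything); ``n_components`` merely
    truncates the returned scores/loadings.
    """
    if len(numeric) < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = numeric.to_numpy(dtype=float)
    col_means = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    X = np.where(np.isfinite(X), X, col_means[None, :])
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("zero-variance matrix: PCA undefined")
    k_full = min(X.shape)
    fit = _SKPCA(n_components=k_full, svd_solver="full").fit(X)
    scores = fit.transform(X)
    loadings = fit.components_.T  # marker x component
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[i, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    comp_names = [f"PC{k + 1}" for k in range(k_full)]
    keep = k_full if n_components is None else min(n_components, k_full)
    return PCAResult(
        scores=pd.DataFrame(scores[:, :keep], index=numeric.index,
                            columns=comp_names[:keep]),
        loadings=pd.DataFrame(loadings[:, :keep], index=numeric.columns,
                              columns=comp_names[:keep]),
        eigenvalues=fit.explained_variance_[:keep],
        variance_explained=100.0 * fit.explained_variance_ratio_[:keep],
        column_means=pd.Series(col_means, index=numeric.columns),
        imputed=pd.DataFrame(X, index=numeric.index, columns=numeric.columns),
    )


def marker_contributions(result: PCAResult, dims: int = 2) -> pd.DataFrame:
    """Percent contribution of each marker to each of the first ``dims``
    components, plus their eigenvalue-weighted combination.

    contrib(j, k) = 100 * loading(j, k)^2 / sum_j loading(j, k)^2;
    combined(j)   = sum_k contrib(j, k) * lambda_k / sum_k lambda_k.
    Each column sums to 100 over markers.
    """
    if dims > result.n_components:
        raise ValueError(f"dims={dims} exceeds {result.n_components} components")
    L = result.loadings.iloc[:, :dims].to_numpy()
    lam = result.eigenvalues[:dims]
    contrib = 100.0 * L ** 2 / (L ** 2).sum(axis=0, keepdims=True)
    combined = contrib @ (lam / lam.sum())
    out = pd.DataFrame(contrib, index=result.loadings.index,
                       columns=result.loadings.columns[:dims])
    out["combined"] = combined
    return out
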