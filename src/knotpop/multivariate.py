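"""Clustering, ordination, and univariate screening shared by all layers.

Similarity between band profiles follows the two-state matching
coefficients: ``dice_paper`` is 2·n_xy/(n_x + n_y) (the Dice/Sørensen
form, the default for the genetic dendrogram), ``jaccard_true`` is
n_xy/(n_x + n_y − n_xy); n_x and n_y count presences per profile and
n_xy the shared presences.  Hierarchical clustering (Ward.D2-style on the
given dissimilarities, or UPGMA) and cophenetic access are delegated to
scipy; PCA is a plain SVD with a fixed sign convention; MCA is a
correspondence analysis of the two-category indicator expansion of the
band matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import kruskal

from .io import BandMatrix, TraitTable


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """N x N similarity in [0, 1] with its method tag."""

    values: pd.DataFrame
    method: str

    def to_distance(self) -> pd.DataFrame:
        return 1.0 - self.values


def band_similarity(bm: BandMatrix, method: str = "dice_paper") -> SimilarityMatrix:
    """Pairwise profile similarity over jointly observed bands."""
    if method not in ("dice_paper", "jaccard_true"):
        raise ValueError(f"unknown similarity method {method!r}")
    x = bm.values.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    xz = np.nan_to_num(x)
    n = x.shape[0]
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = obs[i] & obs[j]
            nx = xz[i, joint].sum()
            ny = xz[j, joint].sum()
            nxy = (xz[i, joint] * xz[j, joint]).sum()
            if nx + ny == 0:
                warnings.warn("two all-zero profiles: similarity set to 1",
                              stacklevel=2)
                s = 1.0
            elif method == "dice_paper":
                s = 2.0 * nxy / (nx + ny)
            else:
                s = nxy / (nx + ny - nxy)
            sim[i, j] = sim[j, i] = s
    return SimilarityMatrix(
        pd.DataFrame(sim, index=bm.sample_ids, columns=bm.sample_ids), method)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    leaves: list[str]
    method: str = ""

    def __post_init__(self) -> None:
        if self.linkage.shape != (len(self.leaves) - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cophenetic_heights(self) -> pd.DataFrame:
        dvec = sch.cophenet(self.linkage)
        return pd.DataFrame(squareform(dvec), index=self.leaves,
                            columns=self.leaves)

    def fusion_ranks(self) -> pd.DataFrame:
        """Merge index (1-based) at which each leaf pair first co-clusters."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        ranks = np.zeros((n, n))
        for m, (a, b, _h, _c) in enumerate(self.linkage, start=1):
            left, right = members.pop(int(a)), members.pop(int(b))
            for i in left:
                for j in right:
                    ranks[i, j] = ranks[j, i] = m
            members[n + m - 1] = left + right
        return pd.DataFrame(ranks, index=self.leaves, columns=self.leaves)

    def to_newick(self, path: str | Path | None = None) -> str:
        """Newick string with branch lengths from merge heights."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage,
                                            id_list=list(self.leaves))
        nwk = str(tree).strip()
        if path is not None:
            Path(path).write_text(nwk + "\n")
        return nwk


def hierarchical_cluster(D: pd.DataFrame, method: str = "ward") -> Dendrogram:
    """Agglomerate a symmetric dissimilarity matrix.

    ``ward`` applies the Ward.D2-style Lance–Williams update directly to
    the given dissimilarities (an accepted approximation when they are not
    Euclidean); ``upgma`` is average linkage.
    """
    if D.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    scipy_method = {"ward": "ward", "upgma": "average"}.get(method)
    if scipy_method is None:
        raise ValueError(f"unknown clustering method {method!r}")
    dvec = squareform(D.to_numpy(dtype=float), checks=True)
    Z = sch.linkage(dvec, method=scipy_method)
    return Dendrogram(Z, list(D.index), method=method)


def cophenetic_matrix(dend: Dendrogram) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(heights, fusion-level ranks) for every leaf pair."""
    return dend.cophenetic_heights(), dend.fusion_ranks()


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Sample scores, variable loadings/categories, explained fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    kind: str
    preprocessing: str = ""
    #: principal inertias (MCA) or component variances (PCA)
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    total_inertia: float | None = None


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: per axis, the largest-|loading| entry is positive
    for k in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, k]))
        if v[i, k] < 0:
            v[:, k] *= -1
            u[:, k] *= -1
    return u, v


def pca(X: pd.DataFrame, center: bool = True, scale: bool = False,
        n_axes: int | None = None) -> OrdinationResult:
    """Principal component analysis by SVD of the preprocessed matrix.

    ``scale`` divides each column by its sample standard deviation;
    zero-variance columns are dropped with a warning in that case.
    """
    X = X.astype(float)
    if X.isna().to_numpy().any():
        X = X.dropna(axis=0)
        warnings.warn("rows with missing values dropped", stacklevel=2)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    M = X.to_numpy(dtype=float)
    cols = list(X.columns)
    if center:
        M = M - M.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1).to_numpy()
        zero = sd == 0
        if zero.any():
            warnings.warn(f"zero-variance columns dropped: "
                          f"{[c for c, z in zip(cols, zero) if z]}",
                          stacklevel=2)
            M = M[:, ~zero]
            cols = [c for c, z in zip(cols, zero) if not z]
            sd = sd[~zero]
        M = M / sd
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    scores = u * s
    loadings = vt.T
    scores, loadings = _fix_signs(scores, loadings)
    var = s ** 2 / max(X.shape[0] - 1, 1)
    explained = s ** 2 / (s ** 2).sum() if (s ** 2).sum() > 0 else s * 0
    k = len(s) if n_axes is None else min(n_axes, len(s))
    axes = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores[:, :k], index=X.index, columns=axes),
        loadings=pd.DataFrame(loadings[:, :k], index=cols, columns=axes),
        explained=explained[:k], kind="pca",
        preprocessing=f"center={center},scale={scale}",
        eigenvalues=var[:k])


def mca_binary(bm: BandMatrix, n_axes: int = 2,
               correction: str | None = None) -> OrdinationResult:
    """Multiple correspondence analysis of the band matrix.

    Each band becomes two indicator categories (present/absent); the
    N x 2L indicator matrix is analysed by correspondence analysis (SVD of
    the standardized residuals).  Total inertia of such a table is exactly
    J/Q − 1 = 1.  Constant bands contribute a zero-count category and are
    dropped with a warning.  ``correction='benzecri'`` rescales principal
    inertias above 1/Q.
    """
    if correction not in (None, "benzecri"):
        raise ValueError(f"unknown correction {correction!r}")
    x = bm.values
    if x.isna().to_numpy().any():
        raise ValueError("MCA requires a complete matrix")
    keep = [b for b in x.columns if x[b].nunique() > 1]
    dropped = [b for b in x.columns if b not in keep]
    if dropped:
        warnings.warn(f"constant bands dropped: {dropped[:5]}", stacklevel=2)
    if not keep:
        raise ValueError("no variable bands for MCA")
    x = x[keep]
    q = x.shape[1]
    ind = pd.concat([x.rename(columns=lambda b: f"{b}=1"),
                     (1.0 - x).rename(columns=lambda b: f"{b}=0")], axis=1)
    Z = ind.to_numpy(dtype=float)
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, s, vt = np.linalg.svd(S, full_matrices=False)
    # drop the trivial zero-inertia dimensions at machine precision
    nz = s > 1e-12
    u, s, vt = u[:, nz], s[nz], vt[nz]
    inertias = s ** 2
    total = float(inertias.sum())
    row_coords = (u * s) / np.sqrt(r)[:, None]
    col_coords = (vt.T * s) / np.sqrt(c)[:, None]
    row_coords, col_coords = _fix_signs(row_coords, col_coords)
    if correction == "benzecri":
        lam = inertias
        adj = np.where(lam > 1.0 / q,
                       ((q / (q - 1.0)) * (lam - 1.0 / q)) ** 2, 0.0)
        explained = adj / adj.sum() if adj.sum() > 0 else adj
    else:
        explained = inertias / total
    k = min(n_axes, len(s))
    axes = [f"Dim{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(row_coords[:, :k], index=x.index, columns=axes),
        loadings=pd.DataFrame(col_coords[:, :k], index=ind.columns,
                              columns=axes),
        explained=explained[:k], kind="mca",
        preprocessing=f"correction={correction}",
        eigenvalues=inertias[:k], total_inertia=total)


# ---------------------------------------------------------------------------
# univariate screening
# ---------------------------------------------------------------------------

def kruskal_wallis(traits: TraitTable, labels: pd.Series | None = None
                   ) -> pd.DataFrame:
    """Tie-corrected Kruskal–Wallis H per trait across populations."""
    labels = traits.populations if labels is None else labels.reindex(
        traits.data.index)
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >=2 groups")
    rows = []
    for trait in traits.data.columns:
        samples = [traits.data.loc[labels == g, trait].dropna().to_numpy()
                   for g in groups]
        if any(len(s) == 0 for s in samples):
            raise ValueError(f"empty group for trait {trait!r}")
        flat = np.concatenate(samples)
        if np.all(flat == flat[0]):
            h, p = 0.0, 1.0
        else:
            h, p = kruskal(*samples)
        rows.append({"trait": trait, "H": float(h),
                     "df": len(groups) - 1, "p_value": float(p)})
    return pd.DataFrame(rows).set_index("trait")
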