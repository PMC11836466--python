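"""Cross-layer synthesis: Evanno ΔK, an admixture EM stand-in, and
dendrogram concordance via Baker's gamma.

The Evanno statistic post-processes replicate log-likelihoods lnP(D) from
an external structure-inference run:

    L'(K)   = L(K) − L(K−1)
    |L''(K)| = |L(K+1) − 2·L(K) + L(K−1)|
    ΔK      = mean over replicates of |L''(K)|  /  sd over replicates of L(K)

and the K maximizing ΔK (interior K only) estimates the number of genetic
clusters.

``admixture_em`` is a deliberately lightweight maximum-likelihood stand-in
for the Bayesian MCMC admixture sampler: band presence is modelled as an
independent Bernoulli per cluster, x_ik ~ Bern(Σ_c q_ic f_ck), and (Q, F)
are fit by EM with restarts.  It ignores dominance and ploidy; it
approximates, not reproduces, a Bayesian bar plot.

Baker's gamma between two dendrograms on the same leaves is the Spearman
rank correlation, over all leaf pairs, of the fusion levels (merge
indices) at which each pair first co-clusters — purely topological.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .errors import ConfigError, StructureError
from .io import BandMatrix
from .multivariate import Dendrogram
from .simulate import StructureRuns


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------

@dataclass
class DeltaKResult:
    """Per-K Evanno table and the selected K (None when ΔK is flat zero)."""

    table: pd.DataFrame
    best_k: int | None


def evanno_delta_k(runs: StructureRuns) -> DeltaKResult:
    """ΔK over the interior of the K grid.

    Ks where the replicate sd of L(K) is zero get an undefined (NaN) ΔK
    with a warning; if no K has a defined ΔK an error is raised.
    """
    if len(runs.k_values) < 3:
        raise ConfigError("ΔK needs >=3 consecutive K values")
    if runs.n_replicates < 2:
        raise ConfigError("ΔK needs >=2 replicates per K")
    L = runs.logliks
    ks = runs.k_values
    mean_l = L.mean(axis=1)
    sd_l = L.std(axis=1, ddof=1)
    # per-replicate second difference, |.|, averaged over replicates
    l2 = L[2:] - 2.0 * L[1:-1] + L[:-2]
    mean_abs_l2 = np.abs(l2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = mean_abs_l2 / sd_l[1:-1]
    delta = np.where(sd_l[1:-1] == 0, np.nan, delta)
    if np.isnan(delta).any():
        warnings.warn("ΔK undefined at K with zero replicate sd", stacklevel=2)
    if np.isnan(delta).all():
        raise StructureError("ΔK undefined at every interior K")
    table = pd.DataFrame({
        "K": ks, "mean_lnP": mean_l, "sd_lnP": sd_l,
        "mean_abs_L2": np.concatenate([[np.nan], mean_abs_l2, [np.nan]]),
        "delta_K": np.concatenate([[np.nan], delta, [np.nan]]),
    }).set_index("K")
    finite = table["delta_K"].dropna()
    best = None
    if np.nanmax(finite.to_numpy()) > 0:
        best = int(finite.idxmax())
    return DeltaKResult(table=table, best_k=best)


# ---------------------------------------------------------------------------
# admixture EM stand-in
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureEstimate:
    """Membership fractions Q (samples x clusters), cluster band-frequency
    profiles F (clusters x bands), and the EM log-likelihood trace."""

    q: pd.DataFrame
    f: pd.DataFrame
    loglik_trace: np.ndarray
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _admix_loglik(x: np.ndarray, q: np.ndarray, f: np.ndarray) -> float:
    p1 = q @ f
    p = np.where(x == 1.0, p1, 1.0 - p1)
    return float(np.log(np.clip(p, 1e-300, None)).sum())


def _admix_em_once(x: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int, tol: float):
    n, L = x.shape
    q = rng.dirichlet(np.ones(k), size=n)
    f = np.clip(x.mean(axis=0)[None, :] + rng.normal(0, 0.1, (k, L)),
                0.01, 0.99)
    trace = [_admix_loglik(x, q, f)]
    converged = False
    eps = 1e-12
    for _ in range(max_iter):
        # E-step: posterior ancestry of each (sample, band) observation
        num1 = q[:, :, None] * f[None, :, :]          # n x k x L, x=1 branch
        num0 = q[:, :, None] * (1.0 - f[None, :, :])  # x=0 branch
        num = np.where(x[:, None, :] == 1.0, num1, num0)
        post = num / (num.sum(axis=1, keepdims=True) + eps)
        # M-step
        q = post.sum(axis=2)
        q = q / q.sum(axis=1, keepdims=True)
        w = post.sum(axis=0)                           # k x L
        f = (post * x[:, None, :]).sum(axis=0) / (w + eps)
        f = np.clip(f, eps, 1.0 - eps)
        trace.append(_admix_loglik(x, q, f))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return q, f, np.asarray(trace), converged


def admixture_em(bm: BandMatrix, k: int, seed: int = 0,
                 n_restarts: int = 10, max_iter: int = 500,
                 tol: float = 1e-6) -> AdmixtureEstimate:
    """Fit the Bernoulli admixture model by EM from random starts.

    The best-likelihood restart is returned; non-convergence within
    ``max_iter`` leaves ``converged`` False.  ``k=1`` has the closed form
    Q = 1, F = pooled band frequencies.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    x = bm.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ConfigError("admixture EM requires a complete matrix")
    if k == 1:
        q = np.ones((x.shape[0], 1))
        f = x.mean(axis=0)[None, :]
        ll = _admix_loglik(x, q, f)
        return AdmixtureEstimate(
            pd.DataFrame(q, index=bm.sample_ids, columns=["cluster1"]),
            pd.DataFrame(f, index=["cluster1"], columns=bm.band_ids),
            np.array([ll]), True)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        fit = _admix_em_once(x, k, rng, max_iter, tol)
        if best is None or fit[2][-1] > best[2][-1]:
            best = fit
    q, f, trace, converged = best
    if not converged:
        warnings.warn("EM did not converge; returning best iterate",
                      stacklevel=2)
    cols = [f"cluster{c + 1}" for c in range(k)]
    return AdmixtureEstimate(
        pd.DataFrame(q, index=bm.sample_ids, columns=cols),
        pd.DataFrame(f, index=cols, columns=bm.band_ids),
        trace, converged)


def match_clusters(f_est: pd.DataFrame, f_true: np.ndarray) -> list[int]:
    """Resolve label switching: the permutation of estimated clusters
    minimizing total |F_est − F_true| (exhaustive; K is small)."""
    k = f_est.shape[0]
    best_perm, best_err = None, np.inf
    est = f_est.to_numpy()
    for perm in permutations(range(k)):
        err = np.abs(est[list(perm)] - f_true).mean()
        if err < best_err:
            best_perm, best_err = list(perm), err
    return best_perm


# ---------------------------------------------------------------------------
# dendrogram concordance
# ---------------------------------------------------------------------------

@dataclass
class DendroComparison:
    """Baker's gamma (primary) and cophenetic Pearson (secondary)."""

    name_a: str
    name_b: str
    gamma: float
    cophenetic_r: float
    p_value: float | None = None


def _pair_vector(mat: pd.DataFrame, leaves: list[str]) -> np.ndarray:
    m = mat.loc[leaves, leaves].to_numpy()
    iu = np.triu_indices(len(leaves), k=1)
    return m[iu]


def bakers_gamma(t1: Dendrogram, t2: Dendrogram,
                 name_a: str = "tree1", name_b: str = "tree2",
                 n_perm: int = 0, seed: int | None = None) -> DendroComparison:
    """Baker's gamma between two dendrograms on identical leaf sets.

    Spearman correlation (average ranks on ties) of the fusion-level
    vectors over all leaf pairs; with ``n_perm`` > 0 a permutation p-value
    is computed by shuffling the leaf labels of the second tree.
    """
    if set(t1.leaves) != set(t2.leaves):
        diff = sorted(set(t1.leaves) ^ set(t2.leaves))
        raise ValueError(f"leaf sets differ: {diff}")
    leaves = sorted(t1.leaves)
    r1 = _pair_vector(t1.fusion_ranks(), leaves)
    r2 = _pair_vector(t2.fusion_ranks(), leaves)
    gamma = _safe_spearman(r1, r2)
    h1 = _pair_vector(t1.cophenetic_heights(), leaves)
    h2 = _pair_vector(t2.cophenetic_heights(), leaves)
    coph = _safe_pearson(h1, h2)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ranks2 = t2.fusion_ranks()
        count = 0
        for _ in range(n_perm):
            shuffled = list(rng.permutation(leaves))
            perm_mat = ranks2.loc[shuffled, shuffled]
            perm_mat.index = perm_mat.columns = leaves
            g = _safe_spearman(r1, _pair_vector(perm_mat, leaves))
            if abs(g) >= abs(gamma):
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
    return DendroComparison(name_a, name_b, gamma=gamma,
                            cophenetic_r=coph, p_value=p)


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) or np.all(b == b[0]):
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(spearmanr(a, b).statistic)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) or np.all(b == b[0]):
        return 1.0 if np.allclose(a, b) else 0.0
    return float(pearsonr(a, b).statistic)


def concordance_report(dendros: dict[str, Dendrogram], n_perm: int = 0,
                       seed: int | None = None) -> pd.DataFrame:
    """All pairwise Baker's gammas between named evidence-layer dendrograms,
    as a square matrix (diagonal 1)."""
    if len(dendros) < 2:
        raise ValueError("need at least two dendrograms")
    names = list(dendros)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cmpr = bakers_gamma(dendros[a], dendros[b], a, b,
                                n_perm=n_perm, seed=seed)
            out.loc[a, b] = out.loc[b, a] = cmpr.gamma
    return out
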