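"""Two-level analysis of molecular variance (AMOVA) on binary band profiles.

The squared Euclidean distance between two 0/1 profiles equals their band
mismatch count, so total and within-group sums of squares follow the
classical decomposition over pairwise distances:

    SS_total  = (1/N)  Σ_{i<j} d²(i, j)
    SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²(i, j)
    SS_among  = SS_total − SS_within

with df_among = a − 1, df_within = N − a, df_total = N − 1.  The among
variance component uses the average-sample-size coefficient
n0 = (N − Σ n_g²/N)/(a − 1):

    σ²_within = MS_within
    σ²_among  = max(0, (MS_among − MS_within)/n0)
    Phi       = σ²_among / (σ²_among + σ²_within)

Significance is assessed by permuting population labels across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, StructureError
from .io import BandMatrix


def squared_euclidean_binary(bm: BandMatrix,
                             pairwise_complete: bool = False) -> pd.DataFrame:
    """N x N matrix of band mismatch counts (= squared Euclidean distance).

    With ``pairwise_complete`` the count is over jointly observed bands,
    rescaled to the full band count; the SS decomposition is then only
    approximate and a warning is raised.
    """
    x = bm.values.to_numpy(dtype=float)
    if not pairwise_complete:
        if np.isnan(x).any():
            raise FormatError("missing values present; drop them or use "
                              "pairwise_complete=True")
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    else:
        warnings.warn("pairwise-complete distances: SS decomposition is "
                      "approximate", stacklevel=2)
        obs = ~np.isnan(x)
        joint = obs[:, None, :] & obs[None, :, :]
        n_joint = joint.sum(axis=2).astype(float)
        if (n_joint == 0).any():
            raise FormatError("sample pair with no jointly observed band")
        diff = np.abs(np.nan_to_num(x)[:, None, :] - np.nan_to_num(x)[None, :, :])
        d = (diff * joint).sum(axis=2) * (x.shape[1] / n_joint)
    return pd.DataFrame(d, index=bm.sample_ids, columns=bm.sample_ids)


@dataclass
class AmovaResult:
    """AMOVA table (among/within/total rows), Phi, and the n0 coefficient."""

    table: pd.DataFrame
    phi: float
    n0: float
    p_value: float | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = "" if self.p_value is None else f", p = {self.p_value:.4g}"
        return f"AmovaResult(Phi = {self.phi:.7f}{p})\n{self.table}"


def _group_indices(labels: pd.Series) -> list[np.ndarray]:
    codes, _ = pd.factorize(labels)
    return [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]


def _amova_stats(d2: np.ndarray, groups: list[np.ndarray]) -> tuple[float, ...]:
    n = d2.shape[0]
    a = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, k=1).sum() / len(idx)
    ss_among = ss_total - ss_within
    return ss_total, ss_within, ss_among, n, a


def amova_two_level(D: pd.DataFrame, labels: pd.Series,
                    clamp_warn: bool = True) -> AmovaResult:
    """One-level AMOVA (among vs within populations) from a squared-distance
    matrix and population labels aligned to its index."""
    labels = labels.reindex(D.index)
    if labels.isna().any():
        raise StructureError("labels missing for some samples")
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise StructureError("AMOVA needs >=2 populations")
    d2 = D.to_numpy(dtype=float)
    ss_total, ss_within, ss_among, n, a = _amova_stats(d2, groups)

    df_among, df_within, df_total = a - 1, n - a, n - 1
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sizes = np.array([len(g) for g in groups], dtype=float)
    n0 = (n - (sizes ** 2).sum() / n) / (a - 1)
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    if sigma_among < 0:
        if clamp_warn:
            warnings.warn("negative among-population variance clamped to 0",
                          stacklevel=2)
        sigma_among = 0.0
    sigma_total = sigma_among + sigma_within
    phi = 0.0 if sigma_total == 0 else sigma_among / sigma_total

    table = pd.DataFrame(
        {
            "df": [df_among, df_within, df_total],
            "SS": [ss_among, ss_within, ss_total],
            "MS": [ms_among, ms_within, np.nan],
            "sigma2": [sigma_among, sigma_within, sigma_total],
            "pct_var": [100 * phi, 100 * (1 - phi), 100.0],
        },
        index=["among_populations", "within_populations", "total"],
    )
    return AmovaResult(table=table, phi=phi, n0=n0)


def phi_from_components(sigma_among: float, sigma_within: float) -> float:
    """Phi from already-estimated variance components."""
    total = sigma_among + sigma_within
    if total <= 0:
        return 0.0
    return sigma_among / total


def permutation_test_phi(D: pd.DataFrame, labels: pd.Series,
                         n_perm: int = 999, seed: int | None = None):
    """Permutation p-value for Phi: labels shuffled across samples,
    p = (1 + #{Phi_perm >= Phi_obs}) / (1 + n_perm).

    Returns the observed :class:`AmovaResult` (p filled in) and the null
    Phi distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = amova_two_level(D, labels)
    labels = labels.reindex(D.index)
    groups = _group_indices(labels)
    d2 = D.to_numpy(dtype=float)
    n = d2.shape[0]
    sizes = np.array([len(g) for g in groups], dtype=float)
    a = len(groups)
    n0 = (n - (sizes ** 2).sum() / n) / (a - 1)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    perm_codes, _ = pd.factorize(labels)
    for b in range(n_perm):
        perm = rng.permutation(perm_codes)
        g = [np.flatnonzero(perm == c) for c in range(a)]
        _, ss_w, ss_a, _, _ = _amova_stats(d2, g)
        ms_a = ss_a / (a - 1)
        ms_w = ss_w / (n - a)
        s_a = max(0.0, (ms_a - ms_w) / n0)
        null[b] = 0.0 if s_a + ms_w == 0 else s_a / (s_a + ms_w)
    p = (1.0 + np.sum(null >= obs.phi)) / (1.0 + n_perm)
    obs.p_value = float(p)
    return obs, null
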