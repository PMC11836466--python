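"""Synthetic three-taxon datasets with the structure the analyses assume.

The generators emulate a two-parent-plus-hybrid design: two divergent
parental populations (a Japanese-knotweed-like and a giant-knotweed-like
taxon) and a hybrid population whose band frequencies are an admixture
blend of the parents.  Each generator is a pure function of its
configuration and seed, and returns (or stores) the generating ground
truth so downstream estimators can be tested for parameter recovery.

Band presence is simulated independently per band given population
frequencies (the same independence the per-band statistics assume).
Parental band frequencies follow a Balding–Nichols-style model: given an
ancestral frequency ``p0`` and a divergence parameter ``F``, each parent
draws its frequency from ``Beta(p0(1-F)/F, (1-p0)(1-F)/F)``, so larger
``F`` means stronger differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import PRIMER_SEP, BandMatrix, FeatureTable, TraitTable


@dataclass
class PopulationSpec:
    """Generating parameters for one population."""

    name: str
    n_samples: int
    band_freqs: np.ndarray | None = None
    trait_means: np.ndarray | None = None
    trait_cov: np.ndarray | None = None
    feature_log_means: np.ndarray | None = None
    feature_log_sd: np.ndarray | None = None
    #: features structurally absent (exactly zero) in this population
    structural_zero_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError(f"population {self.name!r} has no samples")
        if self.band_freqs is not None:
            f = np.asarray(self.band_freqs, dtype=float)
            if ((f < 0) | (f > 1)).any():
                raise ConfigError("band frequencies outside [0, 1]")
            self.band_freqs = f
        if self.trait_cov is not None:
            c = np.asarray(self.trait_cov, dtype=float)
            if not np.allclose(c, c.T):
                raise ConfigError("trait covariance not symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ConfigError("trait covariance not positive semi-definite")
            self.trait_cov = c
        if self.feature_log_sd is not None:
            sd = np.asarray(self.feature_log_sd, dtype=float)
            if (sd < 0).any():
                raise ConfigError("negative feature log-sd")
            self.feature_log_sd = sd


@dataclass
class SyntheticConfig:
    """Full design: two parents, a hybrid, noise rates, and a seed."""

    parent_a: PopulationSpec
    parent_b: PopulationSpec
    n_hybrids: int = 7
    hybrid_name: str = "RB"
    #: fraction of parent-A ancestry in the hybrid blend
    hybrid_admixture_alpha: float = 0.55
    #: "blend" draws each hybrid band from the frequency mixture;
    #: "mosaic" draws a parental ancestry per band per individual
    hybrid_mode: str = "blend"
    clonal_duplicate_rate: float = 0.0
    flip_noise: float = 0.0
    seed: int = 0
    trait_names: tuple[str, ...] = ()
    feature_names: tuple[str, ...] = ()
    #: primer id per band (defines primer grouping of the band matrix)
    band_primers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, val in [("hybrid_admixture_alpha", self.hybrid_admixture_alpha),
                          ("clonal_duplicate_rate", self.clonal_duplicate_rate),
                          ("flip_noise", self.flip_noise)]:
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if self.n_hybrids < 1:
            raise ConfigError("hybrid population has no samples")
        if self.hybrid_mode not in ("blend", "mosaic"):
            raise ConfigError(f"unknown hybrid_mode {self.hybrid_mode!r}")

    @property
    def population_names(self) -> list[str]:
        return [self.parent_a.name, self.hybrid_name, self.parent_b.name]


def _sample_ids(cfg: SyntheticConfig) -> dict[str, list[str]]:
    out = {}
    for name, n in [(cfg.parent_a.name, cfg.parent_a.n_samples),
                    (cfg.hybrid_name, cfg.n_hybrids),
                    (cfg.parent_b.name, cfg.parent_b.n_samples)]:
        out[name] = [f"{name}{i + 1}" for i in range(n)]
    return out


def simulate_band_matrix(cfg: SyntheticConfig):
    """Draw a band matrix; returns ``(BandMatrix, truth)``.

    ``truth`` holds the generating per-population frequencies (the hybrid's
    blended frequency included) and the admixture fraction, for
    parameter-recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    f_a = cfg.parent_a.band_freqs
    f_b = cfg.parent_b.band_freqs
    if f_a is None or f_b is None or len(f_a) != len(f_b):
        raise ConfigError("both parents need band_freqs of equal length")
    n_bands = len(f_a)
    alpha = cfg.hybrid_admixture_alpha
    f_h = alpha * f_a + (1.0 - alpha) * f_b

    primers = cfg.band_primers or tuple("P1" for _ in range(n_bands))
    if len(primers) != n_bands:
        raise ConfigError("band_primers length mismatch")
    counters: dict[str, int] = {}
    band_ids = []
    for p in primers:
        counters[p] = counters.get(p, 0) + 1
        band_ids.append(f"{p}{PRIMER_SEP}b{counters[p]}")

    ids = _sample_ids(cfg)
    rows, labels, index = [], [], []
    for name, freqs in [(cfg.parent_a.name, f_a),
                        (cfg.hybrid_name, f_h),
                        (cfg.parent_b.name, f_b)]:
        block = []
        for sid in ids[name]:
            if name == cfg.hybrid_name and cfg.hybrid_mode == "mosaic":
                take_a = rng.random(n_bands) < alpha
                probs = np.where(take_a, f_a, f_b)
            else:
                probs = freqs
            row = (rng.random(n_bands) < probs).astype(float)
            # clonal near-duplicates: copy an earlier row of the same
            # population, then apply per-cell flip noise to the copy
            if block and rng.random() < cfg.clonal_duplicate_rate:
                row = block[rng.integers(len(block))].copy()
                flips = rng.random(n_bands) < cfg.flip_noise
                row[flips] = 1.0 - row[flips]
            block.append(row)
            index.append(sid)
            labels.append(name)
        rows.extend(block)

    values = pd.DataFrame(np.vstack(rows), index=index, columns=band_ids)
    populations = pd.Series(labels, index=index)
    truth = {
        "band_freqs": {cfg.parent_a.name: f_a, cfg.hybrid_name: f_h,
                       cfg.parent_b.name: f_b},
        "alpha": alpha,
    }
    return BandMatrix(values, populations), truth


def simulate_morphology(cfg: SyntheticConfig) -> TraitTable:
    """Multivariate-normal leaf traits per taxon; the hybrid's mean and
    covariance are the admixture blend of the parents.  Values are
    truncated at zero (all defaults are length traits)."""
    m_a, m_b = cfg.parent_a.trait_means, cfg.parent_b.trait_means
    c_a, c_b = cfg.parent_a.trait_cov, cfg.parent_b.trait_cov
    if m_a is None or m_b is None or c_a is None or c_b is None:
        raise ConfigError("both parents need trait_means and trait_cov")
    if len(m_a) != len(m_b):
        raise ConfigError("trait dimensions differ between parents")
    alpha = cfg.hybrid_admixture_alpha
    m_h = alpha * np.asarray(m_a) + (1 - alpha) * np.asarray(m_b)
    c_h = alpha * np.asarray(c_a) + (1 - alpha) * np.asarray(c_b)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    ids = _sample_ids(cfg)
    names = cfg.trait_names or tuple(f"trait{i + 1}" for i in range(len(m_a)))
    rows, labels, index = [], [], []
    for name, mean, cov, sids in [
        (cfg.parent_a.name, m_a, c_a, ids[cfg.parent_a.name]),
        (cfg.hybrid_name, m_h, c_h, ids[cfg.hybrid_name]),
        (cfg.parent_b.name, m_b, c_b, ids[cfg.parent_b.name]),
    ]:
        draw = rng.multivariate_normal(mean, cov, size=len(sids),
                                       method="svd")
        rows.append(np.clip(draw, 0.0, None))
        labels += [name] * len(sids)
        index += sids
    data = pd.DataFrame(np.vstack(rows), index=index, columns=list(names))
    return TraitTable(data, pd.Series(labels, index=index))


def simulate_feature_table(cfg: SyntheticConfig) -> FeatureTable:
    """Log-normal metabolite intensities per taxon, with taxon-specific
    structural zeros (a feature masked in a population is exactly 0 for
    every sample of that population; the hybrid inherits only the zeros
    shared by both parents)."""
    lm_a, lm_b = cfg.parent_a.feature_log_means, cfg.parent_b.feature_log_means
    ls_a, ls_b = cfg.parent_a.feature_log_sd, cfg.parent_b.feature_log_sd
    if lm_a is None or lm_b is None or ls_a is None or ls_b is None:
        raise ConfigError("both parents need feature_log_means and feature_log_sd")
    n_feat = len(lm_a)
    z_a = (np.zeros(n_feat, bool) if cfg.parent_a.structural_zero_mask is None
           else np.asarray(cfg.parent_a.structural_zero_mask, bool))
    z_b = (np.zeros(n_feat, bool) if cfg.parent_b.structural_zero_mask is None
           else np.asarray(cfg.parent_b.structural_zero_mask, bool))
    alpha = cfg.hybrid_admixture_alpha
    lm_h = alpha * np.asarray(lm_a) + (1 - alpha) * np.asarray(lm_b)
    ls_h = alpha * np.asarray(ls_a) + (1 - alpha) * np.asarray(ls_b)
    z_h = z_a & z_b

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    ids = _sample_ids(cfg)
    names = cfg.feature_names or tuple(f"feat{i + 1}" for i in range(n_feat))
    rows, labels, index = [], [], []
    for name, lm, ls, mask, sids in [
        (cfg.parent_a.name, lm_a, ls_a, z_a, ids[cfg.parent_a.name]),
        (cfg.hybrid_name, lm_h, ls_h, z_h, ids[cfg.hybrid_name]),
        (cfg.parent_b.name, lm_b, ls_b, z_b, ids[cfg.parent_b.name]),
    ]:
        draw = np.exp(np.asarray(lm) + np.asarray(ls) * rng.standard_normal(
            (len(sids), n_feat)))
        draw[:, np.asarray(mask, bool)] = 0.0
        rows.append(draw)
        labels += [name] * len(sids)
        index += sids
    data = pd.DataFrame(np.vstack(rows), index=index, columns=list(names))
    return FeatureTable(data, pd.Series(labels, index=index))


def balding_nichols_freqs(n_bands: int, divergence: float, seed: int,
                          ancestral_range: tuple[float, float] = (0.05, 0.95)):
    """Draw ancestral frequencies and two diverged parental frequency
    vectors (Balding–Nichols Beta model with parameter ``divergence``)."""
    if not 0.0 < divergence < 1.0:
        raise ConfigError("divergence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(*ancestral_range, size=n_bands)
    scale = (1.0 - divergence) / divergence
    f_a = rng.beta(p0 * scale, (1 - p0) * scale)
    f_b = rng.beta(p0 * scale, (1 - p0) * scale)
    return p0, np.clip(f_a, 0.0, 1.0), np.clip(f_b, 0.0, 1.0)


#: six leaf morphometric characters (mm), mirroring the field's usual set
DEFAULT_TRAIT_NAMES = ("blade_length", "blade_width", "apex_length",
                       "apex_width", "base_width", "petiolar_sinus")


def default_config(seed: int = 0, n_per_primer: int = 17,
                   primers_per_system: int = 9,
                   divergence: float = 0.35,
                   n_features: int = 117,
                   scale: int = 1) -> SyntheticConfig:
    """Desk-scale preset mirroring the study design: 5 + 7 + 3 accessions,
    two marker systems (SCoT-like and SRAP-like) of nine primers each with
    ~17 bands per primer, six leaf traits, and 117 metabolite features with
    a piceid-like structural zero in the giant-knotweed-like parent.

    ``scale`` multiplies every population size (for large-n recovery tests).
    """
    primers = tuple(
        f"{sys}{i + 1}"
        for sys in ("SCoT", "SRAP")
        for i in range(primers_per_system)
        for _ in range(n_per_primer)
    )
    n_bands = len(primers)
    _, f_a, f_b = balding_nichols_freqs(n_bands, divergence, seed)

    # leaf morphometry (mm): giant knotweed has much larger blades; apex
    # characters share one mean across taxa (they do not discriminate)
    m_a = np.array([150.0, 100.0, 30.0, 25.0, 60.0, 5.0])    # japonica-like
    m_b = np.array([400.0, 250.0, 30.0, 25.0, 150.0, 25.0])  # sachalinensis-like
    cov_a = np.diag((0.12 * m_a) ** 2)
    cov_b = np.diag((0.12 * m_b) ** 2)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    lm_a = rng.normal(1.0, 1.0, size=n_features)
    lm_b = lm_a.copy()
    sig = rng.permutation(n_features)
    lm_b[sig[:15]] += 2.0     # signature features of the B parent
    lm_b[sig[15:30]] -= 2.0   # signature features of the A parent
    z_b = np.zeros(n_features, bool)
    z_b[sig[30:33]] = True    # piceid-like: absent in the B parent only
    log_sd = np.full(n_features, 0.4)

    parent_a = PopulationSpec(
        name="RJ", n_samples=5 * scale, band_freqs=f_a,
        trait_means=m_a, trait_cov=cov_a,
        feature_log_means=lm_a, feature_log_sd=log_sd,
        structural_zero_mask=np.zeros(n_features, bool))
    parent_b = PopulationSpec(
        name="RS", n_samples=3 * scale, band_freqs=f_b,
        trait_means=m_b, trait_cov=cov_b,
        feature_log_means=lm_b, feature_log_sd=log_sd,
        structural_zero_mask=z_b)
    return SyntheticConfig(
        parent_a=parent_a, parent_b=parent_b, n_hybrids=7 * scale,
        hybrid_name="RB", hybrid_admixture_alpha=0.55, seed=seed,
        trait_names=DEFAULT_TRAIT_NAMES,
        feature_names=tuple(f"feat{i + 1}" for i in range(n_features)),
        band_primers=primers)


@dataclass
class StructureRuns:
    """Replicate log-likelihoods lnP(D) per K from structure inference."""

    k_values: np.ndarray
    #: shape (n_K, n_replicates)
    logliks: np.ndarray

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.logliks = np.atleast_2d(np.asarray(self.logliks, dtype=float))
        if self.logliks.shape[0] != len(self.k_values):
            raise ConfigError("logliks rows must match k_values")
        if np.any(np.diff(self.k_values) != 1):
            raise ConfigError("k_values must be consecutive integers")

    @property
    def n_replicates(self) -> int:
        return self.logliks.shape[1]

    def to_frame(self) -> pd.DataFrame:
        recs = [(k, r + 1, self.logliks[i, r])
                for i, k in enumerate(self.k_values)
                for r in range(self.n_replicates)]
        return pd.DataFrame(recs, columns=["K", "replicate", "lnP(D)"])

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StructureRuns":
        wide = frame.pivot(index="K", columns="replicate", values="lnP(D)")
        return cls(wide.index.to_numpy(), wide.to_numpy())

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "StructureRuns":
        return cls.from_frame(pd.read_csv(path, sep=sep))


def simulate_structure_likelihoods(
    true_k: int,
    k_range: tuple[int, int] = (1, 10),
    replicates: int = 10,
    noise_sd: float = 50.0,
    seed: int = 0,
    base: float = -8000.0,
    rise: float = 400.0,
    plateau: float = 20.0,
) -> StructureRuns:
    """Piecewise-linear mean lnP(D) with a knee at ``true_k`` (steep rise
    of ``rise`` per K below the knee, gentle ``plateau`` slope above) plus
    Gaussian replicate noise."""
    lo, hi = k_range
    if not lo < true_k < hi:
        raise ConfigError("true_k must lie strictly inside k_range")
    if replicates < 2:
        raise ConfigError("need >=2 replicates for a defined Evanno ΔK")
    ks = np.arange(lo, hi + 1)
    mean = base + rise * np.minimum(ks, true_k) + plateau * np.maximum(ks - true_k, 0)
    rng = np.random.default_rng(seed)
    logliks = mean[:, None] + rng.normal(0.0, noise_sd, size=(len(ks), replicates))
    return StructureRuns(ks, logliks)
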