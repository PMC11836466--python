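"""Per-population diversity indices and Nei differentiation for dominant markers.

Each scored band is treated as a biallelic locus.  In ``raw`` mode the band
presence frequency itself is taken as the allele frequency p (phenotype
frequency); in ``hwe`` mode the null-allele frequency is inferred assuming
Hardy–Weinberg proportions, q = sqrt(1 − p_band), p = 1 − q.  Per locus:

* Na = number of alleles with non-zero frequency (1 or 2)
* Ne = 1 / (p² + q²)                 (effective number of alleles)
* H  = 1 − (p² + q²) = 2pq           (Nei gene diversity)
* I  = −p·ln p − q·ln q              (Shannon information, 0·ln 0 = 0)

Shannon's index is reported both as the per-locus mean and as the
per-population sum over loci: only the sum scale can exceed ln 2 per
population, and published tables use either convention without saying so.

Differentiation follows Nei: HS is the mean within-population diversity,
HT the diversity of the averaged allele frequencies, GST = (HT − HS)/HT,
and gene flow is estimated as Nm = ((1/GST) − 1)/4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructureError
from .io import BandMatrix
from .markers import band_frequencies


def allele_freq_from_dominant(p_band, mode: str = "raw"):
    """Allele frequencies (p, q) from a dominant band-presence frequency."""
    arr = np.asarray(p_band, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("band frequency outside [0, 1]")
    if mode == "raw":
        p = arr
    elif mode == "hwe":
        q = np.sqrt(1.0 - arr)
        p = 1.0 - q
    else:
        raise ValueError(f"unknown allele-frequency mode {mode!r}")
    q = 1.0 - p
    if arr.ndim:
        return p, q
    return float(p), float(q)


def locus_indices(p, q=None):
    """(Na, Ne, H, I) for a biallelic locus with allele frequencies p, q."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p if q is None else np.asarray(q, dtype=float)
    if not np.allclose(p + q, 1.0):
        raise ValueError("allele frequencies must sum to 1")
    na = (p > 0).astype(float) + (q > 0).astype(float)
    homo = p ** 2 + q ** 2
    ne = 1.0 / homo
    h = 1.0 - homo
    with np.errstate(divide="ignore", invalid="ignore"):
        i = -np.where(p > 0, p * np.log(p), 0.0) - np.where(q > 0, q * np.log(q), 0.0)
    if p.ndim:
        return na, ne, h, i
    return float(na), float(ne), float(h), float(i)


@dataclass
class DiversitySummary:
    """Per-population indices plus the panel-level Nei decomposition."""

    per_population: pd.DataFrame
    ht: float
    hs: float
    gst: float
    nm: float


def population_diversity(bm: BandMatrix, mode: str = "raw") -> pd.DataFrame:
    """Per-population table of Na, Ne, H, I (mean and sum), NPL and PPL.

    Loci with no non-missing observation in a population are skipped for
    that population (complete-case per locus).  A population of one sample
    is computed with a warning: its frequencies are degenerate.
    """
    rows = []
    for pop, sids in bm.populations.groupby(bm.populations).groups.items():
        sids = list(sids)
        if len(sids) == 1:
            warnings.warn(f"population {pop!r} has a single sample; "
                          "frequencies are degenerate", stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_band = band_frequencies(bm, sids).p.dropna()
        p, q = allele_freq_from_dominant(p_band.to_numpy(), mode)
        na, ne, h, i = locus_indices(p, q)
        npl = int(np.sum((p_band > 0) & (p_band < 1)))
        rows.append({
            "population": pop, "n_samples": len(sids), "n_loci": len(p_band),
            "Na": float(np.mean(na)), "Ne": float(np.mean(ne)),
            "H": float(np.mean(h)), "I_mean": float(np.mean(i)),
            "I_sum": float(np.sum(i)), "NPL": npl,
            "PPL": 100.0 * npl / len(p_band) if len(p_band) else np.nan,
        })
    return pd.DataFrame(rows).set_index("population")


def gst_nei(bm: BandMatrix, mode: str = "raw",
            weighting: str = "equal") -> tuple[float, float, float]:
    """Nei's (HT, HS, GST) over all loci.

    HS averages per-population H per locus, HT is the H of the averaged
    allele frequencies; both are then averaged over loci.  ``weighting``
    is ``equal`` (default: populations weighted equally, the study's sizes
    being unequal and the convention unstated) or ``size``.
    """
    pops = bm.populations.unique()
    if len(pops) < 2:
        raise StructureError("GST needs >=2 populations")
    if weighting not in ("equal", "size"):
        raise ValueError(f"unknown weighting {weighting!r}")
    freqs, weights = [], []
    for pop in pops:
        sids = bm.populations.index[bm.populations == pop].tolist()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_band = band_frequencies(bm, sids).p
        p, _ = allele_freq_from_dominant(np.clip(p_band.to_numpy(), 0, 1), mode)
        freqs.append(p)
        weights.append(len(sids))
    freqs = np.vstack(freqs)  # pops x loci, NaN where unobserved
    w = np.asarray(weights, float) if weighting == "size" else np.ones(len(pops))
    w = w / w.sum()
    keep = ~np.isnan(freqs).any(axis=0)  # complete-case loci
    freqs = freqs[:, keep]
    hs_locus = (w[:, None] * (2.0 * freqs * (1.0 - freqs))).sum(axis=0)
    pbar = (w[:, None] * freqs).sum(axis=0)
    ht_locus = 2.0 * pbar * (1.0 - pbar)
    hs = float(np.mean(hs_locus))
    ht = float(np.mean(ht_locus))
    gst = 0.0 if ht == 0.0 else (ht - hs) / ht
    return ht, hs, gst


def gene_flow_nm(gst: float) -> float:
    """Gene flow Nm = ((1/GST) − 1)/4; infinite (with warning) at GST <= 0."""
    if gst <= 0.0:
        warnings.warn("GST <= 0: gene flow undefined, returning inf",
                      stacklevel=2)
        return float("inf")
    if gst > 1.0:
        raise ValueError(f"GST outside (0, 1]: {gst}")
    return ((1.0 / gst) - 1.0) / 4.0


def diversity_summary(bm: BandMatrix, mode: str = "raw",
                      weighting: str = "equal") -> DiversitySummary:
    """Full per-population and panel-level diversity report."""
    per_pop = population_diversity(bm, mode)
    ht, hs, gst = gst_nei(bm, mode, weighting)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nm = gene_flow_nm(gst)
    return DiversitySummary(per_pop, ht=ht, hs=hs, gst=gst, nm=nm)
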