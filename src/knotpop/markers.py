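"""Per-primer and panel-level marker informativeness.

For a dominant (presence/absence) band with presence frequency ``p``:

* PIC  = 1 − (p² + q²), q = 1 − p   (maximum 0.5 at p = 0.5)
* Ib   = 1 − 2·|0.5 − p|            (band informativeness, in [0, 1])
* Rp   = Σ Ib over a primer's bands (resolving power)

A band is polymorphic under the strict criterion iff 0 < p < 1; an
optional 95% criterion additionally discards bands with p > 0.95 or
p < 0.05.  Frequencies are computed over non-missing entries only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BandMatrix

TOTAL_ROW = "Total"
MEAN_ROW = "Mean"

_COLS = ["total_bands", "polymorphic_bands", "pct_polymorphic",
         "resolving_power", "mean_pic"]


@dataclass
class FrequencyVector:
    """Per-band presence frequency and non-missing counts over a sample set."""

    p: pd.Series
    n_obs: pd.Series


def band_frequencies(bm: BandMatrix,
                     subset: list[str] | None = None) -> FrequencyVector:
    """Presence frequency p_k = (# present)/(# non-missing) per band.

    Bands with zero non-missing observations in the subset get NaN
    frequency and are flagged with a warning.
    """
    values = bm.values if subset is None else bm.values.loc[subset]
    if values.shape[0] == 0:
        raise ValueError("empty sample subset")
    n_obs = values.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = n_obs.index[n_obs == 0].tolist()
        warnings.warn(f"bands with no observations in subset: {empty[:5]}",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        p = values.sum(axis=0, skipna=True) / n_obs
    return FrequencyVector(p=p, n_obs=n_obs)


def _check_domain(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    ok = np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0))
    if not ok.all():
        raise ValueError(f"frequency outside [0, 1]: {arr[~ok][:5]}")
    return arr


def pic_dominant(p):
    """Polymorphism information content 1 − (p² + q²) for a two-state band."""
    arr = _check_domain(p)
    out = 1.0 - (arr ** 2 + (1.0 - arr) ** 2)
    return out if out.ndim else float(out)


def band_informativeness(p):
    """Band informativeness Ib = 1 − 2·|0.5 − p|."""
    arr = _check_domain(p)
    out = 1.0 - 2.0 * np.abs(0.5 - arr)
    return out if out.ndim else float(out)


def is_polymorphic(p, criterion: str = "strict"):
    """Polymorphism indicator per band frequency.

    ``strict``: any variation (0 < p < 1); ``p95``: additionally requires
    0.05 <= p <= 0.95.
    """
    arr = _check_domain(p)
    strict = (arr > 0.0) & (arr < 1.0)
    if criterion == "strict":
        out = strict
    elif criterion == "p95":
        out = strict & (arr >= 0.05) & (arr <= 0.95)
    else:
        raise ValueError(f"unknown polymorphism criterion {criterion!r}")
    return out if out.ndim else bool(out)


def resolving_power(bm: BandMatrix, primer_id: str) -> float:
    """Rp = sum of Ib over the primer's bands, frequencies over all samples."""
    bands = bm.bands_of(primer_id)  # KeyError for unknown primer
    p = band_frequencies(bm).p[bands].dropna()
    return float(np.sum(band_informativeness(p)))


def primer_summary(bm: BandMatrix, criterion: str = "strict",
                   pic_over: str = "all") -> pd.DataFrame:
    """Per-primer informativeness table: total and polymorphic band counts,
    fraction polymorphic, resolving power, and mean PIC.

    ``pic_over`` selects whether mean PIC averages all bands (default) or
    polymorphic bands only.
    """
    if pic_over not in ("all", "polymorphic"):
        raise ValueError(f"unknown pic_over {pic_over!r}")
    freqs = band_frequencies(bm).p
    rows = []
    for primer in bm.primer_ids:
        p = freqs[bm.bands_of(primer)].dropna()
        poly = is_polymorphic(p, criterion)
        pic = pic_dominant(p if pic_over == "all" else p[poly])
        rows.append({
            "primer": primer,
            "total_bands": len(p),
            "polymorphic_bands": int(np.sum(poly)),
            "pct_polymorphic": float(np.mean(poly)) if len(p) else np.nan,
            "resolving_power": float(np.sum(band_informativeness(p))),
            "mean_pic": float(np.mean(pic)) if np.size(pic) else 0.0,
        })
    return pd.DataFrame(rows).set_index("primer")[_COLS]


def panel_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Append the panel ``Total`` (column sums of counts and Rp) and
    ``Mean`` (column means) rows to a per-primer stats table."""
    stats = stats[_COLS]
    total = pd.Series(
        {"total_bands": stats["total_bands"].sum(),
         "polymorphic_bands": stats["polymorphic_bands"].sum(),
         "pct_polymorphic": np.nan,
         "resolving_power": stats["resolving_power"].sum(),
         "mean_pic": np.nan},
        name=TOTAL_ROW)
    mean = stats.mean(axis=0)
    mean.name = MEAN_ROW
    return pd.concat([stats, total.to_frame().T, mean.to_frame().T])
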