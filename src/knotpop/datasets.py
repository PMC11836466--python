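"""Bundled reference tables for the three-taxon knotweed study design.

Three small published summary tables are shipped as module data so the
desk-scale analyses can run with no downloads:

* the mean content (mg per g dry extract) of six quantified rhizome
  metabolites across the 15 accessions (five *R. japonica* "RJ", seven
  *R. × bohemica* "RB", three *R. sachalinensis* "RS") — note the
  structural zeros: piceid and resveratrol are below detection in all
  *R. sachalinensis* rhizomes;
* the per-primer informativeness summary of the nine SCoT and nine SRAP
  marker panels (band counts, polymorphism, resolving power, mean PIC);
* the estimated AMOVA variance components for the combined and
  per-marker-system analyses.
"""

from __future__ import annotations

import pandas as pd

from .io import FeatureTable

SAMPLES = ["RJ2", "RJ5", "RJ6", "RJ10", "RJ31",
           "RB12", "RB13", "RB14", "RB15", "RB17", "RB18", "RB20",
           "RS21", "RS22", "RS23"]

POPULATIONS = pd.Series(
    ["RJ"] * 5 + ["RB"] * 7 + ["RS"] * 3, index=SAMPLES, name="population")

_COMPOUNDS = {
    "piceid": [36.98, 72.87, 26.40, 36.18, 33.55, 19.69, 26.19, 25.53,
               8.76, 10.84, 22.70, 12.16, 0.00, 0.00, 0.00],
    "resveratrol": [1.66, 1.35, 0.40, 0.76, 1.65, 0.98, 0.59, 1.13,
                    0.18, 0.29, 1.49, 0.50, 0.00, 0.00, 0.00],
    "vanicoside_a": [0.44, 0.30, 0.80, 0.21, 0.33, 0.76, 0.17, 0.81,
                     0.37, 1.16, 1.01, 0.67, 2.31, 0.71, 1.16],
    "vanicoside_b": [4.70, 4.37, 7.12, 2.53, 5.39, 9.12, 1.91, 8.40,
                     4.97, 11.07, 9.83, 5.57, 14.73, 6.70, 10.01],
    "emodin": [13.30, 5.97, 2.07, 4.24, 2.07, 1.92, 2.06, 2.71,
               0.77, 2.77, 1.70, 4.64, 0.55, 0.34, 0.71],
    "physcion": [8.03, 6.93, 2.16, 4.02, 2.09, 2.12, 3.46, 3.63,
                 1.03, 2.90, 1.90, 5.67, 0.62, 0.53, 0.52],
}


def quantified_compounds() -> FeatureTable:
    """15 x 6 mean-content matrix of the quantified rhizome metabolites."""
    data = pd.DataFrame(_COMPOUNDS, index=SAMPLES)
    return FeatureTable(data, POPULATIONS.copy())


_PRIMER_ROWS = {
    # primer: (total_bands, polymorphic_bands, pct_polymorphic,
    #          resolving_power, mean_pic)
    "SCoT1": (22, 20, 0.91, 12.50, 0.352),
    "SCoT2": (19, 17, 0.89, 7.38, 0.262),
    "SCoT7": (16, 12, 0.75, 3.88, 0.177),
    "SCoT13": (18, 16, 0.89, 7.38, 0.290),
    "SCoT15": (10, 7, 0.70, 2.88, 0.202),
    "SCoT16": (17, 15, 0.88, 7.63, 0.306),
    "SCoT24": (13, 11, 0.85, 5.75, 0.300),
    "SCoT26": (16, 13, 0.81, 4.88, 0.229),
    "SCoT32": (14, 14, 1.00, 5.50, 0.277),
    "SRAP11": (15, 14, 0.93, 8.25, 0.349),
    "SRAP15": (19, 17, 0.89, 7.13, 0.271),
    "SRAP22": (16, 13, 0.81, 6.25, 0.267),
    "SRAP23": (15, 13, 0.87, 5.13, 0.241),
    "SRAP25": (17, 15, 0.88, 7.75, 0.306),
    "SRAP32": (19, 17, 0.89, 9.88, 0.340),
    "SRAP35": (16, 15, 0.94, 5.50, 0.235),
    "SRAP43": (20, 19, 0.95, 8.63, 0.302),
    "SRAP45": (15, 12, 0.80, 4.50, 0.226),
}


def primer_informativeness(system: str | None = None) -> pd.DataFrame:
    """Published per-primer informativeness rows; ``system`` filters to
    ``"SCoT"`` or ``"SRAP"``."""
    df = pd.DataFrame.from_dict(
        _PRIMER_ROWS, orient="index",
        columns=["total_bands", "polymorphic_bands", "pct_polymorphic",
                 "resolving_power", "mean_pic"])
    df.index.name = "primer"
    if system is not None:
        df = df[df.index.str.startswith(system)]
        if df.empty:
            raise KeyError(f"unknown marker system {system!r}")
    return df


#: published estimated AMOVA variance components (among, within populations)
AMOVA_VARIANCE_COMPONENTS = pd.DataFrame(
    {
        "sigma2_among": [24.43719, 11.73301, 12.70418],
        "sigma2_within": [27.60073, 13.11355, 14.48718],
    },
    index=["combined", "SCoT", "SRAP"],
)
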