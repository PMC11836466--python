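"""Reading, validation, and alignment of the three evidence layers.

The pipeline integrates three tables over a shared set of accessions:

* a binary band matrix (dominant molecular markers such as SCoT/SRAP,
  scored 1 = band present, 0 = absent, with explicit missing values),
* a continuous leaf-morphometry table, and
* a non-negative metabolite intensity/content table.

All three are plain delimited text.  Band columns carry their primer in the
column name as ``"PRIMER::band"`` unless an explicit primer map is given.
Missing scores are kept as missing (``NaN``) — absence of a band is data,
absence of a score is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, IdentityError

#: tokens accepted as missing on read
MISSING_TOKENS = ("NA", "na", "?", "")

#: separator between primer id and band id in flat column names
PRIMER_SEP = "::"

#: reserved (non-band, non-trait) column name holding population labels
POPULATION_COLUMN = "population"


@dataclass(frozen=True)
class SampleRecord:
    """One accession: its identifier, population label, and free metadata."""

    sample_id: str
    population: str
    metadata: dict = field(default_factory=dict)


def _check_unique_samples(index: pd.Index) -> None:
    dup = index[index.duplicated()].unique().tolist()
    if dup:
        raise IdentityError(f"duplicate sample id(s): {dup}")


@dataclass
class BandMatrix:
    """Samples x bands presence/absence matrix with primer grouping.

    ``values`` is a float DataFrame with entries in {0.0, 1.0, NaN}, indexed
    by sample id; ``populations`` maps sample id -> population label;
    ``primer_map`` maps band id -> primer id.
    """

    values: pd.DataFrame
    populations: pd.Series
    primer_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique_samples(self.values.index)
        if self.values.shape[0] < 2 or self.values.shape[1] < 1:
            raise FormatError(
                f"band matrix needs >=2 samples and >=1 band, got {self.values.shape}"
            )
        vals = self.values.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary cell at sample {self.values.index[i]!r}, "
                f"band {self.values.columns[j]!r}: {vals[i, j]!r}"
            )
        if not self.primer_map:
            self.primer_map = {b: _primer_of(b) for b in self.values.columns}
        missing = [b for b in self.values.columns if b not in self.primer_map]
        if missing:
            raise FormatError(f"bands with no primer assignment: {missing[:5]}")
        self.populations = self.populations.reindex(self.values.index)
        if self.populations.isna().any():
            lost = self.populations.index[self.populations.isna()].tolist()
            raise IdentityError(f"samples with no population label: {lost}")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def band_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def primer_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.values.columns:
            seen.setdefault(self.primer_map[b], None)
        return list(seen)

    def bands_of(self, primer_id: str) -> list[str]:
        bands = [b for b in self.values.columns if self.primer_map[b] == primer_id]
        if not bands:
            raise KeyError(f"unknown primer {primer_id!r}")
        return bands

    def subset_samples(self, sample_ids: list[str]) -> "BandMatrix":
        unknown = [s for s in sample_ids if s not in self.values.index]
        if unknown:
            raise IdentityError(f"unknown sample id(s): {unknown}")
        return BandMatrix(
            self.values.loc[sample_ids].copy(),
            self.populations.loc[sample_ids].copy(),
            dict(self.primer_map),
        )

    def subset_primers(self, primer_ids: list[str]) -> "BandMatrix":
        bands = [b for p in primer_ids for b in self.bands_of(p)]
        return BandMatrix(
            self.values[bands].copy(),
            self.populations.copy(),
            {b: self.primer_map[b] for b in bands},
        )

    # -- round-trip ------------------------------------------------------
    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        """Write the flat dialect read back by :func:`read_band_matrix`."""
        out = self.values.copy()
        out.columns = [
            b if PRIMER_SEP in b else f"{self.primer_map[b]}{PRIMER_SEP}{b}"
            for b in out.columns
        ]
        out.insert(0, POPULATION_COLUMN, self.populations)
        out.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA",
                   float_format="%.0f")


def _primer_of(band_id: str) -> str:
    if PRIMER_SEP not in band_id:
        raise FormatError(
            f"band id {band_id!r} lacks the '{PRIMER_SEP}' primer prefix and "
            "no primer map was given"
        )
    return band_id.split(PRIMER_SEP, 1)[0]


def read_band_matrix(
    path: str | Path,
    sep: str = ",",
    missing_tokens: tuple[str, ...] = MISSING_TOKENS,
    primer_map: dict[str, str] | None = None,
) -> BandMatrix:
    """Read a flat band-matrix file: sample ids in the first column, a
    ``population`` column, then one column per band (``PRIMER::band``)."""
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    _check_unique_samples(raw.index)
    if POPULATION_COLUMN not in raw.columns:
        raise FormatError(f"missing required column {POPULATION_COLUMN!r}")
    populations = raw.pop(POPULATION_COLUMN)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for sid, tok in raw[col].items():
            tok = tok.strip()
            if tok in missing_tokens:
                values.at[sid, col] = np.nan
            elif tok in ("0", "1"):
                values.at[sid, col] = float(tok)
            else:
                raise FormatError(
                    f"non-binary cell at sample {sid!r}, band {col!r}: {tok!r}"
                )
    return BandMatrix(values, populations, dict(primer_map or {}))


@dataclass
class TraitTable:
    """Continuous morphometric characters (mm or ratios) per specimen,
    with optional categorical columns (e.g. trichome class)."""

    data: pd.DataFrame
    populations: pd.Series
    categorical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique_samples(self.data.index)
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise FormatError("non-finite trait value")
        self.populations = self.populations.reindex(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, sample_ids: list[str]) -> "TraitTable":
        cat = None if self.categorical is None else self.categorical.loc[sample_ids]
        return TraitTable(self.data.loc[sample_ids].copy(),
                          self.populations.loc[sample_ids].copy(), cat)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        out = self.data.copy()
        out.insert(0, POPULATION_COLUMN, self.populations)
        if self.categorical is not None:
            out = out.join(self.categorical)
        out.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")


def read_trait_table(path: str | Path, sep: str = ",",
                     categorical: list[str] | None = None) -> TraitTable:
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    _check_unique_samples(raw.index)
    if POPULATION_COLUMN not in raw.columns:
        raise FormatError(f"missing required column {POPULATION_COLUMN!r}")
    populations = raw.pop(POPULATION_COLUMN)
    cat = None
    if categorical:
        cat = raw[categorical].copy()
        raw = raw.drop(columns=categorical)
    return TraitTable(raw.astype(float), populations, cat)


@dataclass
class FeatureTable:
    """Non-negative metabolite intensities or contents per specimen."""

    data: pd.DataFrame
    populations: pd.Series

    def __post_init__(self) -> None:
        _check_unique_samples(self.data.index)
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate feature names")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise FormatError("negative feature intensity")
        self.populations = self.populations.reindex(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, sample_ids: list[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[sample_ids].copy(),
                            self.populations.loc[sample_ids].copy())

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        out = self.data.copy()
        out.insert(0, POPULATION_COLUMN, self.populations)
        out.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")


def read_feature_table(path: str | Path, sep: str = ",") -> FeatureTable:
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    _check_unique_samples(raw.index)
    if POPULATION_COLUMN not in raw.columns:
        raise FormatError(f"missing required column {POPULATION_COLUMN!r}")
    populations = raw.pop(POPULATION_COLUMN)
    return FeatureTable(raw.astype(float), populations)


@dataclass
class AlignmentReport:
    """Samples dropped from each layer while aligning on the shared set."""

    shared: list[str]
    dropped: dict[str, list[str]]


def align_layers(
    band: BandMatrix | None = None,
    traits: TraitTable | None = None,
    features: FeatureTable | None = None,
):
    """Reorder all provided layers to the lexicographically sorted
    intersection of their sample ids.

    Returns the aligned layers (``None`` where the input was ``None``)
    followed by an :class:`AlignmentReport`.  Idempotent.
    """
    layers = {"band": band, "traits": traits, "features": features}
    present = {k: v for k, v in layers.items() if v is not None}
    if not present:
        raise AlignmentError("no layers given")
    shared: set[str] | None = None
    for layer in present.values():
        ids = set(layer.sample_ids)
        shared = ids if shared is None else shared & ids
    assert shared is not None
    if not shared:
        raise AlignmentError("empty intersection of sample ids across layers")
    order = sorted(shared)
    dropped = {k: sorted(set(v.sample_ids) - shared) for k, v in present.items()}
    aligned = {k: v.subset_samples(order) for k, v in present.items()}
    report = AlignmentReport(shared=order, dropped=dropped)
    return (aligned.get("band"), aligned.get("traits"),
            aligned.get("features"), report)


@dataclass
class ValidationReport:
    """Advisory flags from :func:`validate_band_matrix`; never an error."""

    monomorphic_bands: list[str]
    high_missing_bands: list[str]
    high_missing_samples: list[str]

    @property
    def clean(self) -> bool:
        return not (self.monomorphic_bands or self.high_missing_bands
                    or self.high_missing_samples)


def validate_band_matrix(bm: BandMatrix,
                         max_missing: float = 0.5) -> ValidationReport:
    """Flag monomorphic bands and bands/samples whose missing fraction
    exceeds ``max_missing``.  Pure report; the input is not mutated."""
    vals = bm.values
    mono, miss_b = [], []
    for band in vals.columns:
        col = vals[band]
        obs = col.dropna()
        if len(obs) and obs.nunique() == 1:
            mono.append(band)
        if col.isna().mean() > max_missing:
            miss_b.append(band)
    miss_s = [s for s in vals.index if vals.loc[s].isna().mean() > max_missing]
    if vals.isna().to_numpy().all(axis=0).any() or vals.isna().to_numpy().all(axis=1).any():
        warnings.warn("all-missing row or column present", stacklevel=2)
    return ValidationReport(mono, miss_b, miss_s)
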