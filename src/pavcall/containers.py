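"""Core in-memory containers for genotype-call, dosage and failed-call data.

All matrices are oriented samples x markers in memory (math convention);
the on-disk TSV dialect is markers x samples (array-export convention) and
is transposed on read/write by :mod:`pavcall.formats`.

Calls are stored as small integer codes for speed; the public alphabet is
the four genotype symbols ``AA``, ``AB``, ``BB`` and ``FF``.  ``FF`` is the
single failure/missing state: a failed assay and a genuinely deleted locus
are deliberately indistinguishable, because downstream analysis treats the
failure itself as a presence-absence marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype codes (count of B allele; 3 = failed call)
AA, AB, BB, FF = 0, 1, 2, 3

CALL_SYMBOLS = np.array(["AA", "AB", "BB", "FF"])
_SYMBOL_TO_CODE = {"AA": AA, "AB": AB, "BB": BB, "FF": FF}
# aliases accepted on input and normalized immediately
CALL_ALIASES = {"BA": "AB", "NA": "FF", "--": "FF"}


class PavcallError(Exception):
    """Base class for all package errors."""


class ParseError(PavcallError):
    """Malformed input file."""


class InvariantError(PavcallError):
    """A container invariant was violated."""


def _check_unique(values, what: str) -> None:
    values = np.asarray(values)
    if len(np.unique(values)) != len(values):
        seen: set = set()
        for v in values:
            if v in seen:
                raise InvariantError(f"duplicate {what}: {v!r}")
            seen.add(v)


@dataclass
class MarkerMap:
    """Marker annotation: id, chromosome label and 1-based bp position."""

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if not (len(self.marker_id) == len(self.chrom) == len(self.pos)):
            raise InvariantError("marker map columns have unequal lengths")
        _check_unique(self.marker_id, "marker_id")
        if len(self.pos) and self.pos.min() < 1:
            raise InvariantError("positions must be >= 1 (1-based)")

    def __len__(self) -> int:
        return len(self.marker_id)

    def subset(self, idx) -> "MarkerMap":
        return MarkerMap(self.marker_id[idx], self.chrom[idx], self.pos[idx])

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_id == marker_id)
        if len(hits) != 1:
            raise KeyError(marker_id)
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_id, "chrom": self.chrom, "pos": self.pos}
        )


def _as_sample_ids(sample_ids) -> np.ndarray:
    sample_ids = np.asarray(sample_ids, dtype=object)
    _check_unique(sample_ids, "sample id")
    return sample_ids


@dataclass
class CallMatrix:
    """Samples x markers categorical genotype calls in {AA, AB, BB, FF}."""

    calls: np.ndarray  # int8 codes, samples x markers
    sample_ids: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise InvariantError("calls must be a 2-D samples x markers array")
        self.sample_ids = _as_sample_ids(self.sample_ids)
        if self.calls.shape[0] != len(self.sample_ids):
            raise InvariantError("row count does not match sample_ids")
        if self.calls.shape[1] != len(self.map):
            raise InvariantError("column count does not match marker map")
        if self.calls.size and (self.calls.min() < AA or self.calls.max() > FF):
            raise InvariantError("call codes outside the {AA, AB, BB, FF} alphabet")

    @classmethod
    def from_symbols(cls, symbols, sample_ids, marker_map: MarkerMap) -> "CallMatrix":
        symbols = np.asarray(symbols, dtype=object)
        codes = np.empty(symbols.shape, dtype=np.int8)
        flat_in, flat_out = symbols.ravel(), codes.ravel()
        for i, s in enumerate(flat_in):
            s = CALL_ALIASES.get(s, s)
            try:
                flat_out[i] = _SYMBOL_TO_CODE[s]
            except KeyError:
                raise ParseError(f"unknown call token {s!r}") from None
        return cls(codes, sample_ids, marker_map)

    def to_symbols(self) -> np.ndarray:
        return CALL_SYMBOLS[self.calls]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset_markers(self, idx) -> "CallMatrix":
        return CallMatrix(self.calls[:, idx], self.sample_ids, self.map.subset(idx))

    def copy(self) -> "CallMatrix":
        return CallMatrix(self.calls.copy(), self.sample_ids.copy(), self.map)


@dataclass
class DosageMatrix:
    """Samples x markers B-allele dosages in {0, 1, 2}, no missing entries."""

    values: np.ndarray
    sample_ids: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sample_ids = _as_sample_ids(self.sample_ids)
        if self.values.shape != (len(self.sample_ids), len(self.map)):
            raise InvariantError("dosage matrix shape inconsistent with ids/map")
        if self.values.size and not np.isin(self.values, (0, 1, 2)).all():
            raise InvariantError("dosages must be in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-marker B-allele frequency, mean(dosage) / 2."""
        return self.values.mean(axis=0) / 2.0

    def subset_markers(self, idx) -> "DosageMatrix":
        return DosageMatrix(self.values[:, idx], self.sample_ids, self.map.subset(idx))


@dataclass
class FailMatrix:
    """Samples x markers failed-call indicators: 0 = called, 2 = failed."""

    values: np.ndarray
    sample_ids: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sample_ids = _as_sample_ids(self.sample_ids)
        if self.values.shape != (len(self.sample_ids), len(self.map)):
            raise InvariantError("fail matrix shape inconsistent with ids/map")
        if self.values.size and not np.isin(self.values, (0, 2)).all():
            raise InvariantError("fail indicators must be in {0, 2}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def fail_freq(self) -> np.ndarray:
        """Per-marker frequency of the F/F state (genotype frequency)."""
        return (self.values == 2).mean(axis=0)

    def subset_markers(self, idx) -> "FailMatrix":
        return FailMatrix(self.values[:, idx], self.sample_ids, self.map.subset(idx))


@dataclass
class PhenotypeTable:
    """Per-sample trait values plus optional categorical covariates."""

    table: pd.DataFrame  # index = sample_id
    trait_names: list = field(default_factory=list)
    covariate_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise InvariantError("duplicate sample ids in phenotype table")
        for c in list(self.trait_names) + list(self.covariate_names):
            if c not in self.table.columns:
                raise InvariantError(f"column {c!r} missing from phenotype table")
        for c in self.covariate_names:
            col = self.table[c]
            if col.isna().any() or (col.astype(str) == "").any():
                raise InvariantError(f"covariate {c!r} has empty levels")

    @property
    def sample_ids(self) -> np.ndarray:
        return np.asarray(self.table.index, dtype=object)

    def trait(self, name: str) -> np.ndarray:
        return np.asarray(self.table[name], dtype=float)

    def covariate(self, name: str) -> np.ndarray:
        return np.asarray(self.table[name].astype(str), dtype=object)
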