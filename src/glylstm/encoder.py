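"""Encoding peptide windows as 31 x k numeric matrices.

Each residue letter is replaced by the standardized value of a
physicochemical scale, giving one 31-long column per property.  Three input
layouts are supported: a single property duplicated into two identical
columns (case 1, 31x2), an ordered pair of distinct properties (case 2,
31x2), and all eight properties in canonical order (case 3, 31x8).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .peptide_io import PeptideRecord, WINDOW_LENGTH
from .properties import (
    CANONICAL_ORDER,
    PropertySet,
    ScaleStats,
    fit_scale_stats,
    load_builtin_property_set,
    standardized_lookup,
)


@dataclass(frozen=True)
class CaseSpec:
    """Which experiment case a matrix belongs to and its property columns."""

    case: int
    properties: Tuple[str, ...]

    def __post_init__(self) -> None:
        for p in self.properties:
            if p not in CANONICAL_ORDER:
                raise ValueError(f"unknown property id {p!r}")
        if self.case == 1:
            if len(self.properties) != 1:
                raise ValueError("case 1 takes exactly one property")
        elif self.case == 2:
            if len(self.properties) != 2 or self.properties[0] == self.properties[1]:
                raise ValueError("case 2 takes exactly two distinct properties")
        elif self.case == 3:
            if self.properties != CANONICAL_ORDER:
                raise ValueError("case 3 uses all eight properties in canonical order")
        else:
            raise ValueError(f"case must be 1, 2 or 3, got {self.case}")

    @property
    def width(self) -> int:
        """Number of matrix columns (2 for cases 1-2, 8 for case 3)."""
        return 2 if self.case in (1, 2) else 8

    @property
    def label(self) -> str:
        """Human-readable subcase name, e.g. ``"IEP"`` or ``"Mass+ToA"``."""
        if self.case == 3:
            return "All8"
        return "+".join(self.properties)

    @staticmethod
    def single(prop: str) -> "CaseSpec":
        return CaseSpec(case=1, properties=(prop,))

    @staticmethod
    def pair(a: str, b: str) -> "CaseSpec":
        return CaseSpec(case=2, properties=(a, b))

    @staticmethod
    def all_eight() -> "CaseSpec":
        return CaseSpec(case=3, properties=CANONICAL_ORDER)


@dataclass(frozen=True)
class EncodedExample:
    """A 31 x k input matrix with its label and source record id."""

    matrix: np.ndarray
    label: Optional[int]
    record_id: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != WINDOW_LENGTH:
            raise ValueError(f"matrix must have {WINDOW_LENGTH} rows, got {self.matrix.shape[0]}")
        if self.matrix.shape[1] not in (2, 8):
            raise ValueError(f"matrix must have 2 or 8 columns, got {self.matrix.shape[1]}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"non-finite entries in encoded matrix for {self.record_id!r}")


def _column(sequence: str, lookup: Dict[str, float]) -> np.ndarray:
    return np.array([lookup[ch] for ch in sequence], dtype=np.float64)


def encode_case1(record: PeptideRecord, prop: str, property_set: PropertySet,
                 stats: ScaleStats) -> EncodedExample:
    """31x2 matrix: one property's standardized column, duplicated."""
    lut = standardized_lookup(property_set, prop, stats)
    col = _column(record.sequence, lut)
    return EncodedExample(matrix=np.stack([col, col], axis=1),
                          label=record.label, record_id=record.id)


def encode_case2(record: PeptideRecord, prop_a: str, prop_b: str,
                 property_set: PropertySet, stats: ScaleStats) -> EncodedExample:
    """31x2 matrix: column 1 from *prop_a*, column 2 from *prop_b*."""
    if prop_a == prop_b:
        raise ValueError(f"case 2 needs two distinct properties, got {prop_a!r} twice (use case 1)")
    col_a = _column(record.sequence, standardized_lookup(property_set, prop_a, stats))
    col_b = _column(record.sequence, standardized_lookup(property_set, prop_b, stats))
    return EncodedExample(matrix=np.stack([col_a, col_b], axis=1),
                          label=record.label, record_id=record.id)


def encode_case3(record: PeptideRecord, property_set: PropertySet,
                 stats: ScaleStats) -> EncodedExample:
    """31x8 matrix, one column per property in canonical order."""
    cols = [
        _column(record.sequence, standardized_lookup(property_set, p, stats))
        for p in CANONICAL_ORDER
    ]
    return EncodedExample(matrix=np.stack(cols, axis=1),
                          label=record.label, record_id=record.id)


def encode_record(record: PeptideRecord, case_spec: CaseSpec,
                  property_set: PropertySet, stats: ScaleStats) -> EncodedExample:
    if case_spec.case == 1:
        return encode_case1(record, case_spec.properties[0], property_set, stats)
    if case_spec.case == 2:
        return encode_case2(record, *case_spec.properties, property_set, stats)
    return encode_case3(record, property_set, stats)


def enumerate_pairs(property_ids: Sequence[str]) -> List[Tuple[str, str]]:
    """All unordered pairs of the given properties, in canonical order."""
    ids = list(dict.fromkeys(property_ids))
    for p in ids:
        if p not in CANONICAL_ORDER:
            raise ValueError(f"unknown property id {p!r}")
    if len(ids) < 2:
        raise ValueError("need at least two distinct property ids to enumerate pairs")
    ids.sort(key=CANONICAL_ORDER.index)
    return list(itertools.combinations(ids, 2))


def encode_dataset(records: Sequence[PeptideRecord], case_spec: CaseSpec,
                   property_set: PropertySet, stats: ScaleStats) -> List[EncodedExample]:
    """Encode every record, preserving order."""
    luts = [standardized_lookup(property_set, p, stats) for p in case_spec.properties]
    out: List[EncodedExample] = []
    for rec in records:
        cols = [_column(rec.sequence, lut) for lut in luts]
        if case_spec.case == 1:
            cols = [cols[0], cols[0]]
        out.append(EncodedExample(matrix=np.stack(cols, axis=1),
                                  label=rec.label, record_id=rec.id))
    return out


def encode_matrix(records: Sequence[PeptideRecord], case_spec: CaseSpec,
                  property_set: PropertySet, stats: ScaleStats,
                  dtype=np.float32) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Vectorized batch encoding: ``(n, 31, k)`` array plus label vector.

    Returns labels as an int array, or ``None`` if any record is unlabeled.
    """
    records = list(records)
    n = len(records)
    X = np.empty((n, WINDOW_LENGTH, case_spec.width), dtype=dtype)
    luts = [standardized_lookup(property_set, p, stats) for p in case_spec.properties]
    if case_spec.case == 1:
        luts = [luts[0], luts[0]]
    # Map sequences to integer codes once, then gather per-property vectors.
    alphabet = sorted(luts[0].keys())
    code = {ch: i for i, ch in enumerate(alphabet)}
    if n:
        idx = np.array([[code[ch] for ch in r.sequence] for r in records], dtype=np.intp)
        for j, lut in enumerate(luts):
            vec = np.array([lut[ch] for ch in alphabet], dtype=dtype)
            X[:, :, j] = vec[idx]
    labels = [r.label for r in records]
    y = None if any(l is None for l in labels) else np.array(labels, dtype=np.int64)
    return X, y


class PeptideEncoder(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer: peptide records -> ``(n, 31, k)`` arrays.

    ``fit`` computes per-property standardization statistics on the given
    (training) records; ``transform`` encodes any records with those frozen
    statistics, so validation/test data never influence the scaling.

    Parameters
    ----------
    case_spec : CaseSpec, default all-eight (case 3)
    property_set : PropertySet, default builtin literature scales
    normalize : bool, default True
        If False, raw scale values are used (identity statistics).
    """

    def __init__(self, case_spec: Optional[CaseSpec] = None,
                 property_set: Optional[PropertySet] = None,
                 normalize: bool = True):
        self.case_spec = case_spec
        self.property_set = property_set
        self.normalize = normalize

    def _resolved(self) -> Tuple[CaseSpec, PropertySet]:
        cs = self.case_spec if self.case_spec is not None else CaseSpec.all_eight()
        ps = self.property_set if self.property_set is not None else load_builtin_property_set()
        return cs, ps

    def fit(self, X: Sequence[PeptideRecord], y=None) -> "PeptideEncoder":
        cs, ps = self._resolved()
        if self.normalize:
            self.stats_ = fit_scale_stats(X, ps)
        else:
            self.stats_ = ScaleStats.identity()
        self.n_features_in_ = cs.width
        return self

    def transform(self, X: Sequence[PeptideRecord]) -> np.ndarray:
        if not hasattr(self, "stats_"):
            raise RuntimeError("PeptideEncoder must be fitted before transform")
        cs, ps = self._resolved()
        mat, _ = encode_matrix(X, cs, ps, self.stats_)
        return mat
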