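"""Synthetic 31-mer benchmark generator with a plantable glycation signal.

Emulates the structure of the curated glycation windows — balanced binary
labels on 31-residue peptides with a fixed central lysine — without
mimicking real proteome composition.  When a signal is planted, the label
probability follows a logistic link on the standardized mean value of one or
more physicochemical properties over the flanking residues; the center K is
constant and carries no information, so only the microenvironment is
predictive.  ``generate_separable`` is the infinite-effect-size limit
(deterministic median-threshold labels), useful as a capacity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .peptide_io import CENTER_INDEX, PeptideRecord, WINDOW_LENGTH
from .properties import (
    CANONICAL_ORDER,
    PropertySet,
    STANDARD_RESIDUES,
    load_builtin_property_set,
)

_AA = np.array(list(STANDARD_RESIDUES))
_K_CODE = STANDARD_RESIDUES.index("K")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``neighborhood`` is the flank half-width over which the planted property
    is averaged (15 covers the whole window; 10 probes a narrower
    microenvironment).  ``background`` is the residue distribution, uniform
    over the 20 standard amino acids by default.
    """

    n: int
    balance: float = 0.5
    planted_properties: Tuple[str, ...] = ()
    beta: float = 0.0
    neighborhood: int = 15
    background: Optional[Tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0.0 < self.balance < 1.0):
            raise ValueError("balance must lie strictly between 0 and 1")
        if not (1 <= self.neighborhood <= 15):
            raise ValueError("neighborhood must lie in 1..15")
        for p in self.planted_properties:
            if p not in CANONICAL_ORDER:
                raise ValueError(f"unknown property id {p!r}")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or np.any(bg < 0) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("background must be 20 non-negative weights summing to 1")

    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 0.05)
        return np.asarray(self.background, dtype=float)


def _flank_positions(neighborhood: int) -> np.ndarray:
    left = np.arange(CENTER_INDEX - neighborhood, CENTER_INDEX)
    right = np.arange(CENTER_INDEX + 1, CENTER_INDEX + 1 + neighborhood)
    return np.concatenate([left, right])


def _random_codes(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    codes = rng.choice(20, size=(n, WINDOW_LENGTH), p=probs)
    codes[:, CENTER_INDEX] = _K_CODE
    return codes


def _codes_to_records(codes: np.ndarray, labels: Sequence[Optional[int]],
                      prefix: str) -> List[PeptideRecord]:
    seqs = ["".join(_AA[row]) for row in codes]
    return [
        PeptideRecord(id=f"{prefix}{i}", sequence=seq,
                      label=None if lab is None else int(lab),
                      provenance="synthetic")
        for i, (seq, lab) in enumerate(zip(seqs, labels))
    ]


def planted_statistic(codes: np.ndarray, config: SyntheticConfig,
                      property_set: Optional[PropertySet] = None) -> np.ndarray:
    """Standardized mean planted-property value over the flanking residues.

    The z-score uses the closed-form mean/sd of the flank average under the
    background distribution; multiple planted properties average their
    z-scores.  Raises if any planted property is constant under the
    background (zero variance).
    """
    if not config.planted_properties:
        raise ValueError("no planted properties configured")
    if property_set is None:
        property_set = load_builtin_property_set()
    probs = config.background_probs()
    pos = _flank_positions(config.neighborhood)
    m = len(pos)
    zs = []
    for prop in config.planted_properties:
        v = np.array([property_set.tables[prop][aa] for aa in STANDARD_RESIDUES])
        mu = float(probs @ v)
        var = float(probs @ (v - mu) ** 2)
        if var == 0.0:
            raise ValueError(
                f"planted property {prop!r} has zero variance under the background"
            )
        flank_mean = v[codes[:, pos]].mean(axis=1)
        zs.append((flank_mean - mu) / math.sqrt(var / m))
    return np.mean(zs, axis=0)


def generate_null(config: SyntheticConfig,
                  property_set: Optional[PropertySet] = None) -> List[PeptideRecord]:
    """Balanced dataset whose labels are independent of the sequences."""
    rng = np.random.default_rng(config.seed)
    codes = _random_codes(rng, config.n, config.background_probs())
    n_pos = int(round(config.n * config.balance))
    labels = np.zeros(config.n, dtype=np.int64)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    return _codes_to_records(codes, labels, "null")


def generate_planted(config: SyntheticConfig,
                     property_set: Optional[PropertySet] = None) -> List[PeptideRecord]:
    """Dataset whose labels follow ``Bernoulli(logistic(beta * z))``.

    ``z`` is the planted statistic of :func:`planted_statistic`.  Candidate
    windows are rejection-sampled so the configured class balance is hit
    exactly.  With ``beta == 0`` this reduces to :func:`generate_null`.
    """
    if config.beta == 0.0 or not config.planted_properties:
        return generate_null(config, property_set)
    rng = np.random.default_rng(config.seed)
    probs = config.background_probs()
    n_pos_target = int(round(config.n * config.balance))
    n_neg_target = config.n - n_pos_target
    pos_rows: List[np.ndarray] = []
    neg_rows: List[np.ndarray] = []
    guard = 0
    while len(pos_rows) < n_pos_target or len(neg_rows) < n_neg_target:
        guard += 1
        if guard > 1000:
            raise RuntimeError("rejection sampling failed to reach the target balance")
        chunk = max(256, config.n)
        codes = _random_codes(rng, chunk, probs)
        z = planted_statistic(codes, config, property_set)
        p1 = 1.0 / (1.0 + np.exp(-config.beta * z))
        labels = (rng.random(chunk) < p1).astype(np.int64)
        for row, lab in zip(codes, labels):
            if lab == 1 and len(pos_rows) < n_pos_target:
                pos_rows.append(row)
            elif lab == 0 and len(neg_rows) < n_neg_target:
                neg_rows.append(row)
    codes = np.stack(pos_rows + neg_rows)
    labels = np.array([1] * n_pos_target + [0] * n_neg_target, dtype=np.int64)
    order = rng.permutation(config.n)
    return _codes_to_records(codes[order], labels[order], "planted")


def generate_separable(config: SyntheticConfig,
                       property_set: Optional[PropertySet] = None) -> List[PeptideRecord]:
    """Deterministic labels: 1 iff the planted statistic exceeds its median.

    The infinite-effect-size limit; a threshold rule on the statistic
    classifies this data perfectly, so it serves as a model-capacity oracle.
    Balance is exactly 50/50 (within one record for odd n).
    """
    if not config.planted_properties:
        raise ValueError("generate_separable needs at least one planted property")
    rng = np.random.default_rng(config.seed)
    codes = _random_codes(rng, config.n, config.background_probs())
    z = planted_statistic(codes, config, property_set)
    order = np.argsort(z, kind="stable")
    labels = np.zeros(config.n, dtype=np.int64)
    labels[order[config.n // 2:]] = 1  # top half by z
    return _codes_to_records(codes, labels, "sep")
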