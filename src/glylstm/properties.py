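"""Physicochemical amino-acid scales and their standardization.

Eight per-residue numeric scales drive the peptide encoding: sequence-order
code (SoA), hydropathy (Hyd), average residue mass (Mass), hydrophobicity
(Hyp), polarizability (Pol), normalized van der Waals volume (vdW),
side-chain torsion-angle count (ToA) and isoelectric point (IEP).  A
:class:`PropertySet` bundles one :class:`PropertyTable` per scale; raw values
are z-scored with :class:`ScaleStats` fitted on a training split only, and
the padding symbol ``X`` always encodes as 0 after standardization (the
population center).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np

#: The 20 standard residues, alphabetical by one-letter code.
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Padding symbol used when a window overhangs a protein terminus.
PAD_SYMBOL: str = "X"

#: Canonical property order; fixes column semantics for the 8-wide encoding.
CANONICAL_ORDER: tuple = ("SoA", "Hyd", "Mass", "Hyp", "Pol", "vdW", "ToA", "IEP")

# Ambiguity / non-standard codes are rejected, never imputed.
AMBIGUOUS_CODES = frozenset("BZJUO")


def _table(values: Mapping[str, float]) -> Dict[str, float]:
    return {aa: float(values[aa]) for aa in STANDARD_RESIDUES}


# Kyte & Doolittle hydropathy index.
_HYD = _table({
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
})

# Average residue (monomer minus water) mass in daltons.
_MASS = _table({
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
})

# Fauchère & Pliška octanol/water hydrophobicity (pi values).
_HYP = _table({
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54, "Q": -0.22,
    "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80, "L": 1.70, "K": -0.99,
    "M": 1.23, "F": 1.79, "P": 0.72, "S": -0.04, "T": 0.26, "W": 2.25,
    "Y": 0.96, "V": 1.22,
})

# Charton & Charton side-chain polarizability.
_POL = _table({
    "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128, "Q": 0.180,
    "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186, "L": 0.186, "K": 0.219,
    "M": 0.221, "F": 0.290, "P": 0.131, "S": 0.062, "T": 0.108, "W": 0.409,
    "Y": 0.298, "V": 0.140,
})

# Normalized van der Waals volume (Fauchère et al.).
_VDW = _table({
    "A": 1.00, "R": 6.13, "N": 2.95, "D": 2.78, "C": 2.43, "Q": 3.95,
    "E": 3.78, "G": 0.00, "H": 4.66, "I": 4.00, "L": 4.00, "K": 4.77,
    "M": 4.43, "F": 5.89, "P": 2.72, "S": 1.60, "T": 2.60, "W": 8.08,
    "Y": 6.47, "V": 3.00,
})

# Count of rotatable side-chain torsion (chi) angles per residue.  A
# documented stand-in for a backbone/side-chain dihedral-preference scale;
# replace via load_property_table_file for a different torsion-angle scale.
_TOA = _table({
    "A": 0, "R": 4, "N": 2, "D": 2, "C": 1, "Q": 3, "E": 3, "G": 0,
    "H": 2, "I": 2, "L": 2, "K": 4, "M": 3, "F": 2, "P": 2, "S": 1,
    "T": 1, "W": 2, "Y": 2, "V": 1,
})

# Free amino-acid isoelectric points (pH units).
_IEP = _table({
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
})

# Sequence-order code: ordinal 1..20 by alphabetical one-letter code.
_SOA = {aa: float(i + 1) for i, aa in enumerate(STANDARD_RESIDUES)}

_BUILTIN_VALUES = {
    "SoA": (_SOA, "ordinal code 1-20, alphabetical one-letter order"),
    "Hyd": (_HYD, "Kyte-Doolittle hydropathy index"),
    "Mass": (_MASS, "average residue mass (Da)"),
    "Hyp": (_HYP, "Fauchere-Pliska octanol hydrophobicity"),
    "Pol": (_POL, "Charton-Charton polarizability"),
    "vdW": (_VDW, "normalized van der Waals volume"),
    "ToA": (_TOA, "side-chain torsion (chi) angle count"),
    "IEP": (_IEP, "free amino-acid isoelectric point (pH)"),
}


@dataclass(frozen=True)
class PropertyTable:
    """One named residue -> value scale over the 20 standard amino acids."""

    id: str
    values: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        if self.id not in CANONICAL_ORDER:
            raise ValueError(f"unknown property id {self.id!r}; expected one of {CANONICAL_ORDER}")
        keys = set(self.values)
        expected = set(STANDARD_RESIDUES)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise ValueError(
                f"property table {self.id!r} must key exactly the 20 standard residues; "
                f"missing={missing} extra={extra}"
            )
        for aa, v in self.values.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite value for residue {aa!r} in table {self.id!r}")

    def __getitem__(self, residue: str) -> float:
        return float(self.values[residue])


@dataclass(frozen=True)
class PropertySet:
    """All eight property tables plus the padding convention.

    ``pad_value`` is the value the pad symbol ``X`` takes *after*
    standardization (default 0, the population center).
    """

    tables: Mapping[str, PropertyTable]
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        missing = [p for p in CANONICAL_ORDER if p not in self.tables]
        if missing:
            raise ValueError(f"property set is missing tables: {missing}")

    def value(self, prop: str, residue: str) -> float:
        """Raw scale value; the pad symbol resolves to ``pad_value``."""
        if residue == PAD_SYMBOL:
            return self.pad_value
        return self.tables[prop][residue]

    def table(self, prop: str) -> PropertyTable:
        return self.tables[prop]


@dataclass(frozen=True)
class ScaleStats:
    """Per-property mean/sd fitted on the residue positions of one split."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n_positions: int = 0

    def __post_init__(self) -> None:
        for prop, s in self.sd.items():
            if not (s > 0):
                raise ValueError(f"standard deviation for {prop!r} must be > 0, got {s}")

    @staticmethod
    def identity() -> "ScaleStats":
        """Stats that leave raw values unchanged (normalization off)."""
        return ScaleStats(
            mean={p: 0.0 for p in CANONICAL_ORDER},
            sd={p: 1.0 for p in CANONICAL_ORDER},
            n_positions=0,
        )


def load_builtin_property_set(pad_value: float = 0.0) -> PropertySet:
    """The eight builtin literature scales (see module docstring)."""
    tables = {
        pid: PropertyTable(id=pid, values=vals, source=src)
        for pid, (vals, src) in _BUILTIN_VALUES.items()
    }
    return PropertySet(tables=tables, pad_value=pad_value)


def fit_scale_stats(records: Sequence, property_set: PropertySet) -> ScaleStats:
    """Per-property mean and sd over all non-pad residue positions of *records*.

    Fit this on the training split only; validation/test encodings reuse it.
    Raises if *records* is empty or any property is constant across the
    observed residues (zero sd).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot fit scale statistics on an empty record list")
    counts: Dict[str, int] = {aa: 0 for aa in STANDARD_RESIDUES}
    total = 0
    for rec in records:
        for ch in rec.sequence:
            if ch == PAD_SYMBOL:
                continue
            counts[ch] += 1
            total += 1
    if total == 0:
        raise ValueError("records contain no non-pad residues")
    mean: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    aas = list(STANDARD_RESIDUES)
    w = np.array([counts[aa] for aa in aas], dtype=float)
    for prop in CANONICAL_ORDER:
        v = np.array([property_set.tables[prop][aa] for aa in aas])
        m = float(np.dot(w, v) / total)
        var = float(np.dot(w, (v - m) ** 2) / total)
        s = math.sqrt(var)
        if s == 0.0:
            raise ValueError(f"property {prop!r} has zero variance on the given records")
        mean[prop] = m
        sd[prop] = s
    return ScaleStats(mean=mean, sd=sd, n_positions=total)


def standardize(value: float, prop: str, stats: ScaleStats) -> float:
    """Z-score a raw property value: ``(value - mean) / sd``."""
    return (float(value) - stats.mean[prop]) / stats.sd[prop]


def standardize_residue(residue: str, prop: str, property_set: PropertySet,
                        stats: ScaleStats) -> float:
    """Standardized value of a residue; the pad symbol maps to 0."""
    if residue == PAD_SYMBOL:
        return 0.0
    return standardize(property_set.tables[prop][residue], prop, stats)


def standardized_lookup(property_set: PropertySet, prop: str,
                        stats: ScaleStats) -> Dict[str, float]:
    """Residue -> standardized value map, including ``X`` -> 0."""
    out = {
        aa: standardize(property_set.tables[prop][aa], prop, stats)
        for aa in STANDARD_RESIDUES
    }
    out[PAD_SYMBOL] = 0.0
    return out


def write_property_table_file(property_set: PropertySet, path) -> None:
    """Write the set as the canonical TSV (header + 20 residue rows)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("residue\t" + "\t".join(CANONICAL_ORDER) + "\n")
        for aa in STANDARD_RESIDUES:
            row = [repr(property_set.tables[p][aa]) for p in CANONICAL_ORDER]
            fh.write(aa + "\t" + "\t".join(row) + "\n")


def load_property_table_file(path, base: PropertySet | None = None,
                             pad_value: float = 0.0) -> PropertySet:
    """Load property tables from a TSV file, replacing or augmenting builtins.

    The file has a header row ``residue<TAB><PropertyId>...`` and exactly one
    row per standard residue.  Columns may be any subset of the eight ids;
    omitted properties fall back to *base* (default: builtins).
    """
    if base is None:
        base = load_builtin_property_set(pad_value=pad_value)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty property table file") from None
        if not header or header[0].strip().lower() != "residue":
            raise ValueError(f"{path}: first header column must be 'residue'")
        props = [h.strip() for h in header[1:]]
        for p in props:
            if p not in CANONICAL_ORDER:
                raise ValueError(f"{path}: unknown property column {p!r}")
        seen: Dict[str, Dict[str, float]] = {p: {} for p in props}
        residues_seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            aa = row[0].strip()
            if aa not in STANDARD_RESIDUES:
                raise ValueError(f"{path}:{lineno}: unknown residue {aa!r}")
            if aa in residues_seen:
                raise ValueError(f"{path}:{lineno}: duplicate row for residue {aa!r}")
            residues_seen.add(aa)
            if len(row) != len(props) + 1:
                raise ValueError(f"{path}:{lineno}: expected {len(props) + 1} columns, got {len(row)}")
            for p, cell in zip(props, row[1:]):
                try:
                    seen[p][aa] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {p!r}"
                    ) from None
        missing = sorted(set(STANDARD_RESIDUES) - residues_seen)
        if missing:
            raise ValueError(f"{path}: missing residue row(s): {', '.join(missing)}")
    tables = dict(base.tables)
    for p in props:
        tables[p] = PropertyTable(id=p, values=seen[p], source=str(path))
    return PropertySet(tables=tables, pad_value=pad_value)
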