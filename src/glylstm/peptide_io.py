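"""Reading, writing and splitting labeled 31-residue lysine windows.

Every record is a 31-mer with the candidate lysine at position 16 (1-based),
15 flanking residues on each side, truncations at protein termini padded with
``X``.  Splits and fold plans are stratified by label and fully determined by
their seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from sklearn.model_selection import StratifiedKFold

from .properties import PAD_SYMBOL, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 31
#: 0-based index of the central lysine (position 16, 1-based).
CENTER_INDEX = WINDOW_LENGTH // 2

_VALID_CHARS = frozenset(STANDARD_RESIDUES + PAD_SYMBOL)


@dataclass(frozen=True)
class PeptideRecord:
    """A 31-mer window centered on a lysine, with an optional binary label.

    ``label`` is 1 (glycated), 0 (nonglycated) or ``None`` (unknown, e.g.
    prediction-mode windows extracted from a FASTA).
    """

    id: str
    sequence: str
    label: Optional[int] = None
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"record {self.id!r}: sequence length must be {WINDOW_LENGTH}, "
                f"got {len(self.sequence)}"
            )
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue code(s) {sorted(bad)} "
                f"(ambiguity codes are rejected, not imputed)"
            )
        if self.sequence[CENTER_INDEX] != "K":
            raise ValueError(
                f"record {self.id!r}: central residue (position {CENTER_INDEX + 1}) "
                f"must be 'K', got {self.sequence[CENTER_INDEX]!r}"
            )
        if self.label not in (0, 1, None):
            raise ValueError(f"record {self.id!r}: label must be 0, 1 or unknown, got {self.label!r}")


@dataclass(frozen=True)
class DatasetSplit:
    """Train/validation/test record lists with the seed that produced them."""

    train: Tuple[PeptideRecord, ...]
    validation: Tuple[PeptideRecord, ...]
    test: Tuple[PeptideRecord, ...]
    seed: int = 0


@dataclass(frozen=True)
class FoldPlan:
    """A stratified k-way partition of record ids."""

    folds: Tuple[Tuple[str, ...], ...]
    seed: int = 0


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fasta", ".fa", ".faa"}:
        return "fasta"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_peptide_table(path, dialect: Optional[str] = None) -> List[PeptideRecord]:
    """Read labeled peptide windows from a delimited table or FASTA file.

    Delimited files need columns ``id``, ``sequence``, ``label``; FASTA
    headers carry ``id|label``.  All invalid rows are reported together,
    with line numbers.
    """
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in {"tsv", "csv", "fasta"}:
        raise ValueError(f"unknown dialect {dialect!r}; expected tsv, csv or fasta")

    records: List[PeptideRecord] = []
    errors: List[str] = []

    if dialect == "fasta":
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            parts = rec.id.split("|")
            if len(parts) < 2:
                errors.append(f"entry {i} ({rec.id!r}): header must be 'id|label'")
                continue
            rid, raw_label = "|".join(parts[:-1]), parts[-1]
            if raw_label not in {"0", "1"}:
                errors.append(f"entry {i} ({rec.id!r}): label must be 0 or 1, got {raw_label!r}")
                continue
            try:
                records.append(PeptideRecord(id=rid, sequence=str(rec.seq).upper(),
                                             label=int(raw_label), provenance=str(path)))
            except ValueError as exc:
                errors.append(f"entry {i}: {exc}")
    else:
        delim = "," if dialect == "csv" else "\t"
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter=delim)
            try:
                header = [h.strip().lower() for h in next(reader)]
            except StopIteration:
                raise ValueError(f"{path}: empty file") from None
            try:
                idx = {col: header.index(col) for col in ("id", "sequence", "label")}
            except ValueError:
                raise ValueError(
                    f"{path}: header must contain columns id, sequence, label; got {header}"
                ) from None
            for lineno, row in enumerate(reader, start=2):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                try:
                    raw_label = row[idx["label"]].strip()
                    if raw_label not in {"0", "1"}:
                        raise ValueError(f"label must be 0 or 1, got {raw_label!r}")
                    records.append(PeptideRecord(
                        id=row[idx["id"]].strip(),
                        sequence=row[idx["sequence"]].strip().upper(),
                        label=int(raw_label),
                        provenance=str(path),
                    ))
                except (ValueError, IndexError) as exc:
                    errors.append(f"line {lineno}: {exc}")

    if errors:
        raise ValueError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return records


def write_peptide_table(records: Sequence[PeptideRecord], path) -> None:
    """Write records as the canonical TSV (id, sequence, label)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tsequence\tlabel\n")
        for rec in records:
            label = "" if rec.label is None else str(rec.label)
            fh.write(f"{rec.id}\t{rec.sequence}\t{label}\n")


def extract_windows(fasta_path, flank: int = 15) -> List[PeptideRecord]:
    """Extract one unlabeled window per lysine from a protein FASTA.

    Windows overhanging a terminus are padded with ``X`` so the lysine stays
    centered.  Proteins containing non-standard residue codes are skipped
    with a warning.  Record ids are ``"<protein_id>:K<pos>"`` (1-based).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    out: List[PeptideRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(STANDARD_RESIDUES)
        if bad:
            logger.warning(
                "skipping protein %s: non-standard residue code(s) %s",
                rec.id, sorted(bad),
            )
            continue
        padded = PAD_SYMBOL * flank + seq + PAD_SYMBOL * flank
        for i, ch in enumerate(seq):
            if ch != "K":
                continue
            window = padded[i:i + 2 * flank + 1]
            out.append(PeptideRecord(
                id=f"{rec.id}:K{i + 1}",
                sequence=window,
                label=None,
                provenance=str(fasta_path),
            ))
    return out


def _stratified_allocation(n_per_class: Dict[int, int], sizes: Sequence[int]) -> Dict[int, List[int]]:
    """Largest-remainder allocation of each class across the split sizes."""
    total = sum(n_per_class.values())
    alloc = {c: [0] * len(sizes) for c in n_per_class}
    for i, s in enumerate(sizes):
        quotas = {c: s * n / total for c, n in n_per_class.items()}
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        short = s - sum(base.values())
        order = sorted(n_per_class, key=lambda c: quotas[c] - base[c], reverse=True)
        for c in order[:short]:
            base[c] += 1
        for c in n_per_class:
            alloc[c][i] = base[c]
    # Repair any per-class oversubscription (possible with tiny classes).
    for c, n in n_per_class.items():
        used = sum(alloc[c])
        i = 0
        while used > n:
            if alloc[c][i] > 0:
                alloc[c][i] -= 1
                others = [d for d in n_per_class if d != c and sum(alloc[d]) < n_per_class[d]]
                if not others:
                    raise ValueError("cannot satisfy split sizes with the given class counts")
                alloc[others[0]][i] += 1
                used -= 1
            i = (i + 1) % len(sizes)
    return alloc


def make_split(records: Sequence[PeptideRecord],
               sizes: Tuple[int, int, int] = (4830, 1000, 1000),
               seed: int = 0) -> DatasetSplit:
    """Stratified random train/validation/test split with exact sizes.

    Deterministic given *seed*; requires all labels known and
    ``len(records) >= sum(sizes)``.
    """
    records = list(records)
    needed = sum(sizes)
    if len(records) < needed:
        raise ValueError(
            f"insufficient records: need {needed} for sizes {tuple(sizes)}, "
            f"have {len(records)}"
        )
    if any(r.label is None for r in records):
        raise ValueError("all records must carry a known label to be split")
    rng = np.random.default_rng(seed)
    by_class: Dict[int, List[int]] = {0: [], 1: []}
    for i, r in enumerate(records):
        by_class[r.label].append(i)
    for c in by_class:
        idx = np.array(by_class[c], dtype=int)
        rng.shuffle(idx)
        by_class[c] = list(idx)
    n_per_class = {c: len(v) for c, v in by_class.items() if v}
    alloc = _stratified_allocation(n_per_class, sizes)
    parts: List[List[PeptideRecord]] = [[], [], []]
    cursor = {c: 0 for c in n_per_class}
    for i in range(3):
        for c in n_per_class:
            take = alloc[c][i]
            sel = by_class[c][cursor[c]:cursor[c] + take]
            cursor[c] += take
            parts[i].extend(records[j] for j in sel)
    # Shuffle within each part so class blocks are not contiguous.
    for part in parts:
        order = rng.permutation(len(part))
        part[:] = [part[j] for j in order]
    return DatasetSplit(train=tuple(parts[0]), validation=tuple(parts[1]),
                        test=tuple(parts[2]), seed=seed)


def make_folds(records: Sequence[PeptideRecord], k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-way partition of record ids (sizes differ by at most 1)."""
    records = list(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, have {len(records)}")
    if any(r.label is None for r in records):
        raise ValueError("all records must carry a known label for fold assignment")
    y = np.array([r.label for r in records])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 32))
    folds = []
    for _, test_idx in skf.split(np.zeros(len(records)), y):
        folds.append(tuple(records[i].id for i in test_idx))
    return FoldPlan(folds=tuple(folds), seed=seed)


def write_predictions(records: Sequence[PeptideRecord],
                      probabilities: Sequence[Tuple[float, float]],
                      path) -> None:
    """Write per-window glycation probabilities as TSV.

    *probabilities* holds one ``(p_glycated, p_nonglycated)`` pair per
    record, each summing to 1 within 1e-6.  The predicted label is 1 iff
    ``p_glycated > p_nonglycated`` (exact ties resolve to 0).
    """
    probabilities = list(probabilities)
    if len(probabilities) != len(records):
        raise ValueError(
            f"got {len(probabilities)} probability pairs for {len(records)} records"
        )
    for i, (p1, p0) in enumerate(probabilities):
        if abs((p1 + p0) - 1.0) > 1e-6:
            raise ValueError(f"probability pair {i} sums to {p1 + p0}, expected 1")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tsequence\tp_glycated\tp_nonglycated\tpredicted_label\n")
        for rec, (p1, p0) in zip(records, probabilities):
            pred = 1 if p1 > p0 else 0
            fh.write(f"{rec.id}\t{rec.sequence}\t{p1:.6f}\t{p0:.6f}\t{pred}\n")
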