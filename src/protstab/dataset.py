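"""Mutation datasets: records, labelling, TSV/FASTA input and output.

A record describes one single amino-acid substitution: the protein sequence,
the 1-based substitution position, wild-type and mutant residues, the pH at
which the stability change was measured, and a stability free-energy change
ddG (kcal/mol) and/or a binary direction label.  The sign convention is:
ddG < 0 means destabilization (class "negative"); ddG >= 0 — including
exactly zero — means the substitution does not destabilize (class
"positive", increased stability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .scales import AMINO_ACIDS

POSITIVE = "positive"
NEGATIVE = "negative"

TSV_COLUMNS = ["protein_id", "position", "wt", "mut", "ph", "ddg", "label", "sequence"]


class DatasetError(ValueError):
    """Raised for invalid mutation records or malformed dataset files."""


def label_from_ddg(ddg: float) -> str:
    """Binary direction label from the stability free-energy change.

    ``ddg < 0`` (destabilizing) -> ``"negative"``; otherwise -> ``"positive"``.
    Note that ddG exactly 0 maps to positive under this rule.
    """
    if not math.isfinite(ddg):
        raise DatasetError(f"non-finite ddG: {ddg!r}")
    return NEGATIVE if ddg < 0 else POSITIVE


@dataclass(frozen=True)
class MutationInstance:
    """One substitution record.  ``position`` is 1-based (G56S = position 56)."""

    protein_id: str
    sequence: str
    position: int
    wt_residue: str
    mut_residue: str
    ph: float
    ddg: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatasetError(f"{self.protein_id}: empty sequence")
        if not (1 <= self.position <= len(self.sequence)):
            raise DatasetError(
                f"{self.protein_id}: position {self.position} outside "
                f"1..{len(self.sequence)}"
            )
        if self.sequence[self.position - 1] != self.wt_residue:
            raise DatasetError(
                f"{self.protein_id}: sequence has "
                f"{self.sequence[self.position - 1]!r} at position "
                f"{self.position}, expected wild-type {self.wt_residue!r}"
            )
        if self.wt_residue == self.mut_residue:
            raise DatasetError(
                f"{self.protein_id}: wild-type and mutant residue both "
                f"{self.wt_residue!r}"
            )
        if self.mut_residue not in AMINO_ACIDS:
            raise DatasetError(
                f"{self.protein_id}: non-standard mutant residue "
                f"{self.mut_residue!r}"
            )
        if not (0.0 <= self.ph <= 14.0):
            raise DatasetError(f"{self.protein_id}: pH {self.ph} outside 0..14")
        if self.ddg is not None and self.label is not None:
            if self.label != label_from_ddg(self.ddg):
                raise DatasetError(
                    f"{self.protein_id}: label {self.label!r} inconsistent "
                    f"with ddG {self.ddg}"
                )
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise DatasetError(f"{self.protein_id}: bad label {self.label!r}")

    def with_label(self) -> "MutationInstance":
        """Return a copy whose label is filled from ddG if absent."""
        if self.label is not None or self.ddg is None:
            return self
        return replace(self, label=label_from_ddg(self.ddg))

    @property
    def key(self) -> tuple[str, int, str, float]:
        return (self.protein_id, self.position, self.mut_residue, self.ph)


@dataclass
class Dataset:
    """Ordered collection of :class:`MutationInstance` records."""

    instances: list[MutationInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for inst in self.instances:
            if inst.key in seen:
                raise DatasetError(
                    f"duplicate record (protein_id, position, mut, ph) = "
                    f"{inst.key}"
                )
            seen.add(inst.key)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[MutationInstance]:
        return iter(self.instances)

    def __getitem__(self, i: int) -> MutationInstance:
        return self.instances[i]

    @property
    def counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) over labelled instances."""
        pos = sum(1 for i in self.instances if i.label == POSITIVE)
        neg = sum(1 for i in self.instances if i.label == NEGATIVE)
        return pos, neg

    def labels(self) -> list[str]:
        return [i.label for i in self.instances]  # type: ignore[misc]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": i.protein_id,
                "position": i.position,
                "wt": i.wt_residue,
                "mut": i.mut_residue,
                "ph": i.ph,
                "ddg": i.ddg,
                "label": i.label,
                "sequence": i.sequence,
            }
            for i in self.instances
        ]
        return pd.DataFrame(rows, columns=TSV_COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_fasta(self, path: str | Path) -> None:
        seqs: dict[str, str] = {}
        for inst in self.instances:
            seqs.setdefault(inst.protein_id, inst.sequence)
        with open(path, "w") as fh:
            for pid, seq in seqs.items():
                fh.write(f">{pid}\n{seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: sequence}``.

    Sequences are upper-cased, whitespace removed, and a trailing ``*``
    terminator stripped.  Duplicate ids and empty files are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DatasetError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper().replace(" ", "")
        records[rec.id] = seq.rstrip("*")
    if not records:
        raise DatasetError(f"{path}: no FASTA records found")
    return records


def _build_instance(row: dict, sequences: dict[str, str] | None) -> MutationInstance:
    pid = str(row["protein_id"])
    if "sequence" in row and isinstance(row.get("sequence"), str) and row["sequence"]:
        seq = row["sequence"].upper()
    elif sequences is not None and pid in sequences:
        seq = sequences[pid]
    else:
        raise DatasetError(f"{pid}: no sequence (inline column or FASTA) found")
    ddg = row.get("ddg")
    if ddg is not None and (isinstance(ddg, float) and math.isnan(ddg)):
        ddg = None
    label = row.get("label")
    if isinstance(label, float) and math.isnan(label):
        label = None
    if pd.isna(row.get("ph")):
        raise DatasetError(f"{pid}: missing pH (pH is part of the input vector)")
    inst = MutationInstance(
        protein_id=pid,
        sequence=seq,
        position=int(row["position"]),
        wt_residue=str(row["wt"]),
        mut_residue=str(row["mut"]),
        ph=float(row["ph"]),
        ddg=None if ddg is None else float(ddg),
        label=label,
    )
    if inst.ddg is None and inst.label is None:
        raise DatasetError(f"{pid}: record has neither ddG nor label")
    return inst.with_label()


def read_dataset(
    path: str | Path,
    fasta: str | Path | None = None,
    skip_invalid: bool = False,
) -> Dataset:
    """Read a mutation table (TSV) into a validated :class:`Dataset`.

    Required columns: ``protein_id``, ``position``, ``wt``, ``mut``, ``ph``
    and at least one of ``ddg`` / ``label``; sequences come from an inline
    ``sequence`` column or from the companion FASTA.  Invalid rows are
    collected and reported with their row numbers; by default any invalid
    row is fatal, with ``skip_invalid=True`` they are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "wt", "mut", "ph"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing columns {sorted(missing)}")
    if "ddg" not in df.columns and "label" not in df.columns:
        raise DatasetError(f"{path}: need a 'ddg' or 'label' column")
    sequences = read_fasta(fasta) if fasta is not None else None

    instances: list[MutationInstance] = []
    errors: list[str] = []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            instances.append(_build_instance(row, sequences))
        except DatasetError as exc:
            errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if errors and not skip_invalid:
        raise DatasetError(
            f"{path}: {len(errors)} invalid record(s):\n  " + "\n  ".join(errors)
        )
    return Dataset(instances)


def from_records(records: Iterable[MutationInstance]) -> Dataset:
    return Dataset([r.with_label() for r in records])
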